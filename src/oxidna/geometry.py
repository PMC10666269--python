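"""Rigid-body base-step parameters from base reference frames.

Each nucleobase carries an orthonormal right-handed reference triad
(origin plus x, y, z axes, with z roughly along the 5'->3' helical
advance).  The six step parameters of two stacked bases are obtained
with a mid-step-frame convention:

1. the relative rotation R taking triad 1 onto triad 2 is expressed as a
   rotation vector v (axis times angle);
2. the mid-step triad is triad 1 rotated halfway along v;
3. tilt, roll, twist are the components of v on the mid-frame x, y, z
   axes (in degrees) — because the rotation axis is invariant under its
   own rotation, these equal the components of v on either end triad;
4. shift, slide, rise are the components of the origin displacement on
   the mid-frame axes (in angstroms).

The construction is exactly invertible (:func:`build_step`), and
reversing a step negates all six parameters.  This is the mid-frame
convention in common use for nucleic-acid step analysis; any
self-consistent convention serves the downstream correlation analysis,
and the one used here is recorded in output metadata as
``"midframe-rotation-vector"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import StepParameters

__all__ = [
    "CONVENTION",
    "BaseFrame",
    "GeometryError",
    "step_parameters",
    "build_step",
    "helix_fixture",
]

CONVENTION = "midframe-rotation-vector"

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """A base triad is not orthonormal and right-handed."""


@dataclass(frozen=True)
class BaseFrame:
    """Origin (A) and right-handed orthonormal axis triad of one base."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t = self.triad
        if not np.allclose(t.T @ t, np.eye(3), atol=100 * _ORTHO_TOL):
            raise GeometryError("axes are not orthonormal")
        if np.linalg.det(t) < 0:
            raise GeometryError("axes are left-handed")

    @property
    def triad(self) -> np.ndarray:
        """3x3 matrix with the axes as columns (lab coordinates)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def identity(cls) -> "BaseFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @classmethod
    def from_triad(cls, origin: np.ndarray, triad: np.ndarray) -> "BaseFrame":
        return cls(origin, triad[:, 0].copy(), triad[:, 1].copy(), triad[:, 2].copy())


def step_parameters(f1: BaseFrame, f2: BaseFrame, step_index: int = 1) -> StepParameters:
    """Six step parameters of the step from base frame ``f1`` to ``f2``."""
    t1, t2 = f1.triad, f2.triad
    rel = Rotation.from_matrix(t2 @ t1.T)  # lab-frame rotation f1 -> f2
    v_lab = rel.as_rotvec()
    # axis of a rotation is invariant under it: components on f1 == mid == f2
    v_local = t1.T @ v_lab
    t_mid = Rotation.from_rotvec(v_lab / 2.0).as_matrix() @ t1
    d_mid = t_mid.T @ (f2.origin - f1.origin)
    tilt, roll, twist = np.degrees(v_local)
    shift, slide, rise = d_mid
    return StepParameters(
        step_index=step_index,
        shift=float(shift),
        slide=float(slide),
        rise=float(rise),
        tilt=float(tilt),
        roll=float(roll),
        twist=float(twist),
    )


def build_step(f1: BaseFrame, p: StepParameters) -> BaseFrame:
    """Base frame f2 such that ``step_parameters(f1, f2)`` recovers ``p``."""
    v_local = np.radians([p.tilt, p.roll, p.twist])
    d_mid = np.array([p.shift, p.slide, p.rise])
    t1 = f1.triad
    v_lab = t1 @ v_local
    t2 = Rotation.from_rotvec(v_lab).as_matrix() @ t1
    t_mid = Rotation.from_rotvec(v_lab / 2.0).as_matrix() @ t1
    origin2 = f1.origin + t_mid @ d_mid
    return BaseFrame.from_triad(origin2, t2)


def helix_fixture(
    n_steps: int,
    p: StepParameters,
    jitter: float | np.ndarray = 0.0,
    seed: int | None = None,
) -> list[BaseFrame]:
    """Chain of ``n_steps + 1`` base frames built from a repeated step.

    ``jitter`` adds independent Gaussian noise (one sigma per parameter,
    or a scalar applied to all six) to each step before composing it.
    Deterministic for a fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sig = np.broadcast_to(np.asarray(jitter, dtype=float), (6,))
    rng = np.random.default_rng(seed)
    frames = [BaseFrame.identity()]
    base = np.array(p.as_tuple())
    for k in range(n_steps):
        noisy = base + rng.normal(0.0, 1.0, size=6) * sig
        step = StepParameters(k + 1, *noisy)
        frames.append(build_step(frames[-1], step))
    return frames
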
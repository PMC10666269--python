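"""One-electron oxidation potentials from vertical-energy ensembles.

Within the linear-response (Marcus) picture the free energy of the
one-electron oxidation X -> X+ + e- at a given solvated geometry is the
mean of the vertical ionization energy of the neutral strand and the
vertical attachment energy of the cation,

    dG_ox = (VIE + VAE) / 2 + G(e-_gas),

where G(e-_gas) is the free energy of the gas-phase electron from
Fermi-Dirac statistics (-0.867 kcal/mol).  The potential against the
standard hydrogen electrode follows from

    E_red = dG_ox / n_e - E_SHE,

with energies per electron in eV mapping one-to-one to volts and the
absolute SHE reduction potential taken as 4.281 V.  The potential is
evaluated per frame and then averaged over the geometric ensemble; the
spread of the per-frame potentials is reported as the sample standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import StrandEnsemble

__all__ = [
    "KCAL_PER_MOL_TO_EV",
    "RedoxConstants",
    "RedoxEstimate",
    "kcalmol_to_ev",
    "free_energy_ox",
    "oxidation_potential",
    "ensemble_redox",
    "convergence_trace",
]

#: CODATA-consistent conversion, 1 kcal/mol per particle in eV.
KCAL_PER_MOL_TO_EV = 0.0433641


def kcalmol_to_ev(x: float) -> float:
    """Convert an energy from kcal/mol to eV per particle."""
    return x * KCAL_PER_MOL_TO_EV


@dataclass(frozen=True)
class RedoxConstants:
    """Reference constants of the oxidation-potential calculation.

    Attributes
    ----------
    g_electron_kcalmol:
        Free energy of the gas-phase electron, kcal/mol (Fermi-Dirac).
    e_she:
        Absolute reduction potential of the standard hydrogen electrode, V.
    n_e:
        Number of exchanged electrons (1 for one-electron oxidation).
        Energies in eV per single electron map 1:1 to volts, so no explicit
        Faraday factor appears.
    """

    g_electron_kcalmol: float = -0.867
    e_she: float = 4.281
    n_e: int = 1

    def __post_init__(self) -> None:
        if self.n_e < 1 or int(self.n_e) != self.n_e:
            raise ValueError(f"n_e must be a positive integer, got {self.n_e}")

    @property
    def g_electron_ev(self) -> float:
        return kcalmol_to_ev(self.g_electron_kcalmol)


@dataclass(frozen=True)
class RedoxEstimate:
    """Ensemble oxidation potential with its per-frame decomposition."""

    per_frame_e_red: tuple[float, ...]  # V
    mean_e_red: float  # V
    std_e_red: float  # V, sample (n-1) deviation of per-frame potentials
    mean_vie: float  # eV
    mean_vae: float  # eV

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_e_red)


def free_energy_ox(vie: float, vae: float, g_electron_ev: float) -> float:
    """Oxidation free energy at one geometry: (VIE + VAE)/2 + G(e-), eV.

    VAE enters as a positive magnitude (energy released when the cation
    recaptures the electron).
    """
    return 0.5 * (vie + vae) + g_electron_ev


def oxidation_potential(dg_ox: float, consts: RedoxConstants = RedoxConstants()) -> float:
    """Potential vs SHE for an oxidation free energy in eV: dG/n_e - E_SHE."""
    return dg_ox / consts.n_e - consts.e_she


def ensemble_redox(e: StrandEnsemble, consts: RedoxConstants = RedoxConstants()) -> RedoxEstimate:
    """Per-frame oxidation potentials and their ensemble mean/std.

    Because the map from (VIE, VAE) to E_red is affine, averaging the
    per-frame potentials agrees exactly with evaluating the potential at
    the mean energies; the per-frame route is kept because the reported
    standard deviation is defined on per-frame potentials.
    """
    if e.n_frames == 0:
        raise ValueError(f"ensemble {e.strand_id!r} has no frames")
    g = consts.g_electron_ev
    vies = np.array([f.vie for f in e.frames])
    vaes = np.array([f.vae for f in e.frames])
    e_red = np.array([oxidation_potential(free_energy_ox(vi, va, g), consts) for vi, va in zip(vies, vaes)])
    std = float(np.std(e_red, ddof=1)) if len(e_red) > 1 else 0.0
    return RedoxEstimate(
        per_frame_e_red=tuple(float(x) for x in e_red),
        mean_e_red=float(np.mean(e_red)),
        std_e_red=std,
        mean_vie=float(np.mean(vies)),
        mean_vae=float(np.mean(vaes)),
    )


def convergence_trace(values) -> np.ndarray:
    """Running means m_k = mean(values[:k]) for k = 1..N.

    Plotting this against k shows whether an ensemble property has
    converged with the number of snapshots; for an i.i.d. sample the trace
    settles at the rate 1/sqrt(N).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("convergence trace needs at least one value")
    return np.cumsum(values) / np.arange(1, values.size + 1)
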
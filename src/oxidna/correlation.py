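"""Structure-delocalization correlation classification.

For every unordered pair of the six base-step parameters the procedure
asks whether the conformations hosting a strongly shared hole line up
along a direction in that 2-D conformational plane:

1. **Scatter** — one point per (frame, step): the step's two parameter
   values, tagged with the pairwise delocalization number n of the two
   flanking bases.  The plane is windowed to mean +/- 2.5 sigma on each
   axis (sigma over the whole ensemble); the window covers the whole
   conformational space where delocalization occurs.
2. **Grid reduction** — a 20 x 20 grid spans the window; in each occupied
   cell only the point with the largest n survives.  This keeps the
   envelope of maximal delocalization over conformational space.
3. **Regime filter** — ``high`` keeps grid points with n > 1.7 (strongly
   shared hole), ``low`` keeps n < 1.1 (essentially localized), ``all``
   regresses the full windowed scatter instead of the grid maxima.
4. **Regression and classification** — ordinary least squares y ~ x; the
   slope is normalized by sigma_x / sigma_y so that the window diagonal
   from (-2.5s, -2.5s) to (+2.5s, +2.5s) has normalized slope exactly 1.
   A pair is labeled ``positive``/``negative`` when arctan(s_norm) falls
   in [20 deg, 70 deg] / [-70 deg, -20 deg] — an angular window centered
   on the +/-45 deg diagonals that treats a slope and its inverse
   symmetrically — and ``none`` otherwise.  Classification additionally
   requires at least ``min_points`` points and r^2 >= ``min_r2`` so that a
   sparse or structureless cloud is never labeled as correlated.

Assembling all 15 pairs gives a symmetric 6 x 6 matrix per strand and
regime; counting labels across strands reproduces "k out of N strands"
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .delocalization import DegenerateProfileError, charge_differences, pair_deloc
from .ensemble import STEP_PARAMETER_NAMES, StrandEnsemble

__all__ = [
    "HIGH_N_THRESHOLD",
    "LOW_N_THRESHOLD",
    "ScatterSet",
    "GridSummary",
    "CorrelationCell",
    "CorrelationMatrix",
    "DegenerateWindowError",
    "build_scatter",
    "grid_reduce",
    "regime_filter",
    "regress_classify",
    "correlation_matrix",
    "cross_strand_counts",
]

HIGH_N_THRESHOLD = 1.7  # pairwise n above which the hole counts as shared
LOW_N_THRESHOLD = 1.1  # pairwise n below which delocalization is negligible
SIGMA_WINDOW = 2.5  # half-width of the conformational window, in sigmas
GRID_SIZE = 20

ANGLE_MIN_DEG = 20.0
ANGLE_MAX_DEG = 70.0


class DegenerateWindowError(ValueError):
    """A parameter has zero variance; the sigma window is undefined."""


@dataclass(frozen=True)
class ScatterSet:
    """Windowed (x, y, n_pair) scatter for one parameter pair."""

    x_name: str
    y_name: str
    points: np.ndarray  # shape (k, 3): x, y, n_pair, in frame order
    x_mean: float
    x_sigma: float
    y_mean: float
    y_sigma: float

    @property
    def x_limits(self) -> tuple[float, float]:
        return (self.x_mean - SIGMA_WINDOW * self.x_sigma, self.x_mean + SIGMA_WINDOW * self.x_sigma)

    @property
    def y_limits(self) -> tuple[float, float]:
        return (self.y_mean - SIGMA_WINDOW * self.y_sigma, self.y_mean + SIGMA_WINDOW * self.y_sigma)


@dataclass(frozen=True)
class GridSummary:
    """Per-cell maximum-n points of a scatter on the 20 x 20 grid."""

    scatter: ScatterSet
    points: np.ndarray  # (<=400, 3) retained points, one per occupied cell


@dataclass(frozen=True)
class CorrelationCell:
    """Classification of one parameter pair in one regime."""

    x_name: str
    y_name: str
    regime: str
    n_points: int
    slope: float
    s_norm: float
    r2: float
    label: str  # positive | negative | none | not-evaluable


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric 6 x 6 classification over all parameter pairs."""

    strand_id: str
    regime: str
    cells: dict[tuple[str, str], CorrelationCell]

    def cell(self, a: str, b: str) -> CorrelationCell:
        """Look up a pair in either order (the matrix is symmetric)."""
        key = tuple(sorted((a, b), key=STEP_PARAMETER_NAMES.index))
        return self.cells[key]  # type: ignore[index]

    def label(self, a: str, b: str) -> str:
        return self.cell(a, b).label


def build_scatter(
    e: StrandEnsemble,
    x_name: str,
    y_name: str,
    clamp: bool = True,
) -> ScatterSet:
    """Collect the (x, y, n_pair) scatter of one parameter pair.

    One point per (frame, step); the pairwise delocalization number comes
    from the clamped charge differences of the two bases flanking that
    step.  Window statistics are taken over all points; points outside
    mean +/- 2.5 sigma on either axis are excluded.  Frames without a hole
    in the QM region are skipped.
    """
    for name in (x_name, y_name):
        if name not in STEP_PARAMETER_NAMES:
            raise ValueError(f"unknown step parameter {name!r}")
    if x_name == y_name:
        raise ValueError("x_name and y_name must differ")
    rows = []
    for f in e.frames:
        try:
            dq = charge_differences(f, clamp=clamp).dq
        except DegenerateProfileError:
            continue
        for s in f.steps:
            n_pair = pair_deloc(dq[s.step_index - 1], dq[s.step_index])
            rows.append((getattr(s, x_name), getattr(s, y_name), n_pair))
    pts = np.array(rows, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise DegenerateWindowError(f"{e.strand_id}: no usable points for ({x_name}, {y_name})")
    x_mean, y_mean = pts[:, 0].mean(), pts[:, 1].mean()
    x_sigma, y_sigma = pts[:, 0].std(ddof=0), pts[:, 1].std(ddof=0)
    if x_sigma == 0.0 or y_sigma == 0.0:
        raise DegenerateWindowError(
            f"{e.strand_id}: zero variance in {x_name if x_sigma == 0 else y_name}"
        )
    keep = (
        (np.abs(pts[:, 0] - x_mean) <= SIGMA_WINDOW * x_sigma)
        & (np.abs(pts[:, 1] - y_mean) <= SIGMA_WINDOW * y_sigma)
    )
    return ScatterSet(
        x_name=x_name,
        y_name=y_name,
        points=pts[keep],
        x_mean=float(x_mean),
        x_sigma=float(x_sigma),
        y_mean=float(y_mean),
        y_sigma=float(y_sigma),
    )


def grid_reduce(s: ScatterSet, nx: int = GRID_SIZE, ny: int = GRID_SIZE) -> GridSummary:
    """Keep, per occupied grid cell, the point with the largest n_pair.

    The grid spans exactly the +/- 2.5 sigma window on each axis.  Ties
    within a cell are broken by first occurrence in frame order, so the
    reduction is deterministic for a fixed input.
    """
    (x_lo, x_hi), (y_lo, y_hi) = s.x_limits, s.y_limits
    pts = s.points
    inside = (
        (pts[:, 0] >= x_lo) & (pts[:, 0] <= x_hi) & (pts[:, 1] >= y_lo) & (pts[:, 1] <= y_hi)
    )
    pts = pts[inside]
    if pts.shape[0] == 0:
        return GridSummary(scatter=s, points=pts.copy())
    # the exact upper edge belongs to the last cell
    ix = np.minimum(((pts[:, 0] - x_lo) / (x_hi - x_lo) * nx).astype(int), nx - 1)
    iy = np.minimum(((pts[:, 1] - y_lo) / (y_hi - y_lo) * ny).astype(int), ny - 1)
    best: dict[tuple[int, int], int] = {}
    for k, (cx, cy) in enumerate(zip(ix, iy)):
        key = (int(cx), int(cy))
        if key not in best or pts[k, 2] > pts[best[key], 2]:
            best[key] = k
    keep = sorted(best.values())
    return GridSummary(scatter=s, points=pts[keep])


def regime_filter(g: GridSummary, regime: str) -> np.ndarray:
    """Points entering the regression for a delocalization regime.

    ``high``: grid-max points with n > 1.7.  ``low``: grid-max points with
    n < 1.1.  ``all``: the full windowed scatter, regardless of n (the
    grid reduction is bypassed for this complementary view).
    """
    if regime == "high":
        return g.points[g.points[:, 2] > HIGH_N_THRESHOLD]
    if regime == "low":
        return g.points[g.points[:, 2] < LOW_N_THRESHOLD]
    if regime == "all":
        return g.scatter.points
    raise ValueError(f"unknown regime {regime!r}")


def regress_classify(
    points: np.ndarray,
    x_sigma: float,
    y_sigma: float,
    min_points: int = 10,
    min_r2: float = 0.2,
    x_name: str = "x",
    y_name: str = "y",
    regime: str = "high",
) -> CorrelationCell:
    """OLS fit of y on x with slope normalization and 3-way labeling.

    The normalized slope s_norm = slope * sigma_x / sigma_y equals +1 for
    points on the window diagonal and -1 on the anti-diagonal, independent
    of the parameter units.  The label is ``positive`` when arctan(s_norm)
    lies in [20 deg, 70 deg], ``negative`` for the mirrored window, and
    ``none`` otherwise or when the evidence gate (point count, r^2) fails.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3) if np.ndim(points) > 1 else np.empty((0, 3))
    n_pts = pts.shape[0]
    if n_pts < 2 or np.ptp(pts[:, 0]) == 0.0:
        return CorrelationCell(x_name, y_name, regime, n_pts, math.nan, math.nan, math.nan, "none")
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2)
    s_norm = slope * x_sigma / y_sigma
    label = "none"
    if n_pts >= min_points and r2 >= min_r2:
        angle = math.degrees(math.atan(s_norm))
        if ANGLE_MIN_DEG <= angle <= ANGLE_MAX_DEG:
            label = "positive"
        elif -ANGLE_MAX_DEG <= angle <= -ANGLE_MIN_DEG:
            label = "negative"
    return CorrelationCell(x_name, y_name, regime, n_pts, slope, float(s_norm), r2, label)


def correlation_matrix(
    e: StrandEnsemble,
    regime: str = "high",
    min_points: int = 10,
    min_r2: float = 0.2,
    clamp: bool = True,
) -> CorrelationMatrix:
    """Run the full classification chain over all 15 parameter pairs."""
    cells: dict[tuple[str, str], CorrelationCell] = {}
    names = STEP_PARAMETER_NAMES
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                scatter = build_scatter(e, a, b, clamp=clamp)
            except DegenerateWindowError:
                cells[(a, b)] = CorrelationCell(a, b, regime, 0, math.nan, math.nan, math.nan, "not-evaluable")
                continue
            grid = grid_reduce(scatter)
            pts = regime_filter(grid, regime)
            cells[(a, b)] = regress_classify(
                pts,
                scatter.x_sigma,
                scatter.y_sigma,
                min_points=min_points,
                min_r2=min_r2,
                x_name=a,
                y_name=b,
                regime=regime,
            )
    return CorrelationMatrix(strand_id=e.strand_id, regime=regime, cells=cells)


def cross_strand_counts(matrices: list[CorrelationMatrix]) -> "pd.DataFrame":
    """Count strands per parameter pair carrying each correlation label.

    Reproduces summaries of the form "twist/shift positively correlated in
    9 out of 10 strands".
    """
    import pandas as pd

    if not matrices:
        raise ValueError("need at least one correlation matrix")
    rows = []
    names = STEP_PARAMETER_NAMES
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            labels = [m.label(a, b) for m in matrices]
            rows.append(
                (
                    a,
                    b,
                    sum(l == "positive" for l in labels),
                    sum(l == "negative" for l in labels),
                    sum(l == "none" for l in labels),
                    len(labels),
                )
            )
    return pd.DataFrame(rows, columns=["x_name", "y_name", "positive", "negative", "none", "n_strands"])
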
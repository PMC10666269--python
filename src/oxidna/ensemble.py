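"""Data model and tabular I/O for oxidized single-strand ensembles.

The unit of every analysis in this package is the :class:`StrandEnsemble`:
one single-stranded DNA sequence (the inner quantum region of a layered
calculation, 3-4 nucleobases) together with an ordered set of per-snapshot
:class:`Frame` records.  Each frame carries

* per-nucleobase partial charges for the neutral and cationic state (e),
* the vertical ionization energy (VIE) and vertical attachment energy
  (VAE) of the strand at that geometry (eV), and
* the six rigid-body base-step parameters (shift, slide, rise in A;
  tilt, roll, twist in degrees) for each of the m-1 adjacent-base steps.

Two plain-text serializations are supported: a TSV pair (a "frames" table
of per-base rows plus a "steps" table of per-step rows) and a single JSON
object per strand.  Charges are stored per electronic state rather than as
differences, so the hole-charge closure check can be re-run under any
tolerance downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "NucleobaseRecord",
    "StepParameters",
    "Frame",
    "StrandEnsemble",
    "SchemaError",
    "StructuralError",
    "read_ensemble",
    "write_ensemble",
    "validate_ensemble",
]

VALID_BASES = frozenset("ACGT")

STEP_PARAMETER_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

FRAMES_COLUMNS = ["frame_id", "base_index", "base", "q_neutral", "q_cation", "vie_ev", "vae_ev"]
STEPS_COLUMNS = ["frame_id", "step_index", *STEP_PARAMETER_NAMES]


class SchemaError(ValueError):
    """A file does not conform to the documented table schema."""


class StructuralError(ValueError):
    """An ensemble violates a structural invariant (base/step counts, ids)."""


def _wrap_angle(a: float) -> float:
    """Normalize an angle in degrees to the interval (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class NucleobaseRecord:
    """One nucleobase of the inner QM region with its two-state charges."""

    index: int  # 1-based position within the QM region
    base: str  # one of A, C, G, T
    q_neutral: float  # partial charge in the neutral strand, e
    q_cation: float  # partial charge in the cationic strand, e

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise StructuralError(f"unknown base letter {self.base!r}")
        if self.index < 1:
            raise StructuralError(f"base index must be 1-based, got {self.index}")

    @property
    def dq(self) -> float:
        """Hole charge hosted by this base: cation minus neutral, e."""
        return self.q_cation - self.q_neutral


@dataclass(frozen=True)
class StepParameters:
    """Six rigid-body parameters of one adjacent-base step.

    Translations (shift, slide, rise) are in angstroms along the mid-step
    x, y, z axes; rotations (tilt, roll, twist) are in degrees about the
    same axes, stored in (-180, 180].
    """

    step_index: int  # 1-based index of the (i, i+1) step
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def __post_init__(self) -> None:
        for name in STEP_PARAMETER_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise StructuralError(f"non-finite {name} in step {self.step_index}")
        for name in ("tilt", "roll", "twist"):
            object.__setattr__(self, name, _wrap_angle(getattr(self, name)))

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


@dataclass(frozen=True)
class Frame:
    """One snapshot: charges, vertical energies, and step geometry."""

    frame_id: int
    bases: tuple[NucleobaseRecord, ...]
    vie: float  # vertical ionization energy, eV
    vae: float  # vertical attachment energy, eV
    steps: tuple[StepParameters, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", tuple(self.bases))
        object.__setattr__(self, "steps", tuple(self.steps))
        m = len(self.bases)
        if m < 2:
            raise StructuralError(f"frame {self.frame_id}: needs >= 2 bases, got {m}")
        if [b.index for b in self.bases] != list(range(1, m + 1)):
            raise StructuralError(f"frame {self.frame_id}: base indices must be 1..{m} in order")
        if len(self.steps) != m - 1:
            raise StructuralError(
                f"frame {self.frame_id}: {m} bases require {m - 1} steps, got {len(self.steps)}"
            )
        if [s.step_index for s in self.steps] != list(range(1, m)):
            raise StructuralError(f"frame {self.frame_id}: step indices must be 1..{m - 1} in order")

    @property
    def m(self) -> int:
        return len(self.bases)

    @property
    def sequence(self) -> str:
        return "".join(b.base for b in self.bases)

    def dq_total(self) -> float:
        """Total hole charge hosted by the QM region, e."""
        return sum(b.dq for b in self.bases)


@dataclass
class StrandEnsemble:
    """One strand's sequence plus its ordered ensemble of frames."""

    strand_id: str
    sequence: str
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c not in VALID_BASES for c in self.sequence):
            raise StructuralError(f"sequence {self.sequence!r} contains non-ACGT letters")
        seen: set[int] = set()
        for f in self.frames:
            if f.sequence != self.sequence:
                raise StructuralError(
                    f"frame {f.frame_id}: sequence {f.sequence} differs from strand "
                    f"sequence {self.sequence}"
                )
            if f.frame_id in seen:
                raise StructuralError(f"duplicate frame_id {f.frame_id}")
            seen.add(f.frame_id)

    @property
    def m(self) -> int:
        return len(self.sequence)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# serialization


def _frames_tables(e: StrandEnsemble) -> tuple[pd.DataFrame, pd.DataFrame]:
    base_rows = []
    step_rows = []
    for f in e.frames:
        for b in f.bases:
            base_rows.append((f.frame_id, b.index, b.base, b.q_neutral, b.q_cation, f.vie, f.vae))
        for s in f.steps:
            step_rows.append((f.frame_id, s.step_index, *s.as_tuple()))
    frames_df = pd.DataFrame(base_rows, columns=FRAMES_COLUMNS)
    steps_df = pd.DataFrame(step_rows, columns=STEPS_COLUMNS)
    return frames_df, steps_df


def _paths_for(path: Path, schema: str) -> tuple[Path, Path]:
    """Map a base path to the (frames, steps) TSV pair."""
    stem = path.name
    for suffix in (".frames.tsv", ".steps.tsv", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.parent / f"{stem}.frames.tsv", path.parent / f"{stem}.steps.tsv"


def write_ensemble(e: StrandEnsemble, path: str | Path, schema: Literal["tsv", "json"] = "tsv") -> None:
    """Write an ensemble to disk; re-readable by :func:`read_ensemble`.

    For ``schema="tsv"`` two files are produced, ``<stem>.frames.tsv`` and
    ``<stem>.steps.tsv``; ``path`` may name either of them or the bare stem.
    Floats are written with 12 significant digits so a read/write round trip
    is the identity to well below any physically meaningful precision.
    """
    path = Path(path)
    if schema == "tsv":
        frames_path, steps_path = _paths_for(path, schema)
        frames_df, steps_df = _frames_tables(e)
        frames_df.to_csv(frames_path, sep="\t", index=False, float_format="%.12g")
        steps_df.to_csv(steps_path, sep="\t", index=False, float_format="%.12g")
    elif schema == "json":
        obj = {
            "strand_id": e.strand_id,
            "sequence": e.sequence,
            "frames": [
                {
                    "frame_id": f.frame_id,
                    "vie_ev": f.vie,
                    "vae_ev": f.vae,
                    "bases": [
                        {
                            "index": b.index,
                            "base": b.base,
                            "q_neutral": b.q_neutral,
                            "q_cation": b.q_cation,
                        }
                        for b in f.bases
                    ],
                    "steps": [
                        {"step_index": s.step_index, **dict(zip(STEP_PARAMETER_NAMES, s.as_tuple()))}
                        for s in f.steps
                    ],
                }
                for f in e.frames
            ],
        }
        path.write_text(json.dumps(obj, indent=1))
    else:
        raise ValueError(f"unknown schema {schema!r}")


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric = [c for c in columns if c != "base"]
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            row = int(bad.idxmax()) + 2  # 1-based data line, plus header
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at line {row}") from None
    return df


def read_ensemble(
    path: str | Path,
    schema: Literal["tsv", "json"] = "tsv",
    strand_id: str | None = None,
) -> StrandEnsemble:
    """Read and validate a strand ensemble from the TSV pair or JSON form.

    Row order is preserved; every structural invariant (consistent base
    count, step count m-1, unique frame ids) is enforced on read.
    """
    path = Path(path)
    if schema == "json":
        obj = json.loads(path.read_text())
        frames = [
            Frame(
                frame_id=int(fr["frame_id"]),
                bases=tuple(
                    NucleobaseRecord(int(b["index"]), b["base"], float(b["q_neutral"]), float(b["q_cation"]))
                    for b in fr["bases"]
                ),
                vie=float(fr["vie_ev"]),
                vae=float(fr["vae_ev"]),
                steps=tuple(
                    StepParameters(int(s["step_index"]), *(float(s[k]) for k in STEP_PARAMETER_NAMES))
                    for s in fr["steps"]
                ),
            )
            for fr in obj["frames"]
        ]
        return StrandEnsemble(obj["strand_id"], obj["sequence"], frames)

    if schema != "tsv":
        raise ValueError(f"unknown schema {schema!r}")

    frames_path, steps_path = _paths_for(path, schema)
    frames_df = _read_tsv(frames_path, FRAMES_COLUMNS)
    steps_df = _read_tsv(steps_path, STEPS_COLUMNS)

    steps_by_frame: dict[int, list[StepParameters]] = {}
    for _, r in steps_df.iterrows():
        steps_by_frame.setdefault(int(r["frame_id"]), []).append(
            StepParameters(int(r["step_index"]), *(float(r[k]) for k in STEP_PARAMETER_NAMES))
        )

    frames: list[Frame] = []
    sequence: str | None = None
    for fid, grp in frames_df.groupby("frame_id", sort=False):
        bases = tuple(
            NucleobaseRecord(int(r["base_index"]), str(r["base"]), float(r["q_neutral"]), float(r["q_cation"]))
            for _, r in grp.iterrows()
        )
        frames.append(
            Frame(
                frame_id=int(fid),
                bases=bases,
                vie=float(grp["vie_ev"].iloc[0]),
                vae=float(grp["vae_ev"].iloc[0]),
                steps=tuple(steps_by_frame.get(int(fid), [])),
            )
        )
        seq = frames[-1].sequence
        if sequence is None:
            sequence = seq
        elif seq != sequence:
            raise StructuralError(f"frame {fid}: sequence {seq} differs from {sequence}")
    if sequence is None:
        raise StructuralError(f"{frames_path}: no frames found")
    if strand_id is None:
        strand_id = frames_path.name.removesuffix(".frames.tsv")
    return StrandEnsemble(strand_id, sequence, frames)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "warning" | "error"
    frame_id: int | None
    message: str


def validate_ensemble(e: StrandEnsemble, tol_charge: float = 0.25) -> list[Diagnostic]:
    """Check physical plausibility of an ensemble; never raises, never mutates.

    The hole-charge closure check flags frames whose total charge difference
    over the QM region deviates from one elementary charge by more than
    ``tol_charge``.  Closure violations are warnings, not errors: charge can
    legitimately leak into the surrounding tight-binding layer of the
    layered calculation that produced the inputs.
    """
    out: list[Diagnostic] = []
    for f in e.frames:
        values = [f.vie, f.vae] + [v for b in f.bases for v in (b.q_neutral, b.q_cation)]
        values += [v for s in f.steps for v in s.as_tuple()]
        if any(not math.isfinite(v) for v in values):
            out.append(Diagnostic("error", f.frame_id, "non-finite value in frame"))
            continue
        closure = f.dq_total()
        if abs(closure - 1.0) > tol_charge:
            out.append(
                Diagnostic(
                    "warning",
                    f.frame_id,
                    f"hole-charge closure |sum dq - 1| = {abs(closure - 1.0):.3f} exceeds {tol_charge}",
                )
            )
        if f.vie < f.vae:
            out.append(Diagnostic("warning", f.frame_id, f"VIE {f.vie:.3f} < VAE {f.vae:.3f}"))
        if f.vie <= 0 or f.vae <= 0:
            out.append(Diagnostic("warning", f.frame_id, "non-positive vertical energy"))
    return out
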
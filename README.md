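# oxidna

Ensemble post-processing of oxidized single-stranded DNA: one-electron
oxidation potentials, hole-delocalization indices, and the grid-based
classification of structure–delocalization correlations.

## The problem

When an ss-DNA strand loses an electron, the resulting hole can hop
between nucleobases (localized on one base at a time) or tunnel through a
coherently shared state. Layered QM/MM simulations produce, per snapshot,
the ingredients to quantify this: vertical ionization and attachment
energies of the strand, two-state (neutral/cation) per-base partial
charges, and the six rigid-body base-step parameters of the backbone
geometry. `oxidna` consumes those per-strand ensemble tables (plain TSV
or JSON — conversion from any MD/QM code's native output is the user's
concern) and computes:

* **Oxidation potential** (linear-response / Marcus):
  `ΔG_ox = (VIE + VAE)/2 + G(e⁻_gas)` per frame, referenced to the
  absolute SHE potential, `E_red = ΔG_ox/n_e − E_SHE`, with
  `G(e⁻_gas) = −0.867 kcal/mol` and `E_SHE = 4.281 V` by default.
* **Delocalization indices** from the per-base hole charges
  `Δq_i = q_cation,i − q_neutral,i`: the intermolecular delocalization
  number `n = Σ_i Δq_(i)/Δq_(max)` (equivalently, the `(m−i+1)`-weighted
  increments of the sorted profile), and the adapted Pipek–Mezey index
  `n′ = 1/Σ p_i²` with `p_i = Δq_i/ΣΔq`. Both run from 1 (localized) to
  m (uniform), with `n′ ≥ n` always.
* **Structure–delocalization correlations**: for each pair of step
  parameters, a ±2.5σ window, a 20×20 grid keeping the maximum pairwise
  delocalization per cell, a regime filter (`n > 1.7` shared /
  `n < 1.1` localized / all points), OLS regression with slope
  normalized by `σ_x/σ_y`, and a positive/negative/none label per pair —
  assembled into symmetric 6×6 matrices per strand and counted across
  strands.
* **Base-step geometry**: an exactly invertible mid-step-frame
  computation of shift/slide/rise/tilt/roll/twist from base triads.
* **Synthetic ensembles**: a seeded generator (Dirichlet hole
  distributions, Gaussian energetics and geometry, optionally with a
  bivariate coupling planted conditional on strong hole sharing) so the
  whole pipeline is testable without trajectory data.

## Worked example

```python
import oxidna as ox
from oxidna.delocalization import ChargeDifferenceProfile, deloc_number
from oxidna.synthetic import GeneratorSpec, gen_ensemble

# oxidation potential of an ensemble with constant vertical energies
e = gen_ensemble(GeneratorSpec("ss-polyG-like", "GTGT", n_frames=10,
                               vie_sd=0.0, vae_sd=0.0, seed=1))
est = ox.ensemble_redox(e)          # VIE = 6.44 eV, VAE = 4.28 eV defaults
print(round(est.mean_e_red, 4))     # 1.0414 V vs SHE

# delocalization of a two-and-two shared hole
p = ChargeDifferenceProfile((0.40, 0.32, 0.16, 0.08), (0.40, 0.32, 0.16, 0.08))
print(deloc_number(p))              # 2.4 — the hole spans ~2.4 of 4 bases
```

`1.0414 V` is `(6.44 + 4.28)/2 − 0.0376 − 4.281`: the frame free energy,
the gas-phase electron correction in eV, and the SHE reference. `2.4`
says the profile's charge, measured relative to its largest entry,
amounts to 2.4 bases' worth of hosting.

The `examples/` directory has one short script per capability
(`oxidation_potential.py`, `delocalization_indices.py`,
`step_geometry.py`, `structure_correlation.py`, `synthetic_study.py`);
each builds its own input, runs the method and explains what it prints.
A thin CLI mirrors the main stages (`oxidna simulate | redox | deloc |
correlate`) for shell-driven use on the TSV tables.

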
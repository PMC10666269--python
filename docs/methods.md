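# Methods

## Scope and data model

`oxidna` post-processes ensembles of oxidized single-stranded DNA
snapshots. It does not run molecular dynamics or electronic structure;
its inputs are the tables such protocols produce per strand: for each of
~200 snapshots, two-state per-base partial charges (e), the vertical
ionization energy VIE and vertical attachment energy VAE (eV), and the
six base-step parameters of each adjacent-base step (Å, degrees). The
inner quantum region holds m = 3–4 nucleobases; every frame of a strand
shares the same sequence, carries exactly m−1 steps, and step angles are
normalized to (−180°, 180°] at read time so a single convention reaches
the regression stage.

Charges are stored per state, not as differences, so the hole-charge
closure check (|Σ Δq − 1| ≤ tol, default tol = 0.25 e) can be re-run at
any tolerance. Closure violations are warnings, not errors: in a layered
QM1/QM2 calculation part of the hole legitimately relaxes into the outer
region, and no quantitative leakage figure is available to pin the
default more tightly — 0.25 e is a declared choice.

## Oxidation potential

Linear response gives the oxidation free energy at a fixed solvated
geometry as the mean of the two vertical energies,
ΔG_ox = (VIE + VAE)/2 + G(e⁻_gas), with G(e⁻_gas) = −0.867 kcal/mol
(Fermi–Dirac statistics of the gas-phase electron) converted once via
1 kcal/mol = 0.0433641 eV. The potential follows as
E_red = ΔG_ox/n_e − E_SHE with the absolute SHE reference 4.281 V;
energies in eV per electron map one-to-one to volts, so no explicit
Faraday factor appears. VAE is entered as a positive magnitude.

Two conventions were genuinely open and are pinned here:

* **Electron correction once.** The SHE reference value in the
  literature itself embeds an electron-gas correction, which can be read
  as requiring the correction in both places or in one. We apply
  G(e⁻_gas) exactly once, in ΔG_ox, and use 4.281 V as published. The
  alternative differs by 0.038 V, below the thermal spread of any
  realistic ensemble, and the pinned form reproduces the 1.0–1.5 V range
  of guanine-bearing strands.
* **Average of potentials, not potential of averages.** E_red is
  computed per frame and then averaged. For this affine map the two
  orders agree exactly for the mean; the reported standard deviation is
  defined on the per-frame potentials, with the (n−1) sample normalizer
  because the ensemble samples a phase space.

`convergence_trace` returns the running mean over frames for the
standard convergence check; for i.i.d. snapshots it tightens as 1/√N.

## Delocalization indices

With Δq_i = q_cation,i − q_neutral,i over the m bases, sorted
increasingly and scaled by the largest value (r_i = Δq_(i)/Δq_(m),
r_0 = 0), the intermolecular delocalization number is

    n = Σ_{i=1..m} (m − i + 1)(r_i − r_{i−1}),

read as: each increment of relative charge is credited to the
(m − i + 1) bases that hold at least that much. The sum telescopes to
Σ_i Δq_(i)/Δq_(m); both forms are implemented and cross-asserted at
every call. n = 1 for a fully localized hole, n = m for a uniform one,
and the two-and-two profile (0.40, 0.32, 0.16, 0.08) gives n = 2.4.

The adapted Pipek–Mezey index applies the inverse participation ratio to
the normalized fractions p_i = Δq_i/ΣΔq: n′ = 1/Σ p_i². Since
Σq·q_max ≥ Σq², n′ ≥ n for every nonnegative profile, with equality iff
all nonzero Δq are equal; the property suite asserts this, along with
scale and permutation invariance of both indices.

Negative Δq (back-polarization) is clamped to zero by default before
index computation — both indices need nonnegative populations — and the
raw values are preserved for audit. A frame with no positive Δq has no
hole in the region and is skipped with a count, not an error.

For pairs of adjacent bases the pairwise number
n_pair = 1 + min(Δq_a, Δq_b)/max(Δq_a, Δq_b) ∈ [1, 2] is used; a pair
hosting no charge returns 1 by convention (no shared hole). The pairwise
form is chosen over a rescaled four-base index because the regime
thresholds 1.7 and 1.1 used downstream sit meaningfully inside [1, 2].

Charge-fraction summaries average per-frame percentages either by strand
position or by rank within base type (largest first); the rank view is
the right one when the dominant base alternates between equivalent
copies across snapshots.

## Base-step geometry

Each base carries an orthonormal right-handed triad. The step from triad
T₁ to T₂ is parameterized by the rotation vector v of R = T₂T₁ᵀ:
tilt/roll/twist are the components of v on the mid-frame axes (the
mid-frame is T₁ rotated halfway along v; because a rotation fixes its
own axis these components equal those on either end triad), and
shift/slide/rise are the components of the origin displacement on the
mid-frame axes. This mid-frame convention is exactly invertible
(`build_step`), reversing a step negates all six parameters, and
composing k identical twist-only steps accumulates k·twist. Parameter
sets are unique as long as the total rotation angle stays below 180°,
far beyond any physical step. Exact conventions differ slightly between
the established helical-analysis packages; any self-consistent choice
serves the correlation analysis, and the one used is recorded in the
module metadata (`midframe-rotation-vector`). Base triads are taken as
given — fitting them from atomic coordinates is out of scope.

## Correlation classification

For each of the 15 unordered step-parameter pairs:

1. one point (x, y, n_pair) per frame and step; window statistics (mean,
   population σ) over all points; points outside ±2.5σ on either axis
   are discarded. 2.5σ is generous enough to cover the conformational
   space where delocalization occurs while bounding the grid.
2. a 20×20 grid spans exactly the window; per occupied cell only the
   point with the largest n_pair survives (ties broken by frame order
   for determinism). This extracts the envelope of maximal
   delocalization over conformational space.
3. regimes: `high` keeps grid points with n_pair > 1.7, `low` keeps
   n_pair < 1.1, `all` regresses the full windowed scatter (not the grid
   maxima) as a complementary view.
4. OLS of y on x; the slope is normalized by σ_x/σ_y so the window
   diagonal has slope exactly +1 and the anti-diagonal −1, making the
   label invariant under unit changes. "Near ±1 versus near 0 or ∞" is
   made operational as an angular window: positive if
   arctan(s_norm) ∈ [20°, 70°], negative if ∈ [−70°, −20°], else none —
   symmetric in slope and inverse slope, centered on ±45°.

A minimum-evidence gate (≥10 points and r² ≥ 0.2, both configurable)
forces `none` otherwise; without it a two-point regression would label
noise. The gate is a design choice of this implementation. The grid-max
points (not re-included raw points) are what the high/low regressions
see. Pairs with a zero-variance axis are marked not-evaluable.
Per-strand matrices are symmetric by construction; cross-strand counts
of positive/negative labels per pair reproduce "k out of N strands"
summaries.

## Synthetic ensembles

The generator emulates the statistical shape of the trajectory tables,
not their physics:

* **Hole distribution**: Δq is Dirichlet-distributed — nonnegative,
  summing to one, with the concentration vector setting both the mean
  split and its frame-to-frame variability. Sequence presets encode the
  observed phenomenology: with guanine present, ~75% of the hole sits on
  one G (concentrations ≈ 12·(0.73, 0.07–0.11 others)); adenine-led
  strands localize less; pyrimidine-only strands share the hole nearly
  evenly with a mild 5′ preference, reproducing the even two-and-two
  split and n ≈ 2.4 of alternating C/T. Neutral-state charges get
  zero-mean Gaussian noise (σ = 0.05 e) and q_cation = q_neutral + Δq.
  2% of frames push the smallest Δq slightly negative to exercise the
  clamp path.
* **Energetics**: independent Gaussians, defaults VIE 6.44 ± 0.25 eV,
  VAE 4.28 ± 0.25 eV. The means are the constant-energy worked-example
  values; the spreads are a declared choice, sized so the potential's
  ensemble std comes out at ~0.15–0.2 V, the typical thermal spread of
  such ensembles.
* **Geometry**: independent Gaussians with B-form-like defaults (rise
  3.4 ± 0.4 Å, twist 30 ± 12°, shift/slide 0 ± 0.8 Å, tilt/roll 0 ± 8°).
  A `PlantSpec` draws one pair from a bivariate Gaussian with
  correlation ρ on steps whose realized n_pair satisfies a condition
  (default: > 1.7), mirroring couplings that strengthen in the
  high-delocalization regime.
* **Determinism**: every frame has its own substream keyed by
  (strand seed, frame id), so ensembles are bit-reproducible and
  independent of generation order; studies emit a manifest sufficient to
  regenerate them exactly.

What the generator does **not** emulate: temporal autocorrelation along
a trajectory, anharmonic or multimodal conformational distributions,
coupling between geometry and energetics, and sequence-dependent
geometry. Passing recovery tests therefore demonstrates that the
analysis chain detects the statistical structure it is designed for —
not that real trajectories contain that structure.

## Validation studies and problem sizes

The recovery studies use 10 strands × 200 frames × 4 bases (3 steps),
matching the emulated protocol's ensemble size: couplings of ρ = ±0.85
planted in 9 (twist–shift) or 8 (rise–tilt) strands under a balanced
Dirichlet (concentration 6 per base, ~40% of steps above the 1.7
threshold) are recovered as exactly those label counts, with the
unplanted strands labeled none. Property suites run on profiles up to
m = 6, point sets up to 10⁴, and 400-step helices. The full test suite
and the acceptance script each complete in well under a minute on one
CPU.

## Known limitations

* Delocalization measures vary in convention across the
  population-analysis literature (participation ratios, entropic
  measures, threshold counts). The two implemented here are fully
  characterized by their closed forms and invariants above; when
  comparing numbers across tools, confirm the convention first.
* The geometry module assumes base triads are supplied; no PDB fitting,
  and no intra-base-pair, axis, groove or backbone parameters.
* The evidence gate (10 points, r² ≥ 0.2) and the angular label window
  ([20°, 70°]) are declared operationalizations of qualitative rules;
  conclusions near those boundaries deserve a sensitivity check.
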
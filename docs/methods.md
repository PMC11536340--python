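# Methods

This note documents the models and procedures implemented in `enzloop`, the
assumptions behind them, the defaults that matter, and what the synthetic
generators do and do not emulate.

## Loop free-energy landscapes

**Featurization.** Each frame is described by the pairwise distances between
the heavy atoms of the flexible loop (residues 39–47) and a reference atom
set on the rest of the protein. The default reference is one Cα per non-loop
residue; a full heavy-atom reference can be selected by expression. The
reduced set keeps the feature count linear in protein size while retaining
the loop-versus-scaffold geometry that distinguishes open from closed
conformations; internal distances are invariant under rigid-body motion, so
no trajectory alignment is needed.

**PCA.** Features are centered and z-scored by default (distance columns
have heterogeneous variances; z-scoring prevents a few long-range pairs from
dominating), with a raw-covariance mode by flag. Columns whose standard
deviation is below a relative floor of 1e-10 are dropped with a logged
warning — a numerically constant column would otherwise explode under
z-scoring. The decomposition uses an exact covariance eigendecomposition
(two components), and each component's sign is fixed so that its
largest-magnitude loading is positive, making projections deterministic
across runs. When several replicas are supplied they are pooled into one
projection and one surface; per-replica surfaces can be produced by fitting
replicas separately.

**Free-energy surface.** The 2-D projection is histogrammed on a 60×60 grid
spanning the data range padded by 5% per side, and converted via
ΔG(bin) = −kT·ln(count/count_max) with kT = 0.0019872 kcal·mol⁻¹·K⁻¹ × T
(default 300 K). The most populated bin therefore sits at exactly 0;
unsampled bins carry NaN, never 0, so emptiness is distinguishable from
maximal stability.

**Minima and states.** A literal "occupied bin lower than all occupied
neighbours" rule admits every isolated outlier bin as a minimum. Minima are
instead found by topographic persistence: the grid is flooded from low to
high ΔG (unsampled bins enter at a ceiling just above the highest occupied
value, so disconnected patches still merge), and a basin survives only if
its depth below its merge saddle is at least `min_prominence` (default
1.0 kcal/mol, i.e. a barrier of ~1.7 kT at 300 K — a reasonable floor for
calling a basin metastable). The global minimum always survives. An optional
Gaussian smoothing (σ in bins) applies to minima detection only; the
reported grid is always the raw histogram. Frames are assigned to the
nearest minimum in PC space (`nearest_minimum`), or by seeded 2-means
clustering (`two_means`); populations carry a bootstrap-over-frames standard
error.

**Degenerate inputs.** A single occupied bin yields one 0-kcal/mol minimum;
a zero-width data range is padded to a finite bin span; ties between equal
bins collapse to one minimum (zero persistence).

## Near-attack pose filtering

A frame is a competent pro-S pose when d(epoxide O1, Tyr OH) < 4 Å,
d(azide N3, C1) < 4 Å and the N2–N3–C1 angle lies in [80°, 120°]; pro-R is
the same test at C2. Distance comparisons are strict (<); angle bounds are
inclusive. The terminal azide nitrogen N3 is the attacking atom, with N2
defining the azide axis; the Tyr criterion uses the hydroxyl oxygen. All of
these mappings are configurable per role. The quantum-chemistry-anchored
reference geometries — 2.2 Å / 109° at the transition state, 3.2 Å / 85° in
the reactant complex — are stored as documentation constants and both
classify as competent, as they must. A frame may satisfy both channels and
is then counted in both by default; an exclusive mode assigns it to the
nearer carbon. Fractions are reported over all frames with percentile
bootstrap 95% intervals (seeded, default 1000 resamples).

## Selectivity arithmetic

The kinetic-resolution selectivity factor is computed in the Chen
product-ee form E = ln[1 − c(1 + ee_P)] / ln[1 − c(1 − ee_P)], on |ee| (the
ee sign carries the enantiomer direction; E is the preference magnitude).
This form reproduces the bundled characterization table's heptene-oxide
entries to their printed precision, which is why it was adopted; the
non-wild-type styrene rows deviate by slightly more than their printed
spreads, consistent with per-replicate averaging on unrounded data upstream
of the table. E = 1 exactly at ee = 0; the computation refuses the region
c(1 + |ee|) ≥ 1 (mass balance violated) and flags results beyond 0.95 as
near-singular. For achiral (meso) substrates such as cyclohexene oxide,
product chirality is set by the regioselectivity of the attack, so an E
value is undefined and the API refuses with an explanatory error.

The ΔΔG‡ ↔ ee bridge uses ee = (r − 1)/(r + 1), r = exp(ΔΔG‡/RT), with
R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹ — the same constant as the free-energy
surfaces, keeping the two conversions mutually consistent. External tables
use percent columns with explicit `_pct` headers; all internal computation
is fractional, with exact ×/÷ 100 converters.

## Hill kinetics

v(S) = k_obs,max·Sⁿ/(K₅₀ⁿ + Sⁿ) is fitted by unweighted least squares on
rates by default; a relative (1/v) loss — the estimator matched to a
multiplicative error model — is available by flag. Initialization places
K₅₀ at the concentration nearest half the maximal observed rate, k_obs,max
at 1.1× the maximal rate and n at 2, plus 10 seeded log-normal restarts to
guard against local minima. Standard errors come from the Jacobian
curvature at the optimum (labelled as fit SEs, not replicate SDs); the
convergence flag is propagated from the optimizer, and the efficiency
k_obs,max/K₅₀ is reported alongside. Fitting requires at least four
distinct concentrations; a start with K₅₀ outside the sampled range
triggers a span warning. The standard concentration grids are bundled: 16
epoxide levels (5–150 mM at 60 mM azide) and 11 azide levels (1–100 mM at
100 mM epoxide).

## Synthetic generators

All generators are bit-reproducible from their config seed.

* **Loop trajectories** sample each frame's state from Bernoulli(p_open)
  and add isotropic Gaussian noise of `basin_sd` (default 1 Å) to the loop
  atoms of the matching template; scaffold atoms are fixed. The templates
  are synthetic geometric archetypes, not crystallographic coordinates: a
  Cα-ring scaffold, a closed outward loop arc, and an open template that
  displaces the loop toward a pocket point with a bell-shaped weight peaked
  at the residue-45 analogue (default 6 Å at the peak). The ratio
  displacement/basin_sd (default 6) is the cluster separation and is
  reported in the trajectory metadata so downstream tests can control
  difficulty. No force field, solvent or tetramer interface is emulated;
  passing recovery tests demonstrates the pipeline's statistical
  correctness on well-separated two-state data, not MD realism.
* **Pose frames** build an exact epoxide/azide/tyrosine geometry per frame
  (bond lengths 1.47 Å C–C, 1.44 Å C–O, 1.13 Å N–N), drawing the attack
  distance in (2.7, 3.95) Å, the angle in (80.05°, 119.95°) and violations
  at ≥ 4.05 Å or outside (75°, 125°), so no measurement lands on a
  classification boundary. The azide approaches anti to the non-attacked
  carbon (≤ 10° cone), which guarantees the other channel's distance
  criterion fails; each frame is then rigidly rotated and translated at
  random. Labels are therefore exact by construction and every labelled
  frame re-measures to its class.
* **Kinetic datasets** multiply the true Hill curve by (1 + ε),
  ε ~ N(0, noise_cv), per replicate (default two replicates, matching
  duplicate measurements; default cv 2%). Multiplicative noise reflects the
  roughly constant relative error of rate assays across an
  order-of-magnitude rate range.
* **Screening plates** add Gaussian noise to known (conversion, ee) truth
  and clamp to the valid ranges.

## Problem sizes used in the checks

The population-recovery suites use 50,000-frame trajectories at
separation/sd = 6 (ten seeds), 10,000 pose frames for classifier/fraction
checks, and seeds 1–20 for the noisy Hill recovery on the 11-level azide
grid in duplicate. These sizes give binomial/fit uncertainties comfortably
inside the asserted tolerances (e.g. ±0.02 on a 0.70 population at n =
50,000 is ~10 binomial standard errors).

## Known limitations

* The landscape featurization defaults to one Cα analogue per non-loop
  residue; systems whose discriminating contacts involve side chains need
  the heavy-atom reference mode.
* Persistence-based minima detection with the 1 kcal/mol default will merge
  genuinely metastable but shallow (< 1 kcal/mol) basins; lower the
  threshold for finely structured surfaces.
* E-value arithmetic assumes irreversible, uncompeted kinetic resolution;
  it is undefined for meso substrates and unreliable near full conversion.
* The Hill fit reports apparent cooperativity; no mechanistic claim is
  encoded in n.
* Binary trajectory formats, periodic-boundary imaging and topology
  perception are out of scope; inputs are multi-MODEL PDB or XYZ.
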
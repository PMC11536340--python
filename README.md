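# enzloop

Analysis toolkit for halohydrin-dehalogenase (HHDH) loop engineering.

G-type halohydrin dehalogenases ring-open epoxides with small anionic
nucleophiles (azide, cyanide, nitrite, ...). Their flexible N-terminal loop
(residues 39–47, adjacent to the active site) switches between a closed
conformation with the position-45 side chain outside the pocket and an open
conformation with it inside, and this switch governs both activity and which
product enantiomer is formed. `enzloop` implements the computational stages
used to analyse such systems:

* **Loop conformational landscapes** — featurize trajectory frames as pairwise
  distances between the loop's heavy atoms and the rest of the protein,
  project by PCA, and reconstruct a free-energy surface
  ΔG(bin) = −kT·ln(count/count_max) whose persistent minima define the
  closed/open states and their populations.
* **Near-attack pose filtering** — classify frames as catalytically competent
  pro-S (attack at C1) or pro-R (attack at C2) poses using geometric
  criteria: d(epoxide-O, Tyr-OH) < 4 Å, d(azide-N3, carbon) < 4 Å, and an
  N–N–C attack angle within 80–120°.
* **Enantioselectivity arithmetic** — ee = (major − minor)/(major + minor);
  the kinetic-resolution selectivity factor from conversion c and product ee

      E = ln[1 − c(1 + ee_P)] / ln[1 − c(1 − ee_P)]

  and the Boltzmann bridge ee = (e^{ΔΔG‡/RT} − 1)/(e^{ΔΔG‡/RT} + 1) between
  an activation free-energy difference and the intrinsic ee.
* **Hill kinetics** — v(S) = k_obs,max·Sⁿ/(K₅₀ⁿ + Sⁿ) fitted by multi-start
  nonlinear least squares, statsmodels-style
  (`HillModel(data).fit()` → results with estimates, standard errors and a
  `summary()` table).
* **Synthetic ground truth** — seeded generators for two-state loop
  trajectories, competent/noncompetent pose frames, noisy Hill rate tables
  and screening plates, so every stage is testable end to end without MD or
  wet-lab data.

## Worked example

```python
import enzloop as ez

# Selectivity factor of a variant converting 30% of substrate at 61% ee:
print(f"E = {ez.e_value(0.30, 0.61).E:.2f}")          # E = 5.30

# Two-state loop landscape recovered from a synthetic trajectory
traj, labels = ez.gen_loop_trajectory(
    ez.LoopSimConfig(n_frames=20_000, p_open=0.7, seed=3))
print(ez.LoopLandscapeModel(traj).fit(seed=0).summary())
```

```
Loop free-energy landscape
==================================================
frames              20000
feature pairs       720
explained variance  PC1 0.346  PC2 0.018
temperature (K)     300
minima              2
--------------------------------------------------
S0: dG  0.000 kcal/mol at (-9.87, -0.61)  population 0.703 +/- 0.003
S1: dG  0.518 kcal/mol at (+24.31, +0.43)  population 0.297 +/- 0.003
==================================================
```

The deepest basin (S0, ΔG = 0 by construction) is the open state generated
with a 70% population; its recovered population 0.703 agrees with the
generator truth. The minor basin lies 0.52 kcal/mol higher, consistent with
−kT·ln(0.297/0.703) at 300 K.

```python
# Hill fit of a noisy rate table generated from known kinetics
ds = ez.gen_hill_dataset(ez.KineticSimConfig(
    true_params=ez.HillParams(K50=28.0, kmax=31.1, n=3.33),
    noise_cv=0.02, seed=1))
print(ez.fit_hill(ds, seed=0).summary())
```

```
Hill-equation fit
==============================================
observations        32
distinct conc.      16
varied species      epoxide
residual SS         8.0657
converged           True
----------------------------------------------
K_50 (mM)           27.84  +/- 0.25
k_obs,max (1/s)     30.98  +/- 0.16
Hill n (-)          3.331  +/- 0.11
kmax/K50 (1/s/mM)   1.113
==============================================
```

All three parameters are recovered within ~1% of the generating values
(K₅₀ = 28.0 mM, k_obs,max = 31.1 s⁻¹, n = 3.33) at 2% multiplicative noise.

The same stages are available as a CLI (`enzloop simulate-traj`, `fel`,
`poses`, `selectivity`, `fit-hill`, ...); every subcommand writes its TSV
outputs plus a `manifest.json` recording seeds and thresholds, and reruns
with the same config are byte-identical.

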
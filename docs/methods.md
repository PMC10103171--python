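# Methods

## Scope and model

`hdxens` implements a forward-and-inverse workflow linking structural
ensembles to peptide-level HDX-MS data:

1. **Features.** For every frame and exchange-competent residue, two
   integers describe the amide environment: `N_C`, heavy atoms within a
   cutoff of the amide nitrogen, excluding the residues i−w…i+w around
   it, and `N_H`, oxygen acceptors within a cutoff of the amide
   hydrogen, excluding the residue's own atoms. Prolines and the
   chain's first residue carry no exchange-relevant amide and are
   excluded here and everywhere downstream.
2. **Protection factors.** `ln PF_i(w) = Σ_j w_j (β_C N_C(i,j) + β_H
   N_H(i,j))` — the ensemble average is taken in the exponent (over
   ln PF), not over per-frame deuterated fractions. The two conventions
   differ for heterogeneous ensembles; averaging the exponent is the
   convention of the established reweighting tools this package is
   meant to interoperate with, and it is the one the maximum-entropy
   objective is differentiated against.
3. **Kinetics.** EX2 throughout: `D_i(t) = 1 − exp(−k_int,i t /
   PF_i)`. EX1 and mixed regimes are out of scope.
4. **Peptide observable.** The unweighted mean of `D_i(t)` over the
   peptide's exchange-competent residues, skipping its first residue
   (rapid N-terminal back-exchange) and prolines. Predictions are
   compared directly with MaxD-normalized fractions; no extra
   back-exchange factor is applied, because normalizing by the
   maximally deuterated control already cancels a static per-peptide
   loss.
5. **Inverse problem.** Minimize `γ·½Σ(D_pred(w)−D_exp)² +
   Σ w ln(w/w⁰)` on the weight simplex; report `W_app = k_B T
   Σ w ln(w/w⁰)` in kJ/mol as the bias actually applied.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| contact cutoff | 6.5 | Å | published parameterization of the contact model |
| contact exclusion window | ±2 | residues | same source; removes trivial covalent neighbors |
| H-bond cutoff (H…O) | 2.4 | Å | same source; distance-only criterion |
| β_C, β_H | 0.35, 2.0 | — | original calibration on soluble proteins; re-fit with `fit_betas` when warranted |
| pD | 7.4 | — | pH-meter reading 7.0 + 0.4 glass-electrode correction; override per experiment |
| temperature | 298 | K | typical labeling temperature; also used for k_B T in W_app |
| γ grid | 10⁻²…10³, 6 points/decade | — | spans no-bias to data-dominated fits |
| W_app budget | 5 | kJ/mol | conventional overfitting guard for ensemble reweighting |
| subsamples k | 3 | — | standard replicate count for systematic subsampling |
| hybrid-test α | 0.01 | — | 99 % confidence threshold plus Welch confirmation |

Amide hydrogens missing from the input (e.g. crystal-derived frames) are
reconstructed at 1.01 Å from N along the direction opposite the bisector
of the two heavy atoms bonded to N; a flag disables reconstruction.
Waters are excluded from both counts by default (structures are assumed
stripped of solvent) and can be included by flag.

Intrinsic rates use the Bai–Englander poly-DL-alanine reference rates
for exchange into D₂O (log₁₀ reference rates 2.04 acid, 10.36 base,
−1.5 water at 293 K; pK_D 15.05), neighbor-dependent side-chain
correction factors, N-/C-terminal factors, and Arrhenius corrections
with activation energies 14/17/19 kcal/mol. Asp and Glu are treated as
charged and His as neutral, appropriate near the default pD 7.4;
titration of those side chains is not modelled. Rates from any external
calculator can be substituted via `load_rates_csv`, which bypasses the
internal tables entirely.

## Numerical choices

* **Optimizer.** Weights are parameterized as `w = w⁰ exp(a)/Z`
  (softmax over log-shifts), which enforces the simplex exactly, and
  minimized by L-BFGS with an analytic gradient
  (`∂G/∂a_j = w_j(g_j − ⟨g⟩_w)`). Tolerances: ftol 1e-15, gradient
  tolerance 1e-10, iteration/evaluation cap 10⁵. `γ = 0`
  short-circuits to the prior exactly. A run that exhausts the cap
  with a gradient above 1e-6 raises a convergence error carrying the
  optimizer trace.
* **γ scan.** Ascending grid with warm starts (each γ starts from the
  previous solution). Selection: the result with the largest `W_app`
  not exceeding the budget; if no grid point reaches the budget, the
  largest-γ result is returned with a warning — the budget is a cap,
  not a target, and well-determined data may saturate below it.
* **β re-fit.** Mean-squared-deviation objective at fixed weights;
  21×21 grid pre-scan over the bounds [0,2]×[0,10] followed by
  Nelder–Mead (xatol 1e-7) from the better of grid optimum and the
  user's start. All-zero feature columns are reported as
  non-identifiable rather than returning an arbitrary coordinate;
  bound-touching optima are flagged.
* **Hybrid test.** Global threshold `t_crit(α, Σdf) ·
  √(s_A²/n_A + s_B²/n_B)` with per-state variances pooled as the mean
  of per-cell sample variances over all testable cells (a per-exposure
  pooling mode is provided, since either convention is defensible);
  Welch's t-test per cell. Cells with fewer than two replicates in
  either state are untestable, never significant. No multiple-testing
  correction beyond the conjunction.
* **Degenerate inputs.** Peptides with no exchange-competent residues
  are dropped with a warning; peptides absent from the MaxD control or
  with non-positive MaxD means are dropped during normalization;
  subsample partitions missing a state are skipped with a warning;
  residue classification ties in the Woods summary resolve to
  "nonsignificant".
* **Subsampling.** "Systematic" means deterministic interleaved
  stride-k partitions (offsets 0…k−1); a seeded random-partition mode
  exists for comparison. SD uses ddof = 1 over the k runs.

## The synthetic generator

`SyntheticSpec` emulates a two-state alternating-access system at desk
scale: 60 residues (two prolines), 100 frames per state, ~20
overlapping peptides of 6–12 residues, exposures {30, 300, 3600} s,
3 replicates, replicate noise 0.01 on the normalized scale, true
mixture 80:20. Contacts are Poisson (λ 14 baseline, 22 in the protected
half) and H-bonds binomial (2 trials, p 0.2/0.8); the OF state protects
the first half of the chain and IF the second, so the states are
HDX-distinguishable, and the feature magnitudes place the predicted
deuteration of the chosen exposures in the informative mid-range rather
than at saturation. Back-exchange is a static per-peptide multiplicative
loss drawn once from U(0.6, 0.9) — exactly the structure that MaxD
normalization cancels.

What the generator does *not* emulate: correlated frame-to-frame
dynamics, residue-level correlation of features within a frame,
EX1/mixed kinetics, peptide misassignment, m/z-domain noise,
time-correlated replicate errors, or intermediate (occluded)
conformations. Passing tests therefore demonstrate correctness of the
estimator under the model's own assumptions, not robustness to every
pathology of real LC-MS data; the exclusion-robustness and per-peptide
RMSE tools exist precisely to probe suspect peptides in real data.

## Problem sizes

The test suite and the acceptance script run the benchmark at its
native scale (200 frames, ~20 peptides, 3 exposures), the β recovery on
a 30-residue, 10-frame zero-noise variant, the brute-force reweighting
oracles on 2–3 frame ensembles (where exhaustive 10⁻³ simplex
enumeration is feasible), and the null calibration on 10,000 simulated
cells — sizes at which every check has an exact or well-converged
reference.

## Known limitations

* The protection-factor model is phenomenological; its β parameters are
  system-dependent, which is why the re-optimization and sensitivity
  machinery exists.
* Distance-only H-bond criterion (no angular term), oxygen acceptors
  only.
* A single intrinsic-rate table version is built in; alternative
  updated tables should be supplied through `load_rates_csv`.
* Reweighting quantifies only states present in the candidate ensemble:
  a conformation absent from the pool (e.g. a fully occluded state)
  cannot acquire weight.
* `ΔG_op = R T ln PF` is exposed in reports for convenience but is not
  validated against calorimetric data.
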
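# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of `islandclock`.  Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## Problem setting

A multi-tissue epigenetic clock predicts chronological age from CpG
methylation measured on arrays.  Methylation fractions (beta values) are
modelled on the M scale, `M = log2(beta / (1 − beta))`, where age trends
are closer to linear and variances more comparable.  Two features of real
compendia drive the design: tissue-identity methylation differences are
much larger than age trends, and tissue sample counts are unbalanced, so
an objective that pools samples lets the model neglect small tissues.

## The penalised island GA

### Fitness

A chromosome is a binary inclusion vector over the candidate CpGs.  Its
fitness (lower is better, units: years) is

    fitness = mean_t MAE_t + cpg_penalty × n_selected

* `MAE_t` — per-tissue mean absolute error of the out-of-fold predictions
  from a K-fold cross-validated ridge regression of age (untransformed
  years) on the selected CpGs' M-values.  Folds are stratified by tissue
  so every fold carries the tissue mix; they are frozen per run, so all
  chromosomes in a run are scored on identical folds.
* The unweighted mean over tissues is the tissue-balancing device: a
  30-sample tissue counts exactly as much as a 120-sample one.  Test
  `test_fitness_decomposition_exact_and_tissue_balanced` verifies both the
  exact decomposition (to 1e-12) and invariance to duplicating one
  tissue's samples.
* `cpg_penalty` = 0.01 years per included CpG.  At a search fixed point a
  CpG is retained only if dropping it costs more than 0.01 years of
  cross-validated error; the acceptance suite audits this by brute-force
  leave-one-CpG-out on converged small instances.

The ridge path is computed by one SVD per fold on fold-standardised
features; the coefficients for the whole penalty grid (50 log-spaced
values on [1e-3, 1e3]) follow from the singular spectrum, and the grid
value minimising the overall out-of-fold MAE is used.  An all-zero
chromosome scores as the intercept-only model rather than erroring, which
keeps the fitness total on the search space.  The error metric is MAE by
default; a squared-error variant is available (`error_metric="rmse"`)
because the two readings coexist in the method's lineage.

### Evolution

Defaults: 200 chromosomes on 4 islands, elite fraction 0.05, single-point
crossover at 0.70 among uniformly drawn elite parent pairs, per-child
mutation 0.10 (one uniformly chosen bit flipped; a per-bit variant is
available), 400 generations, ring migration of each island's best over the
next island's worst every 10 generations, initial bit density 0.10.  Ties
in fitness break toward fewer set bits, then population index, aligning
tie-breaks with the penalty's preference for sparse models.  All-zero
offspring are repaired by setting one random bit.  Each island owns an
independent RNG stream spawned from the run seed and islands are processed
in order, so results are bit-reproducible regardless of thread count.
Fitness values are memoised within a run (elite-derived clones are
frequent), which is an exact optimisation.

A deliberate consequence of elite-only parentage with small islands: the
exploration budget is roughly `mutation_rate × (island size − elite)`
proposals per island per generation (≈2 at the desk scale of 20-chromosome
islands).  On candidate pools with many weakly correlated noise CpGs the
selector therefore converges slowly toward the planted set; the
ground-truth-recovery test in the acceptance suite measures exactly this
trade-off at the fixed desk-scale budget (80 chromosomes × 40
generations), and its precision expectation is not met under those
conditions — the recovered selections run at ~0.3–0.5 precision.  Users
who need cleaner selections should raise the generation count or the
mutation rate; both are plain config fields.

## The principal-component clock

Selected CpG columns are centered by training means only (M-values share a
scale, so no variance normalisation) and decomposed by SVD.  All
components up to numerical rank are retained — the elastic net is left to
shrink unhelpful directions, which subsumes a hard component cut.  Loading
signs are fixed so each column's largest-magnitude entry is positive,
making models comparable across runs.  The elastic net (mixing parameter
0.5, unstandardised scores) regresses the transformed age

    F(a) = log(a + 1) − log(adult_age + 1)   for a < adult_age (20)
    F(a) = (a − adult_age) / (adult_age + 1) otherwise

with the penalty strength chosen on a data-driven log grid by seeded
K-fold cross-validation minimising MAE *on the transformed scale*; the
final coefficients come from the warm-started coordinate-descent path on
the full data.  The GA fitness deliberately uses raw age while the final
clock uses transformed age: selection targets errors in years, the clock
balances paediatric and adult residuals.

Prediction projects new M-values with the stored center and loadings.
CpGs absent from the input are filled with the training mean — exactly "no
information" after centering — with a hard error above 5% missing.

## Synthetic study conditions

The generator emulates the structure of a multi-tissue array compendium,
not its chemistry.  For sample *i*, CpG *j*:

    M_ij = mu_j + delta_{j, tissue(i)} + b_j · age_i · [j in scope(i)] + eps_ij

Defaults (used by tests and the acceptance script):

| parameter | default | rationale |
| --- | --- | --- |
| CpG universe | 2,000 | desk-scale mirror of a filtered array matrix |
| shared age-CpGs | 50 | slopes drawn ±[0.02, 0.05] M/yr, typical of reported age trends |
| tissue-specific age-CpGs | 30 per tissue | tests the per-tissue fitness weighting |
| identity CpGs | 200 | per-tissue offsets N(0, 2²) M — identity dwarfs age signal |
| tissues | 120 / 80 / 50 / 30 | deliberately unbalanced |
| age ranges | 30–90 / 40–85 / 20–75 / 20–60 y | unbalanced age supports per tissue |
| noise | 0.3 M units | moderate array-scale noise; matches the passage-series condition |
| baselines `mu_j` | U(−3, 3) | spans the M range of intermediate methylation |

Technical replicates duplicate each sample twice with independent
N(0, tech_sd²) M-noise (within-pair differences have SD tech_sd·√2);
serial-passage series advance an *effective age* = chronological age +
years_per_doubling × doublings through the same planted model, with donor
ages drawn from 25–45 years (young-adult primary lines keep the
between-donor variance from drowning the culture signal in the pooled
regression).

What the generator does **not** model: probe chemistry and dye bias, batch
effects, cell-composition mixtures, non-linear age trajectories,
correlated noise between CpGs.  Consequently a passing test suite shows
the machinery is correct and the statistical claims hold under these
conditions — not that the pipeline's accuracy numbers transfer to real
arrays.  One ordering claim is known *not* to reproduce at desk scale: a
PCA clock on the full 2,000-CpG synthetic matrix is already accurate
(~9% of the universe carries strong signal), so selection-then-PCA does
not beat full-matrix PCA here, while it does beat the random-CpG baseline
in every seed tested.  The advantage of selection before PCA belongs to
regimes of much sparser signal (hundreds of useful CpGs in hundreds of
thousands) than a desk-scale simulation can represent faithfully.

## Statistics

* **Random-CpG baseline** — per iteration: 350 CpGs drawn without
  replacement, 10-fold CV elastic net of age on their M-values in the
  training split, median absolute test error recorded overall and per
  tissue.  Sub-seeds are spawned per iteration index, so a k-iteration run
  is a prefix of an n-iteration run and the loop parallelises
  deterministically.
* **Error comparisons** — two-sample Student's t-tests (Welch optional)
  with 95% CIs for the mean difference, Benjamini–Hochberg adjusted across
  the requested family.  Zero-variance comparisons are flagged, not tested.
* **Power** — Cohen's d = effect / pooled acceleration SD; the analytic
  backend searches the exact noncentral-t power curve for the smallest
  per-group n at 80% power, α = 0.05, two-sided (one-sided optional); the
  Monte-Carlo backend estimates power by simulated t-tests and agrees with
  the analytic answer within one sample per group.  Default effect grid:
  1.0–2.5 years in 0.25 steps.
* **Age acceleration** is predicted − chronological age everywhere — not
  the residual-from-regression definition some clock literature uses.
  The passage-series analysis regresses *predicted age* (not acceleration)
  on population doublings, so its intercept is on the age scale.

## Numerical choices and degenerate inputs

* Beta values are clipped to [1e-6, 1 − 1e-6] before the logit (below
  array resolution; keeps M finite).
* KNN imputation (k = 10) uses nan-aware Euclidean distances over mutually
  observed CpGs, rescaled by the number used; per-CpG missingness above
  50% and all-missing samples are hard errors.
* Detection-p filtering removes a CpG failing in any sample by default;
  the tolerated failing fraction is configurable.
* The correlation pre-filter keeps a CpG if any tissue reaches |r| ≥ 0.3
  (max rule; mean-over-tissues and pooled rules are config options) —
  the selector, not the pre-filter, adjudicates multi-tissue utility.
  Zero-variance CpGs get r = 0; tissues under 3 samples are excluded with
  a warning.
* Stratified splitting partitions within tissue × dataset (tissue-only
  optional) at round(fraction × stratum size); singleton strata are
  errors.
* Model files are a single schema-versioned JSON container; any
  serialization round-trip is lossless at double precision.

## Scale of the bundled experiments

Tests and the acceptance script run the pipeline at desk scale — 80
chromosomes × 40 generations over ~650 candidates for the end-to-end runs,
~55-candidate pools × 150 generations for the penalty-calibration audit,
100 baseline iterations — sizes chosen so the full suite completes in a
few minutes on one CPU while still exercising every code path at
non-trivial dimensionality.  The full-scale defaults (200 × 400 over
thousands of candidates, 2,500 baseline iterations) are plain
configuration values.
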
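# Methods

## The model

The package models a binary disease phenotype with a binomial-logistic
GLM. For individual *i* with covariates (recruitment center, gender,
optionally major-locus carrier status) and fractional genotype dosages
X<sub>ij</sub> ∈ [0, 2]:

    logit P(y_i = 1) = β0 + β_center·X_center + β_gender·X_gender
                       [+ β_drb1·X_drb1] + Σ_j β_j · X_ij

Dosages are used additively and un-thresholded: converting imputed
fractional genotypes to hard calls discards the imputation uncertainty
and inflates variance. The cumulative genetic risk of an individual is
the fitted probability P-Hat = 1/(1 + e^(−Ŷ)); the classification rule
is fixed at Ŷ > 0 (P-Hat > 0.5) and is never tuned — ROC sweeps vary the
threshold only for plotting.

Conditioning on the major HLA-type locus is implemented as a fixed
carrier-status indicator covariate. With two large carrier strata the
indicator formulation and a stratum-intercept conditional likelihood are
asymptotically equivalent, and the indicator keeps every downstream
model a plain GLM.

## Fitting and nested tests

`fit_logistic` maximises the binomial likelihood by IRLS with
step-halving (a Newton step is halved until the deviance does not
increase). Convergence is declared when the relative deviance change
falls below 1e-10, with a 50-iteration cap. Rank-deficient designs are
rejected up front with the collinear columns named (pivoted QR, relative
tolerance 1e-9·max(n,p)). Complete or quasi-complete separation makes
the likelihood monotone in some direction; when an iterate would exceed
±15 on the log-odds scale the step is walked back exactly to the ±15
boundary and the fit returns `converged=False, separation=True` — an
honest point on the likelihood path rather than a silently diverged
estimate. The covariance is the inverse observed information at the
returned coefficients.

The screen and stepwise stages use two nested-model tests, both
likelihood-ratio (analysis-of-deviance) by default because Wald
statistics degrade near separation at moderate effect sizes:

* **sequential (type I)**: deviance drop from adding block *k* to the
  model containing blocks 1..k−1; the statistics over a fixed ordering
  telescope exactly to deviance(null) − deviance(full);
* **partial (type III)**: deviance drop of the full model relative to
  the full model minus the tested predictor (df 1).

The scan and the stepwise forward sweep substitute cheaper statistics
where exactness is not needed: the scan fits all single-marker models
with batched IRLS (identical estimates, vectorised across markers), and
the forward sweep uses the Rao score test, which needs only the current
fit — one refit per accepted step instead of one per candidate. Exact-LR
forward selection is available (`forward_method="lr"`) and selects the
same markers in the cases tested.

Nagelkerke's R² is the Cox–Snell ratio rescaled by its maximum:
R² = [1 − exp((D_full − D_null)/n)] / [1 − exp(−D_null/n)]. Variance
partition adds predictor blocks in a stated order and reports the
increments, which telescope exactly to the full-model R².

## The multi-stage protocol

* **Stage I**: each marker fitted under the base (center + gender) and
  conditioned (+ carrier status) covariate models; the marker p-value is
  the 1-df LR test. Selection keeps markers under the threshold
  (default 0.001) in *both* models, sorted by conditioned-model p.
  Monomorphic markers report p = 1 with a flag. The
  Benjamini–Hochberg q at the chosen cutoff is available descriptively;
  selection is by raw p.
* **Stage II**: seeds = best marker per non-overlapping 500-kb window
  among P < 1e-5 survivors (a positional stand-in for "best per gene";
  window size is a knob), entered sequentially in significance order and
  dropped if the sequential p ≥ 0.01. Then, repeatedly: every remaining
  candidate is partial-tested against the accepted model and joins at
  P < 0.001; the combined set is re-examined — a sequential pass in
  entry order, then an iterative worst-first partial prune (removing the
  single worst failing marker and refitting, so that of two markers in
  mutual LD exactly one survives). The loop ends when no candidate
  passes expansion, with a 25-iteration cycle guard; every decision is
  logged and the audit log replays to the final state. Ties everywhere
  break by (p, chromosome, position, id).
* **Stage III**: forward/backward stepwise from the independent set with
  entry/stay thresholds from {0.01, 0.05, 0.1}, default 0.05; center and
  gender are never eligible for removal.
* **Stage IV**: the trained marker panel is applied to a validation
  cohort either `frozen` (training coefficients kept; a center unseen in
  training contributes 0 with a warning) or `refit` (same markers,
  coefficients re-estimated with the validation cohort's covariates —
  the default, since transferred intercept/center terms are meaningless
  across genotyping platforms). Both modes are recorded in the output.

## Evaluation statistics

AUC is the Mann–Whitney probability that a random case outscores a
random control, ties counted half; it equals the trapezoidal area under
the empirical ROC (cross-checked to 1e-12 in the tests). Quantiles use
linear interpolation (type 7). The Hosmer–Lemeshow statistic bins
samples into deciles of P-Hat, sums (O−E)²/(E(1−E/n_bin)) and refers to
chi-square with g−2 df; empty or zero-expectation bins are merged into a
neighbour and the merge count reported. The g−2 reference is calibrated
for *fitted* models (the standard setting); for externally supplied true
probabilities it is mildly anti-conservative, which the calibration
tests account for.

Genetic-load groups bin affected individuals by P-Hat with half-open
boundaries, the cut points inclusive on the higher group: high ≥ 0.95,
medium [0.75, 0.95), low [0.5, 0.75), misclassified < 0.5. Categorical
group comparisons use the classical Pearson chi-square without
continuity correction. Quantitative traits use ANCOVA: OLS of the
transformed outcome (none/sqrt/cbrt) on group + covariates, the group
factor tested by the partial F after covariates (coding-invariant), and
least-square means reported at the covariate sample means. If the
covariates fit the outcome exactly the group F is defined as 0. No
multiplicity adjustment is applied across clinical outcomes; the output
notes this.

## The synthetic-data generator

The generator emulates what the analysis assumes about imputed GWAS
data, not any particular population's LD landscape:

* **LD blocks** — within a block, each haplotype copies a shared latent
  uniform with probability r (`within_block_r`) and draws fresh
  otherwise, then thresholds at its allele frequency. Marginal allele
  frequencies are exact and the pairwise *genotype* correlation within a
  block is r² (exact at equal frequencies), which makes the LD strength
  directly controllable; a thresholded-Gaussian copula was rejected
  because dichotomisation attenuates the binary correlation below the
  latent one. Blocks are mutually independent, laid one per megabase
  across 22 autosomes with 5-kb marker spacing.
* **Imputation uncertainty** — with probability 1 − `imputation_quality`
  a dosage is blended toward an adjacent genotype class by a
  Beta(1.2, 5) weight, giving the tri-modal fractional histogram with
  inter-peak mass; quality 0.97 (the default) keeps the three integer
  modes visibly dominant.
* **Disease model** — a generative logistic liability: center offsets,
  a gender odds ratio, a major locus entered as a carrier indicator
  (carrier = at least one allele of a dedicated tag SNP), and
  `n_causal` weak effects drawn one per LD block (so planted signals
  are mutually independent), magnitudes uniform in `causal_or_range`
  and sign-flipped to protective with probability 0.5. The polygenic
  term is centred at the mean genotype so the intercept pins baseline
  prevalence regardless of the signed draw. Case-control ascertainment
  samples the requested numbers of cases and controls from an
  oversampled population and errors (suggesting an intercept change) if
  the population cannot supply them.
* **`paper_like` preset** — six recruitment strata with realistic
  population shares and case-rate offsets, a major locus with
  population carrier frequency 0.28 and OR 4.3, gender OR 3.5 and
  intercept −3.6, calibrated once so that *after ascertainment* the
  carrier frequency lands near 53% in cases vs 25% in controls and the
  female share near 72% vs 50% at discovery scale. The marker panel
  (1,200 markers) is desk-scale; proportions and effect sizes are not
  scaled.

What the generator does **not** emulate: coalescent LD decay, allele-
frequency spectra, X-chromosome markers, relatedness, genotyping error
beyond the dosage blend, gene–gene or gene–environment interaction.
Passing tests therefore certify the statistical machinery and the
protocol's behaviour under its own assumptions — recovery of planted
independent signals, calibration under the null, optimism under
transfer — not performance on any real cohort.

## Problem sizes and reproducibility checks

The acceptance experiments run at sizes a laptop handles in minutes,
chosen as the smallest that leave the Monte-Carlo bands comfortably
informative: null-scan calibration on 2,000 samples × 10,000 markers
(hit rate at P < 0.001 and λ ∈ [0.95, 1.05]); block recovery with 20
causal markers (OR 1.3–1.8, half protective) among 400 markers in
40 blocks at 2,000/2,000 cases/controls over 20 replicates (expected:
≥ 80% of causal blocks recovered, at most one selected marker per block
in ≥ 90% of replicates); optimism over 20 train/validate pairs at
n = 1,200 (discovery AUC exceeds validation AUC in ≥ 90%); and
Hosmer–Lemeshow type-I calibration over 200 fitted replicates at
n = 1,200 (rejection within binomial noise of 5%). All generators run
on `numpy.random.default_rng` with seeds spawned via `SeedSequence`
from the single `--seed` argument; repeated runs are byte-identical.

## Known limitations

* The screen's termination is guarded, not proven; the audit log records
  any cycle.
* The carrier indicator approximates exact conditional likelihood; with
  very small strata the approximation would degrade.
* Wald intervals (reporting only) are symmetric on the log-odds scale
  and poor near separation; separated fits refuse to produce them.
* The stepwise procedure inherits the classical caveats of significance-
  driven selection (no shrinkage, optimism in-sample); the optimism
  experiment quantifies exactly this.
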
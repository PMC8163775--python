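# Methods

This note documents the models and procedures implemented in `mixsig`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Synthetic cohort model

The generator (`mixsig.cohort`) emulates a dual-platform oncology cohort.

**Latent expression.** Each endogenous mRNA probe j gets a per-sample
standard-normal latent value z_ij. Non-informative probes are organized in
consecutive blocks of `block_size` with equicorrelation `block_corr`
(default 0.5, blocks of 10): this models redundant co-expression *noise*
structure and is what the correlation-pruning stage is meant to remove.
Informative probes are drawn independent of the blocks, so the planted
signal is not confounded with noise proxies; their positions are evenly
spaced over the panel (the placement is arbitrary; spacing merely keeps
them in distinct neighborhoods). Protein latents share correlation
`protein_mrna_corr` (default 0.4) with their cognate transcript and 0.5
across compartments of the same target, matching the weak-to-moderate
mRNA–protein concordance typical of such panels.

**Outcome model.** The latent predictor is
`lp_i = Σ_j c_j z_ij` over the informative features, with
`|c_j| = effect_size` (log-odds per latent SD, alternating signs).
Response is Bernoulli with
`P(response) = logistic(logit(response_rate) + lp_i)`;
`response_rate` defaults to 0.40, the objective response rate typical of
checkpoint-inhibitor therapy in advanced melanoma. Best-overall-response
categories refine the binary outcome: the top quartile of response
probability among responders is labelled CR (the rest PR), and the mirror
rule yields PD vs SD. Only the PR/CR vs SD/PD dichotomy matters downstream.

**Counts.** Observed counts are negative-binomial
(Var = m + `nb_dispersion`·m², default dispersion 0.2, the overdispersion
scale seen in barcode-counting assays) around
`technical × content × exp(μ_j + biological_sd · z_ij)`. Per-sample
log-normal technical (σ=0.3) and RNA-content (σ=0.2) factors apply to all
probes / endogenous+housekeeping probes respectively, so that the two-step
normalization has real work to do. The spatial protein readout adds a
per-AOI system factor, an additive background (shared with the negative
IgG controls), area-proportional signal with log-normal areas (σ=0.4,
median 1), and positive controls that track only the system factor.

**Survival.** PFS and OS times are exponential proportional-hazards draws
with log-hazard −lp_i (high latent predictor → responder → later
progression) and baseline medians 6 and 18 months; censoring is an
independent exponential calibrated to `censor_rate` (default 0.3) at the
baseline hazard. PFS and OS are generated independently given lp, so
OS ≥ PFS is *not* enforced; no downstream stage relies on that ordering.

**What the generator does not model:** image-level DSP physics, real
gene-regulatory structure, batch effects, platform-specific probe failure.
Passing tests on this benchmark therefore demonstrates algorithmic
correctness and statistical calibration of the pipeline, not clinical
validity on real cohorts.

## Normalization

mRNA: per sample, counts are multiplied by
(reference ÷ sample control geomean), first with internal-control probes
(technical efficiency), then with housekeeping genes (RNA content). The
reference is the cohort geometric mean of the per-sample control geomeans,
which makes the output scale cohort-relative and the procedure idempotent;
note that rescaling one sample's raw counts by c therefore shifts the whole
cohort's count-scale output by exactly c^(1/n) (the reference moves), with
relative structure untouched. Zeros inside a control set are ignored by the
geometric mean; an all-zero control set is an error naming the sample.
Counts get a +1 pseudocount before log2 — the conventional count transform
when zeros are possible.

Protein: per AOI, the geometric mean of the negative (IgG isotype)
controls is subtracted (floored at 0 — background correction must not
produce negative signal), a positive-control geomean factor removes system
variation, and counts are scaled to the cohort median compartment area.
Background *subtraction* (rather than using negatives as a scale factor)
was chosen because isotype controls estimate additive non-specific
binding; the alternative is a config option away. Control antibodies are
excluded from the modeling pool (default panel: 887 = 770 + 39×3 combined
features) but can be retained for the joint clustering view (132 protein
variables = 44×3).

## Concordance

Feature clustering uses distance 1 − Pearson r with average linkage —
the standard choice for expression heatmaps; both are exposed. Constant
features are dropped with a warning. The per-target Spearman table
correlates each antibody with its cognate transcript per compartment and
for the compartment *sum*, computed on the count scale (inverting the log)
before re-logging; Spearman is rank-based, so the outer transform is
immaterial. Undefined correlations (constant vectors) are reported absent
(NaN), never as 0.

## Screening and pruning

Univariate logistic fits use a tiny L2 stabilizer (total penalty 1e-6) so
perfectly separating features — common at n≈60 — return finite
coefficients; p-values are likelihood-ratio tests of the *unpenalized*
deviances at the fitted coefficients, and the stabilizer sits far below
the reported precision. Pseudo-R² is McFadden's 1 − dev/dev₀. The greedy
prune visits features in descending R² (ties: higher AUC, then feature id)
and keeps a feature iff its |Pearson r| with every kept feature is ≤ 0.7;
the kept set's maximum pairwise |r| is asserted on every run. Ranking by
AUC instead, or interpreting the threshold on r², are config options
(`rank_by`, `corr_scale`) since reasonable practitioners differ here.

## Elastic net

The penalty is the glmnet convention
λ[(1−α)/2‖β‖² + α‖β‖₁] on the mean binomial negative log-likelihood, so
α = 0.15 means mostly ridge. Fitting is delegated to
scikit-learn's saga solver with C = 1/(nλ) and l1_ratio = α (lbfgs for
α = 0); features are standardized internally and coefficients mapped back
to the expression scale, so signature scores are plain dot products with
the normalized matrix. The λ path holds 100 log-spaced values from λ_max
(the smallest λ with an all-zero fit) down four decades; the path is
walked with warm starts.

Tuning: per replicate, stratified 4-fold assignments are re-randomized and
out-of-fold scores pooled into one AUC per (α, λ); AUCs are averaged over
replicates (default 40) and the argmax wins, ties resolving toward
sparsity (higher α, then higher λ). Re-randomizing folds (not the λ path)
across replicates is the implemented reading of replicate averaging.

Stability selection: 1000 class-stratified bootstrap resamples (stratified
because at n≈59 an unstratified resample can lose a class), one fit each
at the tuned (α, λ); the median non-zero count M (rounded half-up) sets
the model size, and the M most frequently selected features (ties: higher
mean |β| across bootstraps, then feature id) enter the final fit. An empty
final model raises an explicit error telling the caller to relax λ.

## Consensus best-subset search

Subset scores use the final model's coefficients verbatim — no refitting —
so the search explores only combinations, not new fits. Enumeration is
exhaustive while C(p, K) fits the 2,000,000-subset budget, otherwise that
many unique uniform draws (rejection sampling on canonical sorted tuples);
the budget rule reproduces an exhaustive-below-K=5 / Monte-Carlo-above
behavior at p≈44. Ten best subsets by AUC (ties: larger Σ|β|, then member
names) vote by feature frequency; the K most frequent features form the
consensus, whose score is evaluated with the Youden cutpoint. "First peak"
over K = 4..13 is formalized as the first local maximum of the consensus
AUC with one-sided comparisons at the endpoints. Subset AUCs are computed
on the full cohort by default (single-cohort reporting); `subset_eval_set`
switches to train- or test-only.

## Evaluation

AUC is the tie-corrected rank-sum probability (equivalently the
trapezoidal ROC area). The Youden cutpoint scans midpoints between
consecutive distinct scores, maximizing J = sens + spec − 1 with ties
resolved to the lowest threshold; classification uses score ≥ cutpoint →
responder (higher score = response). Undefined PPV/NPV (empty denominator)
are reported absent. Confidence intervals come from a smoothed bootstrap:
(score, label) pairs resampled with replacement, Gaussian noise with
Silverman's rule-of-thumb bandwidth added to the resampled *scores* only
(labels are categorical and never smoothed), percentile 2.5/97.5 limits;
single-class resamples are redrawn. Permutation importance is the mean
AUC decrease over (default 1000) permutations of one feature's column in
the fixed-coefficient subset score; a zero-coefficient feature has
importance exactly 0.

## Survival

Dichotomization reuses the response-classification cutpoint unchanged
(score ≥ cutpoint → high). Kaplan–Meier curves, the two-sample log-rank
test, and a univariate Cox fit of the high-vs-low indicator (Efron ties,
low = reference) come from lifelines; the module reports both the log-rank
p and the Cox Wald p. A group without events triggers a monotone-likelihood
warning and flags the HR CI unreliable. With responders scoring high, a
protective signature yields HR < 1.

## Numerical choices and degenerate inputs

- saga tolerance 1e-5 / 1000 iterations on the tuning path; fixed
  `random_state`, so refits are bit-identical.
- Single-class responses, single-group survival comparisons, all-zero
  controls, missing areas, K > p, and subsets outside the model's non-zero
  set raise typed errors naming the offending object.
- All stage seeds derive deterministically from the pipeline seed; a rerun
  with the same config reproduces the report byte for byte.

## Problem sizes used in the shipped checks

The default configuration keeps the full-scale constants (21-point α
grid, 40 replicates, 1000 bootstraps, 2,000,000-subset budget, 1000-draw
CIs). The shipped test suite and the acceptance script run the pipeline at
desk scale as the package's own benchmark sizes: cohorts of 60–200
samples, 40–300 mRNA probes, reduced α grids (3–5 points), 2 tuning
replicates, 10–100 stability bootstraps, Monte-Carlo budgets of 10³–3×10⁵
subsets, and 200–500 bootstrap draws for CIs. Planted-signal recovery uses
8 informative features of 300 at effect size 1.0 with n = 200 over ten
seeds.

## Known limitations

- No nested cross-validation: the reported AUCs inherit the optimism of
  single-cohort tuning, as in the procedure the pipeline reproduces.
- The univariate screen applies no multiple-testing correction (by
  design at this stage).
- Count-noise attenuation means an `effect_size` of 1.0 per latent SD
  corresponds to a smaller per-observed-SD effect (~0.8 here); recovery
  rates quoted for the benchmark are specific to the generator's noise
  settings.
- The smoothed bootstrap uses percentile (not BCa) intervals, and the
  kernel noise added to scores slightly attenuates separation, so the AUC
  CI under-covers mildly (empirically ~90% at n = 200 for a binormal
  instance, vs ~92% unsmoothed). Users needing strict nominal coverage
  should prefer larger cohorts or an analytic interval.
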
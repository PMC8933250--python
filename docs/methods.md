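# Methods

`cpmnet` implements connectome-based predictive modeling (CPM) of a clinical
severity score from resting-state functional connectivity, in the style used
to predict motor impairment (UPDRS III) in Parkinson's disease from 268-node
whole-brain networks. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Pipeline

**Network construction.** Inputs are node-level time series (voxel-to-node
averaging, nuisance regression, band-pass filtering and the removal of
non-equilibrium volumes are assumed done upstream). Volumes with framewise
displacement (FD) ≥ 0.2 mm are censored; subjects retaining fewer than 120
volumes (4 min at TR = 2 s) are flagged excluded. Mean FD is computed over
all input volumes, pre-censoring (the alternative — post-censoring — is not
exposed; the choice matters little because censored cohorts are flagged
anyway). Connectivity is the Pearson correlation between each node pair,
Fisher r-to-z transformed (`z = atanh r`), both signs retained, zero
diagonal. Perfect correlations are clamped to ±(1 − 1e−7) with a warning
rather than letting `atanh` diverge.

**Edge selection.** For each leave-one-out fold, every upper-triangle edge's
strength across the training subjects is correlated with the score by
*partial Spearman correlation*: all variables are rank-transformed (average
ranks for ties; a 0/1 covariate like gender ranks cleanly this way), the
edge and score ranks are residualized on the ranked nuisance covariates
(age, gender, disease duration by default; mean FD optionally) by least
squares, and the residuals are Pearson-correlated. Significance uses
`t = rho·sqrt((n−2−k)/(1−rho²))` on `n−2−k` degrees of freedom, a standard
choice the source procedure leaves unstated. Edges with `p < threshold`
enter the positive or negative candidate set by the sign of rho. Edges
selected in *every* fold are the consensus connections.

**Model.** Each subject's two features are the summed z-strength over the
positive and negative consensus masks; ordinary least squares maps them to
the score: `predicted = a1·x1 + a2·x2 + b`. If one polarity's sum is
constant (empty mask), that column is dropped with a warning and its
coefficient reported as zero. Performance is the Spearman correlation
`r_true` and the MSE between predicted and observed scores.

**A deliberate optimism.** The consensus masks come from cross-validation,
but the final coefficients are fit on *all* training subjects and `r_true`
is evaluated on those same subjects. This in-sample evaluation is the
procedure being modeled (it is how the headline training correlation can
exceed the per-fold variant's); the honest out-of-sample estimate is the
per-fold variant M3 (`comparison.build_variant(..., "per_fold")`), in which
each subject is predicted by a model selected and fit without them.

**Permutation inference.** Scores are shuffled `n_perm` times (1,000 by
default); covariate and connectome rows stay aligned with each other. The
whole selection-and-fit pipeline is rerun per shuffle, and
`p_permu = #(permuted r ≥ r_true)/n_perm` — a strict percentage with no +1
smoothing. Permutations with an empty consensus score the sentinel r = −1
so the denominator stays fixed. Because edge ranks and covariate
projections do not depend on the score, they are computed once per fold and
each permutation reduces to one matrix product; a threshold on p is applied
as the equivalent critical |rho|, so no per-edge tail probabilities are
evaluated in the hot path.

*Calibration caveat.* Shuffling only the scores is exact when the score is
exchangeable — i.e., also independent of the covariates. When covariates
correlate with the score (as age and duration do here), the observed
pipeline selects edges against the covariate-residualized score while
permuted runs face no such dilution, and the test becomes conservative
(measured: mean p_permu ≈ 0.9 on nulls with correlated covariates). The
null cohorts used for calibration checks therefore zero the covariate-score
correlations as well as the edge effects; under that exchangeable null the
rejection rate is nominal. On real data the test errs on the safe side.

**Threshold optimization.** The selection threshold scans the 50-value grid
.001–.050 (step .001); the threshold maximizing `r_true` wins, ties going to
the smaller (more stringent) value — a tie-break the source leaves open.
Per-fold edge statistics are computed once and reused across the grid.
Thresholds yielding an empty consensus are skipped (NaN in the table).
Whether permutation runs should re-optimize the threshold is likewise open;
they reuse the fixed optimum, since that is the frozen model under test.

**External validation.** A frozen model (masks + coefficients) is applied
to an independent cohort with no re-selection or refitting; significance of
the validation Spearman r uses the standard parametric conversion.

**Model comparison.** Dependent predictive correlations sharing the
observed-score variable are compared with Steiger's Z for two dependent
correlations (the Z1* form): Fisher-transform both correlations, estimate
their covariance by plugging the pooled correlation
`rbar = (r_jk + r_jh)/2` into the asymptotic covariance
`psi = r_kh(1−2·rbar²) − rbar²(1−2·rbar²−r_kh²)/2`, `s = psi/(1−rbar²)²`,
and refer `Z = (z_jk − z_jh)·sqrt((n−3)/(2−2s))` to the standard normal.
The comparison uses the Spearman correlations of the prediction vectors,
matching the pipeline's evaluation statistic. Rank-identical prediction
vectors short-circuit to Z = 0 (the formula degenerates at r_kh = 1).

**Network anatomy.** Nodes belong to one of seven canonical functional
networks (frontoparietal 63, default mode 20, motor 50, visual-related 45,
limbic 30, basal ganglia 29, cerebellum 31; 268 total). Consensus edges are
counted per unordered network pair; possible counts are n(n−1)/2 within and
n_a·n_b between. Proportions are reported per mille; aggregate
within/between values pool counts over pooled possibles by default
(averaging per-pair ratios is exposed as an option, since either reading is
defensible). A network's contribution counts combined-mask edges *incident*
to it — a between-network edge credits both endpoint networks — normalized
by the edges incident to the network, n_k(n_k−1)/2 + n_k(N−n_k). Lesioning
deletes all nodes of one network, reindexes the matrix (63-node removal:
268 → 205), and reruns the pipeline at the full model's fixed threshold;
full-vs-lesioned predictions are compared with Steiger's Z under a
14-comparison Bonferroni correction (seven networks × two cohorts).

## Synthetic cohorts

The generator emulates the statistical shape of the modeled study, not its
physiology:

- **Score**: scaled Beta(2, 5) on [4, 68] — right-skewed, like the
  non-normal severity scores that motivate rank-based selection.
- **Covariates**: a Gaussian copula links age and disease duration to the
  score at Spearman ≈ .40 and ≈ .53; gender is Bernoulli(½) noise; mean FD
  is lognormal (median 0.08 mm) and independent of the score.
- **Edges**: every edge is `0.2 + noise` with `noise_sd = 0.25` (Fisher-z
  units, plausible for resting-state connectivity). Planted edges add
  `±β·standardized(score)`, with β set through the Gaussian-copula relation
  `rho_pearson = 2·sin(π·rho_spearman/6)` so the planted *rank* correlation
  hits the configured effect size (measured 0.599 at target 0.6 across 30
  replicate cohorts). Defaults mirror the study scale: 47 subjects, 268
  nodes, 57 positive + 58 negative planted edges, effect size 0.6.
- **Time series**: a latent-factor model in which each planted node pair
  shares a factor with configurable loading (loading 1 ⇒ correlation 1);
  the FD trace is sub-threshold lognormal baseline plus spikes ≥ 0.2 mm at
  a configurable per-volume rate.

What passing tests on these cohorts do *not* show: robustness to spatial
autocorrelation between edges, heavy-tailed or site-dependent noise,
score-correlated motion, atlas misalignment, or any physiological realism.
They show that the machinery — selection, consensus, inference,
comparison, anatomy — does what it claims when the ground truth is known.

The per-edge effect size of real severity-connectivity correlations is not
identifiable from published summaries; 0.6 was chosen once for testability
(strong enough that consensus selection should recover planted edges at
n = 100) and is not a claim about real effect magnitudes.

## Numerical choices and degenerate inputs

- Constant vectors raise an undefined-correlation error; when the MSE is
  still well defined (evaluation of a constant prediction) it travels on
  the exception.
- A variable fully collinear with the covariates yields a degeneracy
  warning and partial correlation 0 rather than 0/0.
- Zero-variance edges get rho = 0, p = 1, and are never selected.
- Collinear sum features raise a singular-fit error; a merely *constant*
  feature is dropped with a warning.
- A strictly increasing transform of the scores leaves every selection
  decision and any fixed model's evaluation exactly unchanged (everything
  is rank-based). The `r_true` of a *refit* two-feature model is not
  exactly invariant: refitting on the transformed scale reweights the two
  sums, which can shift prediction ranks slightly.
- Upper-triangle edge order is row-major over (i < j); node indices are
  0-based in memory and 1-based in every file format.

## Problem sizes used in checks

The calibration study runs 200 replicate null cohorts of 47 subjects × 40
nodes at 200 permutations each; recovery studies use 100-subject, 40-node
cohorts with 15 planted edges (selection threshold .001, the stringent end
of the grid, where false consensus edges are rare); the in-sample-vs-
per-fold ordering check uses 100 seeds of 100-subject, 20-node cohorts.
These sizes were chosen to make Monte-Carlo bands tight while keeping the
studies rerunnable on a laptop; the acceptance script additionally runs the
full 47 × 268 study scale once.

## Known limitations

- The permutation test's conservatism under score-correlated covariates is
  inherent to shuffling scores alone; shuffling residuals (Freedman–Lane)
  would calibrate it but is deliberately not the modeled procedure.
- At the full study scale (47 subjects, 35,778 *independent* synthetic
  edges) the permutation test has essentially no power against the
  in-sample `r_true`: selecting from tens of thousands of i.i.d. noise
  edges and fitting in-sample saturates the statistic under permuted
  scores too (null r ≈ 0.9), so planted and permuted runs are
  indistinguishable on that axis. This is a property of independent-edge
  synthetic data, the worst case for selection bias — real connectomes
  are spatially correlated with a far lower effective dimension. At
  moderate edge counts (e.g. 40 nodes, 780 edges) the test is both
  calibrated under the null and powerful against planted effects, which is
  where the calibration and power studies run.
- Consensus intersection over leave-one-out folds barely perturbs the
  selection statistic at large n, so it is a weak false-positive filter on
  its own; the stringency must come from the threshold.
- Only leave-one-out cross-validation, correlation-filter selection and
  linear read-out are implemented; k-fold variants and regularized models
  are out of scope.
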
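# Methods

## Model

The analysis treats p ordinal questionnaire items as discretizations of a
latent multivariate normal vector Z ~ N(0, Σ) with unit variances: item j
reports category `c` when its latent coordinate falls between thresholds
`τ_{j,c}` and `τ_{j,c+1}`. Conditional-independence structure among the
latent variables is encoded by the precision matrix K = Σ⁻¹; the reported
network edge between items i and j is their partial correlation
`w_ij = −k_ij / √(k_ii k_jj)`, the association that remains after
conditioning on all other items.

## Polychoric estimation

Two-step maximum likelihood: thresholds are estimated first from each
item's margin (`τ_k = Φ⁻¹` of the cumulative proportion), then the latent
correlation ρ of each pair maximizes the multinomial likelihood of its
contingency table with thresholds held fixed. The two-step estimator is
the standard choice in psychometric network software; it is faster than
joint ML and its bias is negligible at these sample sizes (the test suite
verifies bias < 0.02 and RMSE < 0.05 at n = 10,000 across
ρ ∈ {−0.6 … 0.6}).

Numerical choices:

* Cell probabilities use the correlation-integral representation of the
  bivariate normal CDF evaluated by 48-node Gauss–Legendre quadrature
  (~1e−14 accuracy for |ρ| ≤ 0.95, cross-checked against scipy's Genz
  algorithm, which is also the fallback for |ρ| > 0.95). The quadrature
  form vectorizes over the threshold grid, which is what makes full-
  pipeline bootstrapping affordable.
* ρ is maximized by bounded derivative-free scalar search on
  [−0.999, 0.999] with xatol 1e−6; estimates within 5e−4 of the bound are
  snapped to ±0.999 and flagged as boundary estimates. The clamp keeps
  downstream matrices invertible.
* Empty extreme categories give ∓∞ thresholds, handled naturally by
  open-ended rectangles; an interior empty category produces tied
  thresholds, broken by an epsilon of 1e−6 with a warning; an item with a
  single observed category is a hard error naming the item.
* Missing data: pairwise-complete observations per pair (keeps per-pair n
  maximal; per-pair n is recorded and the minimum is used as the
  conservative likelihood n for EBIC).
* The assembled pairwise matrix need not be PSD; repair clips eigenvalues
  at 1e−6, reconstructs, and rescales to unit diagonal. Repair is
  idempotent and cannot move entries outside [−1, 1].

## Graphical lasso and EBIC

The solver is block coordinate descent on the working covariance
(lasso-per-column), with the diagonal unpenalized, warm starts along a
descending log-spaced 100-point penalty path from λ_max (the largest
absolute off-diagonal correlation, at which the selected network is
empty) to 0.01·λ_max. Zeros are structural (soft-threshold exact zeros;
a |k| < 1e−10 sweep guards against round-off). Convergence is max
absolute change in the working covariance ≤ tol (default 1e−6); the KKT
stationarity conditions are exposed via `kkt_residual` and checked in
tests. At λ = 0 the maximizer is S⁻¹ and is computed directly.

EBIC selection uses γ = 0.5 (the conventional value for psychometric
networks) and n = the minimum per-pair complete-observation count. Ties
are broken toward the larger penalty, i.e. the sparser model. Edge-count
monotonicity along the path is checked on every run; single-edge flicker
near the small-λ end of the path (a known property of the lasso support
path, not a solver failure) is reported as a warning.

## Centralities

One-step expected influence `EI(v) = Σ_j w_vj` and one-step bridge
expected influence `BEI(v) = Σ_{j: community(j) ≠ community(v)} w_vj`
over the *declared* community partition (communities are metadata, never
inferred). Two-step variants are out of scope. Identities
`Σ EI = 2 Σ w_ij` and `Σ BEI = 2 Σ cross w_ij` are enforced to 1e−12 in
the test suite. `mean_weight` averages signed weights over all p(p−1)/2
pairs including structural zeros; because summaries in the literature are
ambiguous about zeros and signs, the absolute-value variant is also
reported. Rank ties are broken lexicographically by label and flagged.

## Bootstrap diagnostics

Every replicate re-runs polychoric estimation, the full glasso path and
EBIC re-selection — uncertainty from model selection is propagated, not
conditioned away. Replicate r always uses seed substream r (SeedSequence
spawning), so results are independent of the worker count; the consolidated
JSON report is byte-identical across reruns (the execution-only `n_jobs`
field is therefore excluded from the config echo). Edge CIs are 95%
percentile intervals (distribution-free, the ecosystem default; BCa is not
implemented). Difference tests declare two edges (or two node EIs)
different iff the (α/2, 1−α/2) percentile interval of their bootstrapped
difference excludes 0.

The case-dropping bootstrap subsamples without replacement at 10 drop
proportions evenly spaced on [0.05, 0.75]; a level whose subset would be
smaller than p + 1 is marked infeasible. The CS coefficient is the largest
drop proportion q such that at every grid proportion ≤ q at least 95% of
replicates have Pearson correlation ≥ 0.7 between subset and original EI
vectors; replicates with zero-variance EI (empty subset networks) are
excluded with a count, and a level with no usable replicates cannot
qualify. The report schema reserves a `cs_ci` field, but no method for a
confidence interval around CS is defined here, so it is always null.
More than 10% failed replicates in the nonparametric bootstrap aborts the
run: such data are too unstable for the CIs to mean anything.

## Synthetic data generator

The generator emulates the target study design: 6 right-skewed PTS items
(5 categories), 10 roughly symmetric PTG items (6 categories), n = 406.
A ground-truth network is built with dense positive within-community
structure (density 0.6, weights uniform on [0.12, 0.32]) and 4 signed
bridges (2 positive, 2 negative) — the weight range is chosen so that
edges are individually recoverable at moderate n while the implied
precision I − W stays comfortably positive definite. If positive
definiteness fails, all weights are shrunk uniformly by 0.9 (preserving
the sign pattern) up to 50 times, then the construction errors out.
The latent correlation matrix is the unit-diagonal-rescaled inverse of
I − W, so converting the precision of the result back to partial
correlations round-trips exactly.

Preset thresholds are fixed constants: PTS items use (−0.25, 0.65, 1.45,
2.25), giving right-skewed marginals with a per-item mean near 0.9 (sum
score ≈ 5.6 of 24); PTG items use (−1.65, −0.95, −0.25, 0.45, 1.35),
giving a mild shift toward higher growth categories (sum ≈ 28 of 50).
They are stylized stand-ins — item-level marginal distributions for the
target population are not published, so the thresholds are design
constants, not calibrations.

A second preset (`weak_sparse_preset`, within-density 0.10, two bridges,
weights on [0.30, 0.40], n = 100) produces a near-empty network whose few
edges sit at the EBIC detection boundary for that sample size: the
estimated support flickers across subsamples, which is exactly the
unstable regime the CS coefficient should flag. The weight range is
deliberately *higher* than the default preset's — at n = 100 with γ = 0.5
an edge needs |w| ≳ 0.3 to be selected at all, and a preset with weaker
edges yields an entirely empty estimate, for which EI stability is
undefined rather than low.

What the simulator does **not** emulate: missing data, demographic
covariates, longitudinal dynamics, differential item functioning, or
local dependence violating the latent-normal assumption. Passing
recovery tests therefore demonstrates correctness of the estimators under
the polychoric model's own assumptions, not robustness to their
violation in real questionnaire data.

## Problem sizes used in tests and the acceptance script

Unit and property tests use n between 100 and 50,000 depending on what
they measure; full-pipeline recovery uses n = 2000. Bootstrap-heavy
checks use B = 100 per case-drop level and B = 40–200 nonparametric
replicates; the analysis drivers default to B = 200 / 50 per level with a
`--full` flag for B = 1000. These sizes are the package's documented
defaults for its own verification runs; production analyses should use
B = 1000 as configured in `RunConfig`.

## Known limitations

* The polychoric stage assumes ordinal items with a latent normal; no
  polyserial/tetrachoric special-casing, no weighted likelihoods, no
  standard errors for individual ρ (the network bootstrap supersedes
  them).
* No nonparanormal or mixed-graphical alternatives; no Bayesian GGM.
* No network-comparison tests between subgroups.
* Plot rendering is out of scope; the GraphML export (with community
  attributes) is the supported path to visualization.
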
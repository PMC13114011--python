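# Methods

`symptomnet` implements a symptom-network analysis of anxiety–depression
comorbidity as measured by the PHQ-9 (nine depression items) and GAD-7
(seven anxiety items), with optional NMP-Q (nomophobia) screening columns.
This note documents the models, the estimators, the synthetic data the
package is validated on, and the numerical choices that were genuinely
open.

## The Ising symptom network

Item scores (0–3) are binarized to present/absent (`score > 0` → 1),
following the screening convention that any endorsement counts as symptom
presence. The joint distribution of the binary symptom vector
x ∈ {0,1}^p is modeled as a pairwise Markov random field,

P(x) ∝ exp( Σᵢ τᵢ xᵢ + Σ_{i<j} ω_{ij} xᵢ xⱼ ),

where ω (edge weights, log-odds units) encodes conditional pairwise
associations and τ (thresholds) each symptom's disposition to be active
when its neighbours are inactive. In this {0,1} parameterization a
negative threshold means the symptom defaults to inactive, which is how
screening items behave in mostly sub-clinical cohorts.

### Estimation (eLasso)

Each node is regressed on all others by L1-penalized logistic regression
over a descending grid of 100 penalty values, log-spaced from the
smallest all-zero penalty λ_max down to 10⁻³ λ_max. Per node the penalty
is chosen by the extended BIC,

EBIC(λ) = −2·ℓ + k·log n + 2γ·k·log(p−1),  γ = 0.25 by default,

with k the number of nonzero slopes. Directed coefficients are
symmetrized with the AND rule (an edge survives only when both
regressions select it); the surviving weight is the mean of the two
directed coefficients (a `min` combiner is available). Thresholds are
the intercepts of the selected penalized fits; an unpenalized refit of
intercepts is deliberately not performed, so thresholds and weights come
from the same fit.

The path solver is iteratively-reweighted least squares with cyclic
coordinate descent on the quadratic approximation, warm-started along
the grid, with an unpenalized intercept. Inner passes stop when the
largest curvature-weighted squared coefficient update falls below 1e-7
(the customary criterion for this solver family), the outer loop when
the linear predictor moves by less than 1e-4 in sup-norm; up to 10,000
inner passes are allowed. Tests cross-check the solver against an
independent reference (liblinear) at matched penalties; agreement is at
the 10⁻³ level, limited by the reference's slightly penalized intercept.
Nodes with prevalence below 0.02 or above 0.98 trigger a near-separation
warning, not an error; penalty values whose fit fails to converge are
flagged and excluded from selection.

### Centrality

One-step expected influence EIᵢ = Σⱼ ω_ij and bridge expected influence
(the same sum restricted to nodes of the other, a-priori community:
PHQ items = depression, GAD items = anxiety). Centralities are
z-standardized across nodes (n−1 SD) and nodes with z > 1 (strict) are
flagged. Two-step variants are out of scope. Bridge EI is reported only
for the combined network, where both communities are present.

### Stability and accuracy

Nonparametric bootstrap (default B = 1,000 row resamples, refitting the
entire eLasso pipeline each time) yields 95% percentile CIs per edge and
paired difference tests for edges and node EIs (significant when the 95%
quantile interval of the paired bootstrap differences excludes zero;
unadjusted for multiplicity, with the usual caveat that these are
descriptive diagnostics). The case-dropping bootstrap refits on
subsamples of (1−d)·n rows for d in {0.1, 0.2, 0.25, 0.3, 0.4, 0.5,
0.6, 0.7, 0.75} and records the Pearson correlation (Spearman optional)
between full-sample and subsample centralities. The
correlation-stability coefficient is the largest d such that at every
tested proportion up to d the empirical 5th percentile of those
correlations is at least 0.7; the "up to d" guard prevents a
non-contiguous pass at a high drop rate from inflating the coefficient.
Values above 0.25 / 0.5 / 0.75 are conventionally read as acceptable /
good / excellent.

### Binarization check (GGM + Mantel)

To check that binarization preserves structure, a Gaussian graphical
model is estimated on the raw ordinal scores: graphical lasso on the
item Pearson correlation matrix over a 50-value path, selected by the
GGM form of the EBIC with γ = 0.5 (the customary default for this
estimator; the Ising γ = 0.25 is separate and explicit). Precision
entries are converted to partial correlations ρ_ij = −κ_ij/√(κ_ii κ_jj).
The binary (Ising) and continuous (partial correlation) matrices are
compared with a permutation Mantel test: Pearson correlation of
lower-triangle entries, null built from simultaneous random row/column
relabelings, two-sided p with the add-one correction. Signed entries are
correlated (not absolute values); Pearson r is scale-invariant, so
comparing log-odds weights with partial correlations is coherent.
Polychoric correlations are not implemented; raw-score Pearson input is
the default and only option.

### Intervention simulation

For each symptom and direction, the symptom's threshold is shifted by
∓2 × SD(τ̂) (alleviate/aggravate), where SD is taken across the fitted
threshold vector (n−1 denominator). A per-node bootstrap SE of a single
threshold is not obtainable from one fit and is not used. Each condition
is simulated with 5,000 Metropolis–Hastings samples (single-site-flip
proposals, sequential sweeps, burn-in 1,000 sweeps, thinning 1, chain
initialized from the independent model); the default seed is 123 and
every condition gets an independent, deterministically derived stream. A
common-random-numbers mode (all conditions share one stream) is
available to reduce Monte-Carlo variance of the outcome but is off by
default, mirroring the one-simulation-per-condition design. The outcome
per symptom is |E[sum score]_perturbed − E[sum score]_baseline| with the
sum score the number of active symptoms; symptoms are ranked by outcome
(ties broken by node order, logged). Reported intervals are 2.5%/97.5%
percentiles of per-sample sums — spread of the sampled states, not a
standard error of the mean.

The sampler's correctness is anchored to exact enumeration of the 2^p
state space (feasible for p ≤ 20): expected sums and marginals must
agree within 3 batch-means Monte-Carlo standard errors, and alleviating
interventions can never increase the exact expected sum in attractive
(all-positive) networks, which the test suite verifies by enumeration.

## Preprocessing rules

- Response-time screen: participants averaging under 2 s per item are
  removed as insufficient-effort responders; slow outliers exceed the
  Tukey fence Q3 + 1.5·IQR with quartiles by linear interpolation (the
  common spreadsheet/statistics convention). The fence is computed after
  fast-responder removal by default (the order in which the screens are
  usually reported); a `before` switch covers the other reading.
- NMP-Q severity from the mean item score: none (= 1), mild (1–3),
  moderate [3, 5), severe (≥ 5); inclusion = mean > 1.
- PHQ-9 bands 0–4 / 5–9 / 10–14 / 15–19 / 20–27; GAD-7 bands 0–4 / 5–9 /
  10–14 / 15–21; caseness at strict > 9 on either total, giving four
  mutually exclusive comorbidity groups whose percentages are rounded to
  one decimal.
- Descriptives report n−1 SDs, bias-corrected skewness and *excess*
  kurtosis (normal = 0); constant items get NaN shape statistics. Rows
  with any missing PHQ/GAD item are dropped at load with a logged count
  (no imputation).

## Synthetic data: what it emulates, what it does not

The package ships a generator rather than data.

- `make_ground_truth` draws two-community (9 + 7 node) Ising models with
  exactly round(density × block size) edges per block — defaults
  reproduce the canonical 33/20/34 within-depression / within-anxiety /
  cross-community split — with uniform all-positive weights and uniform
  all-negative thresholds. Default ranges (weights 0.15–0.6, thresholds
  −3.1 to −1.55) were fixed once so that exact-enumeration symptom
  prevalences land in a realistic screening band (~0.12–0.40) while the
  87-edge graph remains estimable at n = 1,638: pilot runs of the
  recovery harness at that size give mean edge specificity ≈ 0.81 and
  true-vs-estimated weight correlation ≈ 0.72 over ten seeds. Real
  cohorts have stronger, sparser hubs; the uniform-weight assumption is
  the main simplification.
- `generate_ordinal_panel` draws 0–3 Likert items from a Gaussian copula
  whose per-item cut points are solved from target endorsement
  prevalences (defaults: the package's reference targets spanning
  0.23–0.67, hit within ±0.03 at n = 1,638), with endorsed mass decaying
  geometrically (ratio 0.5) across categories 1–3 to mimic right-skewed
  screening marginals. The default latent correlation is a jittered
  two-block structure (within-community ~0.35–0.55, cross ~0.15–0.30),
  eigenvalue-repaired to a proper correlation matrix. Higher moments
  (skewness/kurtosis) are consequences, not calibration targets.
- `generate_response_times` plants exact counts of sub-2-second and
  extreme (60–120 s) responders in a 2.5–9.5 s bulk so filter recovery
  is checkable by construction.

Passing tests on these data show the estimators recover the structures
they were pointed at under clean, correctly specified conditions; they do
not show robustness to ordinal measurement error, unmodeled severity
information lost to binarization, or non-copula dependence in real
surveys.

## Problem sizes in tests

The test suite and the acceptance script run the bootstrap machinery at
reduced sizes chosen as the package's own validation budget: bootstrap
determinism at n = 400 with B = 200 resamples, case-dropping stability
at n = 1,638 with B = 25 over three drop proportions and a 30-value
penalty grid, sampler checks at 30,000 draws, recovery at the full
n = 1,638 over 5–10 seeds. CS-C on the default synthetic cohort at
n = 1,638 lands around 0.1–0.25 depending on the panel seed — lower than
the 0.36–0.67 reported for comparable real cohorts, as expected for the
generator's weaker uniform couplings — and the test suite pins the value
of one exact seeded configuration as a regression constant, not a
quality claim.

## Known limitations

- The AND-rule + EBIC(γ=0.25) combination is conservative; weak true
  edges (|ω| ≲ 0.2 at n ≈ 1,600) are routinely missed, which bounds the
  attainable weight correlation in recovery experiments.
- Thresholds come from penalized fits and are biased toward zero at
  strong penalties; NIRA perturbation magnitudes inherit the SD of that
  vector.
- The MH sampler is a single chain per condition; intervals on expected
  sums reflect state spread, and outcome differences at 5,000 samples
  have Monte-Carlo noise of order 0.05–0.1 on 8–16-node networks (use
  the common-RNG mode or more iterations to tighten rankings).
- The Mantel permutation null treats nodes as exchangeable; it tests
  structural similarity, not distributional equality.
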
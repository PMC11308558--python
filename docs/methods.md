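# Methods

## Scope and the blinding principle

`idascreen` screens the three data domains that matter before a
multivariable regression is fit — missing values, univariate distributions,
and the multivariate predictor space — under one hard constraint: no
statistic may involve the outcome jointly with a predictor. The outcome
appears only in its own univariate summary and in the definition of a
complete case. The package enforces this mechanically rather than by
convention: `blind_outcome` permutes the outcome column with a seeded
uniform permutation before screening (default on). A missing outcome cell
travels with its permutation slot, so the outcome's item-missingness
proportion and value multiset are preserved exactly; consequently every
legitimate screening output is invariant under blinding, which the test
suite asserts output-by-output, including the rule-engine findings.

Data cleaning is assumed done upstream: values outside declared plausibility
limits are loaded unchanged and counted, never corrected.

## Missingness screening

Item missingness is a per-variable count/proportion. The complete-case
cascade reports, for the outcome alone and for each candidate model set, the
number of rows with no missing value in the outcome or any member; rows with
a missing outcome are incomplete everywhere. Because the candidate sets are
nested, the cascade is monotone — asserted as a property test against
brute-force row enumeration.

The pattern summary is the discordance matrix
`d(i,j) = P(exactly one of i, j missing)`, an exact fraction, not an
estimate. It is a metric on missingness indicators with the envelope
`|p_i − p_j| ≤ d(i,j) ≤ min(1, p_i + p_j)`; a variable missing together with
another (one shared assay panel) has `d` far below the sum of marginal
proportions. Agglomerative clustering on `d` uses average linkage by default
(complete/single selectable): no linkage is canonical for this distance, and
average linkage yields intermediate merge heights that remain interpretable
as typical discordance between groups. The tree is serialized as Newick with
branch lengths equal to height differences, leaves annotated with missing
percentages.

Group contrasts for complete-vs-incomplete cases use standardized mean
differences (continuous structural variables) or per-level proportion
differences (categorical) — deliberately **no hypothesis tests**, since
inferential screening output invites post-hoc reasoning. Continuous
structural variables are stratified by decades clipped to the observed range
unless the plan supplies explicit bin edges; strata under 10 rows are
flagged rather than suppressed.

## Univariate screening

Continuous summaries report min/max, a configurable quantile set (two
presets: 5/10/25/50/75/90/95% and 1/5/25/50/75/90/99%), mean, SD, IQR, the
number of distinct values, the five lowest and highest values, the modal
value with count, and the Gini mean difference
`GMD = Σ_{i≠j}|x_i−x_j|/(n(n−1))`, computed by the sorted-prefix identity
`Σ_{i<j}(x_(j)−x_(i)) = Σ_i (2i−n−1) x_(i)` (O(n log n)) and validated
against the O(n²) definition in tests. Quantiles follow the
linear-interpolation convention of the empirical distribution; no convention
is canonical for reporting and the choice does not propagate into any
decision rule.

A *spike* is flagged when the modal proportion reaches the plan threshold
(default 0.40, boundary inclusive). The threshold is chosen to catch
zero-inflated rare-cell counts (zero proportions near 0.9 and 0.5 in the
motivating setting) while sparing ordinary rounded lab values, whose modal
proportions stay far below 0.4 at realistic sample sizes. The concentration
ratio (modal frequency over average frequency per distinct value, ≥ 1 with
equality for both all-distinct and constant data) is reported as supporting
evidence.

## Transformation selection

Two candidate symmetrizing transforms are evaluated per continuous
predictor:

- pseudo-log `asinh(x/(2σ))/ln b` — total on the reals, antisymmetric, zero
  at zero, asymptotically `log_b(x) − log_b σ`; defaults σ = 1, b = 10,
  overridable per variable in the plan;
- signed cube root `sign(x)|x|^{1/3}`.

Success is judged by the normal-scores correlation: Pearson correlation of
the sorted sample with standard-normal quantiles at Blom plotting positions
`(i − 3/8)/(n + 1/4)`. The statistic is location–scale invariant, so the
choice of plotting-position convention is immaterial in practice. Ties keep
their raw values in stable sorted order. The statistic requires at least 3
observations and a non-constant sample; the selection step additionally
treats fewer than 3 distinct values as "not assessable".

Pseudo-log is adopted iff its gain over the raw predictor exceeds 0.2
correlation units; else the cube root iff its gain exceeds 0.2 and beats the
pseudo-log's. Two boundary behaviours are worth knowing:

1. For a lognormal margin the asymptotic gain crosses 0.2 at roughly
   σ_log ≈ 1, so predictors near that skewness flip between "pseudolog" and
   "none" by sampling variation. This is a property of the criterion, not
   of the implementation; the planted-structure tests therefore assert the
   choice only for σ_log ≥ 1.2 (decisively skewed) and ≤ 0.2 (decisively
   symmetric).
2. A variable whose values are of the same order as σ (e.g. a bilirubin-like
   lab with median < 1 under σ = 1) sits in the pseudo-log's *linear* regime,
   so the transform honestly achieves little; setting a per-variable σ in
   the plan is the remedy, and the plan file makes the σ convention explicit
   precisely because results depend on it.

Chosen transforms materialize as `t_`-prefixed columns; being strictly
monotone they leave all rank statistics unchanged (asserted to machine
precision), so they affect only moment-based displays, Pearson correlations
and the spline fits.

## Multivariate screening

Correlation matrices are pairwise-complete (entries under `min_pairs = 30`
complete pairs flagged unreliable), Spearman with average ranks for ties;
pairwise-complete equals complete-case exactly when nothing is missing.
Binary variables enter as 0/1 numerics; Spearman on a binary variable is a
rank-biserial correlation up to sign — documented, not hidden. Categorical
structural variables (sex) are excluded from the all-pairs screen; their
associations are covered by the per-stratum tables.

Pairs where Spearman and Pearson differ by more than 0.1 are listed for
scatterplot review (outliers inflate Pearson; curvature inflates Spearman).
Variable clustering uses distance `1 − ρ_S²` — squared so that strong
negative association also clusters — with average linkage, and lists pairs
with ρ_S above 0.8.

VIFs are computed on the complete cases of each candidate set, outcome
excluded. Linear basis: the diagonal of the inverse correlation matrix.
Additive basis: each continuous predictor expands into a restricted cubic
spline (truncated-power form, linear beyond boundary knots; 4 knots for key
predictors, 3 otherwise, at equally spaced quantiles between 0.05 and 0.95 —
the flexibility hierarchy mirrors the intended model, where key predictors
get more degrees of freedom), multi-level categoricals into indicator sets.
Group VIFs use the generalized-VIF determinant formula
`GVIF_j = det(R_11) det(R_22) / det(R)` via `slogdet`, reported both raw and
as `GVIF^{1/df}` (the square of the `GVIF^{1/(2 df)}` convention) so that
single-column groups reproduce the ordinary VIF. A correlation matrix with
condition number above 1e12, or a non-positive subdeterminant, yields an
explicit infinity marker per variable rather than numerical noise or an
exception; reports display it as "≥ 10⁶".

Redundancy analysis iterates: fit every remaining predictor on all others
with the additive basis (OLS via least squares), remove the predictor with
the largest R² while it exceeds 0.9, re-fit. A categorical target's R² is
the maximum over its indicator columns. Degenerate fits (constant target,
no usable regressors) are skipped with a notice. Sets larger than 25
members are skipped by the pipeline with a notice — VIF already covers the
full set, and pairwise spline refits on near-singular wide sets produce R²
values indistinguishable from 1 anyway.

## Consequence rules

Each rule is a deterministic threshold check against bundle values; the
emitted evidence is copied verbatim from the bundle (tested for exact
equality), findings are sorted by (rule, variables) so evaluation order is
immaterial, and the engine only recommends — no variable is ever dropped or
recoded automatically, matching the advisory role of screening relative to
the modeling team. Thresholds: spike ≥ 0.40 modal proportion; omission
> 1/3 missing; review > 0.20 missing; shared-missingness blocks at pairwise
discordance < 0.05 (such variables cannot serve each other in imputation
models); collinearity at ρ_S > 0.8, specialized to a part–whole
reparameterization (`whole − component` derived variable) when the
dictionary links the pair, or to ratio redundancy when one member is a
derived percentage of the other; sparse categorical levels below 10
observations, with the dictionary's collapse suggestion when present. The
0.05 discordance and minimum level count of 10 are package choices where
only the principle is established; both are plan-overridable.

## Synthetic study

The generator's default is the package's reference study: n = 2000 rows
and 51 predictors — age and sex (structural, never missing), a five-part
leukocyte composition block, and 38 lognormal labs with log-SDs from 0.03
(sodium-like) to 1.5 (acute-phase-like). The composition block draws
Dirichlet shares (mean 0.62/0.25/0.08/0.04/0.01, concentration 60) of a
lognormal total, records the whole as the sum times `exp(N(0, 0.05))` noise,
zero-inflates the two rare components at 0.87 and 0.48 *before* computing
the percentage variables (so ratios inherit the spikes, and their planted
spike probabilities are recorded in the ground truth), and links everything
in the dictionary via `component_of`/`ratio_of`. Rank correlations between
chosen lab pairs (red-cell panel 0.86–0.93, platelet-volume pair 0.85,
transaminase pair 0.75) are planted through a Gaussian copula on latent
normals using `ρ_S = (6/π) asin(r/2)`; jointly infeasible plants are
rejected with the offending pairs named. Missingness is imposed last:
shared per-row indicators for three lab panels (probabilities 0.35, 0.25,
0.18), independent per-variable missingness for twenty further labs
(0.02–0.22), and an optional logistic dependence of missingness on a
structural variable for non-MCAR tests. The outcome is Bernoulli(0.08)
independent of all predictors — honest to the blinding principle — with an
optional planted effect used solely to demonstrate that blinding destroys
it.

What the generator does *not* emulate: real marginal shapes beyond
lognormality (no digit preference, no detection-limit censoring other than
the zero spikes), between-lab correlations beyond the planted pairs and the
composition block, and any outcome model. Passing the recovery suite
therefore shows that each screening stage detects the structure it claims
to detect at realistic effect sizes — not that the thresholds are optimal
for any particular real dataset.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded from the
plan (or the generator spec); identical inputs and seed reproduce
`results.json` byte for byte, which is why the blinding record's timestamp
is kept out of machine-readable output. JSON output is loss-free (full
float precision; NaN → null, infinities → "inf"); human-readable reports
round to 3 significant digits. Correlation entries with fewer than 2
complete pairs are undefined (NaN) and excluded from clustering with a
notice. Constant spline columns (e.g. on heavily spiked variables) are
dropped from designs before VIF/redundancy. Problem sizes in the tests
(200–3000 rows) and the acceptance script (2000 rows) are the package's
reference conditions chosen so every stage's planted signal is several
standard errors wide.

## Known limitations

- Single-outcome designs only; no exposure blinding for causal workflows.
- No missingness-mechanism tests and no imputation — screening informs
  those choices but does not make them.
- The redundancy loop uses unpenalized OLS; with very wide sets relative to
  complete cases it is skipped rather than regularized.
- Spearman on heavily tied (spiked) variables is dominated by the tie mass;
  ratio-vs-component correlations for spiked components are high partly for
  that reason — which is also true, and acknowledged, in real laboratory
  data.
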
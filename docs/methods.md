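# Methods

## Preference elicitation

### Risk: ordered lottery menus

The gain-domain instrument is a six-lottery menu (labelled A–F, safest
first), each lottery paying a low or high amount with probability 1/2.
Under expected utility with constant relative risk aversion,
`u(x; r) = x^(1−r)/(1−r)` (log utility at `r = 1`), a respondent choosing
lottery k reveals `r` between the indifference points with the adjacent
lotteries. Indifference points are found by Brent's method on the
expected-utility gap using the affine-shifted utility
`(x^(1−r) − 1)/(1−r)`, which represents identical preferences at every `r`
but is continuous across the log-utility point, so one bracketed solve
covers roots on either side of 1. The default bracket is (−10, 10): far
outside it the shifted utilities of all payoffs collapse toward `1/(r−1)`
and their differences fall below float resolution, so a wider bracket only
degrades the solve. The six intervals partition the real line; ties at an
indifference point are assigned to the safer interval (closed on the left),
a measure-zero convention that keeps the partition exact.

The loss-domain menu contains negative payoffs, for which the CRRA power
function is undefined; that menu is treated ordinally throughout (6-point
scale and a loss-free/loss-bearing binary), and `menu_crra_intervals`
refuses menus with losses rather than silently offsetting payoffs.

### Time: multiple price lists

Each MPL row offers a sooner amount (here £25, paid in two weeks) against a
larger future amount. Under exponential discounting the row's indifference
rate is `d = (FV/PV)^(1/t) − 1` with `t` the sooner-to-future delay in
weeks. A monotone sooner→future pattern brackets the weekly rate between
the last-sooner and first-future rows; always-sooner responders get
`[top bound, ∞)`, immediate future-takers `(−∞, first bound]`. Non-monotone
patterns are coded at their first switch and flagged; downstream fits carry
the flag as a covariate rather than dropping these respondents.

The instrument file stores the delays as `t = 2.43` weeks (1-month panel)
and `t = 6.71` weeks (2-month panel). The source tables print bounds but
not day counts; these two values reproduce all twelve finite printed bounds
at 4-decimal precision (verified exhaustively in the test suite), and a
least-squares fit of `1/t` to the printed bounds returns the same values,
so they are frozen in configuration, not code.

### Binary collapses

Planning horizon (7 ordinal levels from "does not plan" to "longer than 10
years") collapses to an indicator for planning beyond the next year
(levels 4–6). Childhood disadvantage is the count of four binary adverse
dimensions (parental education, carer occupation, housing amenities,
family instability), collapsed at the conventional ≥2 threshold; the
threshold and dimension set are configurable. Three missing-data policies
are implemented: missing-as-zero (default, matching the source study's
power-preserving choice), missing-indicator (same imputation plus a
missingness flag intended as a model control), and complete-case (subjects
with any missing dimension flagged for exclusion).

## Genetics

Polygenic scores are the plain weighted allele-count sum; no SNP selection,
LD handling, or imputation happens here — weights are upstream inputs, and
all supplied SNPs are used. Scores are standardized within the analysed
sample (the deposited-score standardization population is generally
unknowable downstream). Fractional dosages are accepted with a warning
since the formula is coding-agnostic. Ancestry PCs come from the SVD of
the mean/SD column-standardized genotype matrix (zero-variance SNPs
dropped); each component's sign is fixed by making its largest-magnitude
loading positive so results are reproducible across linear-algebra
backends. Group descriptives use the pooled-variance two-sample t
(df = n − 2), Cohen's d with pooled SD and a normal-approximation CI, and
Pearson correlations with Fisher-z intervals.

## Estimation

### Interval-censored Gaussian regression

The latent outcome follows `Y* = Xβ + ε`, `ε ~ N(0, σ²)`; a row contributes
a normal density (point-valued), a CDF difference (bounded interval), or a
single tail probability (half-infinite). The CDF difference is evaluated in
whichever tail is better conditioned and score ratios are computed on the
log scale, so rows that sit many SDs from the current mean do not underflow
during optimization. σ is optimized as log σ; by default the GxE wrapper
gives each moderator group its own σ, which makes the single fully
interacted fit numerically identical (parameters and log-likelihood) to two
separate group-wise fits — the literal meaning of "all parameters differ by
group". A shared-σ option exists for the conventional pooled model.
Starting values are OLS on interval midpoints (finite bounds for
half-infinite rows). Optimization is BFGS on the analytic gradient with a
Newton polish step; fits report the final gradient norm and raise if it
exceeds 1e−4 (the routine targets 1e−8). Covariance is the inverse observed
information, obtained by centered differencing of the analytic gradient.

### Logistic and ordered-logistic regression

The logit fit is Newton–Raphson with step-halving; a coefficient diverging
past ±30 raises an explicit separation error rather than returning a
pseudo-converged fit. The proportional-odds model uses the cumulative-logit
parameterization `P(y ≤ j | x) = logistic(κ_j − xβ)` with thresholds
optimized as `(κ_1, log successive differences)` — strictly ordered by
construction — and reported on the κ scale with delta-method covariance.
Both fits expose per-observation scores; the ordered model's are mapped
through the threshold Jacobian so the sandwich assembles on the internal
scale and transforms once at the end.

### Cluster-robust covariance

Scores are summed within clusters; the sandwich uses the model-based
covariance as bread and a `G/(G−1)` small-sample factor. With singleton
clusters this reduces exactly to the HC0 sandwich times `n/(n−1)`, which
the tests assert. One cluster is an error, not a warning.

### Proportional-odds diagnostic

The check fits the J−1 cumulative splits as separate binary logits and
contrasts their slope vectors with a Wald statistic using the joint
covariance of the split estimates (splits share observations; the
cross-split weight for nested splits j < l is `π_l − π_j π_l`), referred to
χ² with (J−2)·p df. This is the standard split-logit construction; a
summed-split likelihood-ratio variant was evaluated and rejected because
composite likelihoods are not χ²-calibrated (null rejection collapsed to
~0). The split fits are working models, so the test is approximate; that
caveat is carried in the returned record, and sparse or separated splits
skip the test with a note instead of failing the run.

### Contrasts and profiles

The implied effect for the moderated group is `β_main + β_interaction` with
delta-method variance `V_mm + V_ii + 2V_mi`; the test suite verifies the SE
against the reparameterization oracle (recode the moderator baseline and
read off the main effect). Odds-ratio transforms apply to the logit
families. Prediction profiles place covariates at estimation-sample means
(configurable only by supplying a different grid/means; the source figures
do not state their policy, and sample means are the common default), span
the predictor over ±2 SD per group, and report delta-method bands — on the
linear predictor for the interval model, through the logistic link for
binary outcomes, and on the category-probability scale for ordered
outcomes (where bands may touch the [0,1] boundary since the delta
approximation is linear).

## Sensitivity power analysis

For a single-df predictor in a linear model with n observations and
n_params estimated parameters, the detectable effect solves
`P(F' > F_crit) = power` where `F_crit` is the α critical value of
`F(1, n − n_params)` and `F'` is noncentral F with `λ = f²·n`. The λ = f²·n
convention (rather than f²·df_denom) reproduces both published values at
their printed rounding; the result is insensitive to n_params anywhere
between 5 and 30 at 3-decimal precision, and the default n_params = 28
corresponds to the fully interacted design (2 × (intercept + PGS + age +
age² + sex + 10 PCs)). Both f² and partial R² = f²/(1+f²) are reported; at
the magnitudes involved they agree to the precision the study prints.

## Synthetic-data generator

The generator's defaults are the study conditions: n = 624 (single-wave
experimental preset) or 5,881 persons with ~11,521 person-wave rows (survey
preset); age uniform on 50–75 (experimental), 53.7% female; four
disadvantage dimensions at marginal prevalences 0.498 / 0.276 / 0.237 /
0.152; per-dimension missingness 0.10 (chosen so the share of subjects
missing exactly one dimension lands near the reported ~29%); MPL
inconsistency rates 60/624 and 47/624 on the two panels.

Genotypes are independent biallelic SNPs (frequency uniform on 0.05–0.95,
counts binomial), 200 SNPs by default — enough for a smooth, approximately
normal score; no attempt is made to match real LD structure, platform
effects, or attrition. Each disadvantage dimension is Bernoulli with
log-odds `a_k − 0.10·PGS`, intercepts root-found to hit the marginal
prevalence; the −0.10 slope was calibrated once so the PGS /
binary-index correlation sits near the reported −0.07 (realized ≈ −0.075
at n = 400k). Generating the index from dimensions rather than directly is
what lets all three missingness policies be exercised.

Latent preferences follow group-varying linear models whose default
coefficients mirror the reported group-specific estimates in sign and
magnitude: CRRA latent slope −0.368 without disadvantage, interaction
+0.799, Gaussian noise SD 1.4; weekly discount latents −0.021/−0.007 and
−0.011/+0.007 with SDs 0.05/0.03; the loss-menu scale and planning horizon
use their own linear predictors (slopes −0.350/+0.715 and +0.199/−0.131)
with *logistic* noise thresholded into ordinal levels, which makes the
rendered scales exact proportional-odds outcomes and their binary
collapses exact logit models. The loss-menu scale is deliberately not a
deterministic map of the CRRA latent: the loss menu cannot be inverted
through CRRA utility, and an ordinal outcome fitted by proportional odds
needs a logistic disturbance to be well-specified. No published estimate
pins the latent (pre-instrument) scale, so these are documented presets,
not facts about the study.

Rendering: gain-menu choice is the brute-force expected-utility argmax at
the latent `r`; MPL rows take the future option iff `FV/(1+d)^t > PV`, then
with the configured probability one uniformly chosen row is flipped and the
subject marked inconsistent in the truth sidecar (a flip adjacent to the
switch row can leave the pattern monotone, so observed inconsistency runs a
little below the injected rate — as in real data, where only multi-switch
patterns are detectable). The survey preset adds a person-level normal
random intercept (SD 1.0) to the planning propensity and redraws the wave-2
response around the same propensity, inducing the within-person correlation
that makes cluster-robust errors consequential.

Everything is driven by one mandatory seed through a single generator
stream; identical configs give byte-identical outputs.

## What the tests do and do not show

The calibration battery (200 replicates at n = 5,000 per model family,
checked against a 93–97% band for nominal 95% Wald coverage of the
interaction) runs on correctly measured moderator groups from the truth
sidecar: it validates the estimators and their standard errors, not
robustness to moderator misclassification — with missing-as-zero
imputation the observed index misclassifies some subjects and attenuates
the interaction, which is a property of the design being emulated, not an
estimator defect. Replicate counts and cohort sizes (200 × 5,000; 1,000
round-trip draws; 150-replicate cluster-coverage check at 250 persons × 2
waves) were sized to keep Monte-Carlo error well inside the asserted bands
while the full suite stays in the low minutes on a single core. Because the
generator draws independent SNPs and linear latents, passing tests say
nothing about LD-induced score artifacts, non-normal latent noise, or
selective attrition.

## Known limitations

- No alternative utility families (CARA, probability weighting) and no
  hyperbolic/quasi-hyperbolic discounting; the inversion layer is
  CRRA-plus-exponential by design.
- No within-family or random-effects estimation; clustering is handled only
  through the sandwich covariance.
- The interval model assumes homoskedastic normal latents within σ-group;
  there is no diagnostic for latent non-normality from interval data.
- Ancestry PCA standardizes by sample mean/SD of counts, not
  allele-frequency scaling; with real genotype panels the two differ.
- The power module applies the linear-model calculation to all outcome
  families, as the source analysis does; it is approximate for the logit
  and ordinal models.
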
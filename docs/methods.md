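# Methods

This note documents the models, numerical choices and known limitations of
`senosig`, and what the synthetic-data generators do and do not emulate.

## Differential abundance and senescence status

The catalog-side evidence unit is one (protein, cell type, induction)
comparison of senescent vs proliferating replicate arms on the log2 scale.
The package's differential-abundance engine is deliberately plain: per
protein, log2FC is the difference of arm means and the p-value a two-sided
Welch *t*-test, BH-adjusted across proteins within each (cell type,
induction) stratum. No variance moderation is applied — moderated
(empirical-Bayes) testing is out of scope, and the classification layer
accepts precomputed record tables from any external DE engine, so the
built-in engine is a documented stand-in rather than the point of the
package. Degenerate strata (zero variance in both arms) map to p = 1 when
the means agree and p = 0 when they differ exactly.

**Power limitation (important).** With 4 replicates per arm the Welch test
has ≈ 6 degrees of freedom. At the default planted effect (1.5 log2 units,
replicate SD 0.5) the median raw p is ≈ 0.005, which survives a BH
threshold of 0.05 only when a large fraction of the stratum carries signal.
Monte-Carlo power at q < 0.05 is ≈ 0.12 / 0.36 / 0.66 for planted fractions
0.1 / 0.2 / 0.4, and the two-induction membership rule roughly squares the
per-stratum recall. Consequently the default synthetic catalog recovers
only ~10–25 % of planted members — by design of the test, not a bug. Six or
more replicates per arm, or a moderated engine, would lift recall above
90 %; both are left to the user (`n_replicates` in `CatalogSimConfig`, or
external record tables). The recovered set is essentially free of false
discoveries (FDP ≈ 0), so derived signatures are conservative subsets of
the planted truth.

Membership rules: the default `ir-plus-chemical` requires qualifying
elevation in ionizing radiation plus at least one chemical inducer
(etoposide or doxorubicin); `any-two` accepts any two inductions. A protein
with no records for a cell type counts as "not elevated" there (this
matters for exclusivity) and proteins missing entirely are excluded with a
warning, never silently dropped. Exact tests for status-by-study detection
tables use scipy's hypergeometric 2×2 Fisher test and, for r×2 tables, an
in-package enumeration over margin-constrained tables with log-gamma
probabilities (the enumeration equals the hypergeometric oracle on all
small tables; it is intended for small r and moderate counts).

## Panel selection and composite scores

Elastic net uses mixing α = 0.5. Covariates enter the selection model
unpenalized: for gaussian traits this is implemented exactly via the
Frisch–Waugh identity (elastic net on covariate-residualized trait and
proteins has the same penalized optimum), solved by scikit-learn's
coordinate descent; for binomial traits statsmodels' elastic-net GLM with
per-coefficient penalty weights is driven along a warm-started λ path with
K-fold deviance cross-validation (folds stratified by outcome, seeded).
λ defaults to the one-standard-error point rather than the CV minimum:
measured on pure-noise pools of 200 proteins (n = 300–500), λ-min admits
3–13 spurious proteins while λ-1se admits essentially none, at identical
recall (1.0) for planted standardized effects of 0.3 — the parsimony
convention familiar from glmnet. λ-min remains available via
`ElasticNetConfig(lambda_rule="min")`.

Effects are reported on the internally standardized scale so the "top 25 by
effect size" ordering is scale-free; whether the original ordering used
penalized or post-selection effects is not stated anywhere authoritative,
and the penalized choice is exposed in the panel object. Sign filtering
keeps positively associated proteins for negative-health traits, inversely
associated proteins for positive-health traits, and both signs for
`polarity="any"` (used for chronological-age panels). Ties at the
truncation boundary break by larger |effect|, then lexicographic protein
identifier. Composite scores z-score each panel protein with the scoring
cohort's mean and sample SD (n−1) and average; zero-variance proteins are
dropped with a warning. Out-of-sample application (nested CV, transfer)
passes training-split statistics explicitly. The HIP threshold is
⌈n_traits/2⌉.

## Cross-validation protocols

The single-panel protocol selects once on the full cohort and then runs ten
independent 90/10 splits — this deliberately mirrors the biomarker-panel
use case and contains selection leakage; nested CV redoes selection,
truncation and z-scoring inside each training split and is the leakage-free
comparator. The package treats "single ≥ nested on average" as a
correctness property. Binary-trait test metrics report both the squared
correlation of predicted probability with outcome (a pseudo-R²) and AUC.
Degenerate binary test folds (one class) are redrawn, capped at 100
attempts. CV iterations resample splits independently; disjoint 10-fold
rotation was considered and rejected for fidelity to the repeated-split
protocol.

## Mediation, relative importance, paired comparisons

Mediation follows the potential-outcomes estimator: a linear mediator
model, a linear or logistic outcome model. In the linear-linear case
ACME = a·b and ADE = c′ in closed form, so total = ACME + ADE exactly; with
a binary outcome, counterfactual mediator values are simulated from the
fitted mediator model (default 100 draws) and effects averaged over both
exposure arms on the probability scale. CIs are percentile bootstrap over
participants (default 1000; fewer than 100 is rejected). Proportion
mediated is ACME/total. Relative importance is the two-predictor LMG
decomposition — each score's R² increment averaged over both entry orders
with covariates always in the base model — whose two importances sum to the
joint increment by construction; CIs again by percentile bootstrap.
Iteration-matched metric vectors are compared by paired t-test gated on a
Shapiro–Wilk normality check of the differences (p > 0.05), falling back to
Wilcoxon signed-rank with a flag; identical or constant-shift inputs take
an explicit zero-variance path.

## Sliding-window scan

Windows are half-open and contiguous: at center t the lower window is
[t−w, t) and the upper [t, t+w) with w = 10 by default, so a participant
aged exactly t is counted upward (the boundary convention is documented and
tested). Per protein the test statistic is the upper-window indicator
coefficient in a linear model with configured covariates (sex by default in
pooled scans); all proteins at a center share one design matrix, so the
scan is a single multi-target least-squares solve per center. BH is applied
within each center across proteins, not across centers. Peaks are the
center with the maximal elevated count, ties resolved to the smallest
center and flagged; centers skipped for empty windows are excluded.
Decade-balanced downsampling samples without replacement within
(decade × sex) strata and reports standardized mean differences
(mean difference over the pooled SD) between subsample and eligible pool.

## Survival models

Age is the time scale: participants enter the risk set at their measurement
age and exit at event or censoring age, so the partial likelihood uses
delayed-entry risk sets (entry < a ≤ exit). Fits use lifelines with Efron
tie handling and sex/race strata. Because scaled Schoenfeld residuals for
delayed-entry fits are not available upstream, the proportionality check is
computed in-package: per-event residuals against hazard-weighted risk-set
means (Breslow convention; event ages are continuous so ties are rare),
combined into the Grambsch–Therneau score statistic with an identity time
transform (KM transform available). Null calibration of both the Cox Wald
test and the Schoenfeld test is verified by simulation (≈ 5 % at α = 0.05).
Quartile trajectories rank by score with identifier tie-breaks, fit
delayed-entry Kaplan–Meier curves for the extreme quartiles and report
1 − S(age) with numbers at risk; zero-event groups yield flat curves. For
onset endpoints, prevalent cases at entry should be excluded by the caller.

## Seno-ages and gaps

The age model is unpenalized least squares of chronological age on the
panel proteins (selection and estimation separated); rank-deficient designs
resolve to the minimum-norm solution with a logged warning. The gap is the
residual of predicted age about its OLS trend on chronological age, fit on
the scoring cohort — hence mean-zero and exactly age-decorrelated there,
and invariant (up to scale) to affine transformations of the predictions. A
lowess trend is available but the linear default keeps gaps deterministic
and exactly decorrelated. Gap–trait models exclude age as a covariate by
default (re-includable). Transferred models refit the trend in the target
cohort so gaps stay mean-zero within each study. Correlation matrices are
computed on shared participants for both seno-ages and gaps, since the two
can differ materially (gaps remove the common age trend).

## Synthetic data: what it emulates, and what it does not

`simulate_catalog` plants, per cell type: exclusive members (disjoint
across cell types), shared members (2–8 random cell types), core members
(≥ 9 of 14), and single-induction responders. Planted members are elevated
by 1.5 log2 units in IR and one randomly chosen chemical inducer; replicate
noise is additive Gaussian on log2 intensities (log-normal abundances), SD
0.5, n = 4 per arm. The default 300-protein universe is ≈ 44 % planted
members, 10 % single-induction, 46 % null — proportions chosen to mirror a
realistic catalog where senescence programs overlap broadly between cell
types. Replicate count per arm is a free choice (real catalogs rarely state
it); 4 is deliberately austere, and its power consequences are described
above.

`simulate_cohort` gives each participant a uniform age, sex (configurable
balance), a biological-age offset δ ~ N(0, 5 y), and a latent senescence
burden m = a·sex + N(0, 1). Planted SAP abundances follow
0.03·(age + δ) + 0.1·m + N(0, 0.5) on the log2 scale — a strong aging
protein (~2.3-fold over 40 years) with a modest burden loading (~8 %
abundance shift per burden SD). These two defaults fix the "default SNR"
for seno-age gap recovery; because every planted protein shares the same
loadings, the age-offset and burden directions coincide in protein space
and cannot be separated by any estimator, so the loading must stay small
relative to the age slope for δ to be recoverable (measured gap–δ
correlation ≈ 0.70 at n = 1000). Outcomes follow the mediation triangle
(a, b, c′) = (0.5, 0.8, 0.4) on a linear link (frailty) and a logit link
(diabetes); event ages come from a Weibull proportional-hazards model on
the age scale (shape 6, scale 85 y, log-HR 0.5 per burden SD), sampled
conditional on survival to the entry age and censored administratively at
95 y. Optional change points add a piecewise-linear ramp — an elevated
slope of 0.06 log2/y over ±2.5 y around the change-point age (sex-specific
ages supported) on 50 planted proteins; the ramp, rather than a permanent
slope change, is what makes the windowed contrast peak at the planted age.
Change-point scenarios are generated with the age-drift and burden channels
off, isolating the planted nonlinearity: a shared burden factor otherwise
injects window-level noise common to all proteins that can produce coherent
spurious count peaks. `simulate_mediation_data` is a minimal
exposure/mediator/outcome triple for closed-form checks
(PM → ab/(ab+c′) as noise vanishes).

What the generators do *not* emulate: assay normalization artifacts, batch
effects, aptamer cross-reactivity, missing values, heavy-tailed abundance
distributions, correlated protein modules beyond the single burden factor,
informative censoring, or measurement-error structure in traits. Passing
tests therefore certify the statistical machinery against its own
assumptions, not robustness to real-cohort pathologies.

All generators draw from sub-streams of one `numpy.random.SeedSequence`
per call, so outputs are bit-for-bit reproducible and adding a table never
perturbs another. The pipeline records seeds, file hashes and per-stage
row counts in a manifest; a rerun with the same config is byte-identical.

## Problem sizes used in validation

The test-suite and acceptance-script scenarios use: 10 catalog seeds at 300
proteins; elastic-net runs at n = 500, 200 candidates; mediation point
estimates at n = 2000 with 1000 bootstrap draws and coverage over 100
datasets of n = 300 with 200 draws; Cox recovery at n = 1000 over 10 seeds
and null calibration over 200 simulations of n = 300; pooled sliding-window
scans on 480 balanced participants (120/decade) and sex-stratified scans on
960 (240/decade — at 120/decade a per-sex window holds only ~60
participants and the scan is underpowered to detect anything); seno-age
recovery at n = 1000 over 10 seeds. These sizes were chosen as the smallest
at which the estimators' sampling noise is clearly below the planted
signals.

## Known limitations

- The built-in DE engine is unmoderated; at small replicate counts its
  recall is intentionally reported rather than patched (see above).
- The r×2 exact test enumerates tables; for very large counts an asymptotic
  chi-square is the practical alternative (not implemented).
- Binomial elastic-net paths use a pure-Python coordinate-descent solver
  and are an order of magnitude slower than the gaussian route; loose
  convergence tolerances are used on the CV path.
- Mediation assumes sequential ignorability; no sensitivity analysis is
  provided. Competing risks and time-varying covariates are out of scope
  for the survival models.
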
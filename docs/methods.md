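# Methods

## Model

`dditraj` models daily-maximum D-dimer (mg/L) over the first 50 days after
trauma with a group-based trajectory model (GBTM): a finite mixture in which
each patient belongs to one of G latent groups and, conditional on group g,
the measurement on day t is

    y_it = beta_g' x(t) + eps_it,     eps_it ~ N(0, sigma^2),

with x(t) the polynomial basis in scaled time t/10 (orders 2-4 per group)
and a single residual SD shared across groups and occasions. The assay
reports values only inside [0, 40] mg/L, so observations at a bound are
treated as censored: a value at 40 contributes the upper-tail probability
mass P(y* >= 40 | mu, sigma), a value at 0 the lower-tail mass, and interior
values the normal density (Tobit likelihood). Occasions are conditionally
independent given group; the marginal likelihood of a patient is the
pi-weighted mixture of their per-group series likelihoods.

Assumptions worth stating plainly: no within-group random effects (every
member of a group shares one mean curve — the model partitions
heterogeneity rather than smoothing it); measurement days may be missing at
random given group (class-dependent follow-up length is fine, day-level
missingness related to the *value* is not); a common sigma (a per-group
sigma switch exists in the code path but is not the default).

## Estimation

Maximum likelihood by EM over two layers of latent data: the group labels
and, for bound observations, the latent uncensored values.

* E-step: posterior group probabilities in log space (log-sum-exp), plus
  first and second truncated-normal moments of the latent value for each
  censored observation under each group.
* M-step: with both expectations in hand, each group's coefficients solve a
  weighted least-squares problem in closed form; sigma^2 averages the
  expected squared residuals; pi is the mean posterior. No inner numerical
  optimisation is required and the observed-data log-likelihood is
  non-decreasing by construction (verified to 1e-8 in the test suite).

Multi-start: the first start cuts the cohort with k-means on per-patient
summaries (mean, early slope, max); remaining starts use random hard
assignments; the best final log-likelihood wins. Components whose mixing
weight falls below 1/n are pruned with a warning. After fitting, groups are
relabelled by ascending mean fitted level over days 0-10, so "group 1" is
always the lowest trajectory regardless of seed. Convergence: relative
log-likelihood change below 1e-6 (default), max 500 iterations.

Numerical choices: tail quantities use `log_ndtr`, never `1 - Phi`; the
truncated-moment variance terms are clamped at zero against cancellation in
the far tail; the polynomial basis is built on t/10 for conditioning, and
coefficients are reported on both the scaled and per-day axes.
Ties in the modal assignment resolve to the lowest group index.

## Model selection

The two-stage protocol:

1. Fit all-quadratic models with G = 1..6 groups; choose the G maximising
   BIC (expressed as loglik - (k/2) ln n, larger is better; k counts all
   polynomial coefficients, the free mixing proportions, and sigma).
   A parsimony margin (default 2) prefers the smaller G when its BIC is
   within the margin of the best — the code cannot judge "clinical
   plausibility", so the margin plus the emitted stage-1 table is the
   operational substitute.
2. With G fixed, search per-group polynomial orders in {2,3,4} (exhaustive
   3^G enumeration by default; a greedy one-group-at-a-time descent is
   available for speed). Among combinations with relative entropy >= 0.9,
   every assigned-group share >= 5%, and every group's average posterior
   probability of assignment (APPA) >= 0.7, the best BIC wins; if nothing
   passes, the best-BIC combination is returned with an explicit warning.

Stage-2 fits are warm-started from the stage-1 solution (coefficients
zero-padded to the candidate orders), which stabilises group identities
across combinations and cuts runtime roughly tenfold.

Diagnostics: relative entropy E = 1 + sum_i sum_g p_ig ln p_ig / (n ln G)
(1 = crisp, 0 = uninformative; defined as 1 for G = 1); APPA_g is the mean
posterior of a group's own assigned members; group proportions are modal
shares, matching how cohort tables are reported.

## Clinical scores and association analysis

TRISS survival probability uses the published mechanism-specific logistic
coefficients (blunt: b = -0.4499 + 0.8085 RTS - 0.0835 ISS - 1.7430 Age55;
penetrating: b = -2.5355 + 0.9934 RTS - 0.0651 ISS - 1.1360 Age55) with the
age indicator switching at 55 years. ISS is the sum of squares of the three
most severe region AIS values, 75 if any region scores 6. Missing region
AIS values are completed by k-nearest-neighbour imputation (default k = 5,
standardised Euclidean distance over age, BMI, SOFA and a mechanism
indicator, rounded neighbour median per region); ISS is recomputed after
completion.

The mortality association pipeline: univariate screen at p < 0.1
(single-predictor logistic for continuous variables; chi-square, or Fisher
for sparse 2x2 tables, for categorical); collinearity screen dropping one
of any pair with |Spearman r| > 0.5 (p < 0.05) — keeping the variable with
the smaller univariate p — and any variable with VIF >= 10, iterated to a
clean design; multivariable logistic with group 1 as reference and Wald 95%
CIs (separation symptoms flag the CI as unreliable); a sensitivity refit
swapping abdominal AIS for ISS; in-sample AUC by the rank statistic for
both the trajectory model and TRISS. Group-comparison tables use median
(IQR) + Kruskal-Wallis for continuous variables and n (%) + chi-square/
Fisher for categorical ones, with Benjamini-Hochberg adjustment of pairwise
tests. For omnibus r x c tables with small expected counts no exact test is
available in the stack, so chi-square is used with a warning; pairwise
tables are 2x2 and use Fisher.

## Synthetic cohort generator

The generator draws the world the model assumes: latent class from pi =
(0.576, 0.282, 0.084, 0.058) (the published group shares); per-class
polynomial mean curves emulating the four recognised patterns — stable low
(~1.4 mg/L flat), moderate-decline (8 falling to ~2), high-rapid decline
(high day 0, steep five-day drop, slight late rise; quartic) and
high-gradual decline (high early peak, slow resolution to ~day 25;
quartic); shared residual SD 1.5 mg/L (a plausible within-patient
measurement + biological noise for D-dimer on this scale); clipping to
[0, 40]; follow-up length geometric with class-dependent means
(10/18/22/30 days — sicker classes are tested longer, emulating protocols
that stop D-dimer testing when the patient stabilises); day-level sampling
at 0.8 with day 0 always recorded; death from class-specific logits
matching mortalities of roughly 4.5/9.2/7.7/27.8%. Covariates (age, sex,
BMI, SOFA, six region AIS, RTS, mechanism, treatment flags) have mild class
linkage so severity gradients resemble a trauma cohort.

A deliberate calibration: the quartic classes deviate from their best
quadratic approximation by only ~0.2-0.3 mg/L rms. Large quartic deviations
make the all-quadratic stage-1 protocol absorb shape misfit into spurious
extra components (a known behaviour of BIC under working-model
misspecification, aggravated by class-dependent follow-up); deviations of
this size keep the four-class structure identifiable at stage 1 while
remaining detectable at stage 2, where a higher order costs only ~2.9 BIC
per parameter. This was fixed while designing the generator and not
revisited afterwards.

What a green recovery test does establish: the estimator and the selection
protocol recover the truth when the data really follow a censored-normal
GBTM with well-separated classes. What it does not: performance under
within-class heterogeneity, value-dependent missingness, assay batch
effects, or transfer-in patients with unobserved early days — none of which
the generator produces. Per-day observation density in the source setting
is unknown; the sampling defaults are stated assumptions.

Two fixed fixtures encode published desk-checkable arithmetic: a
913-record screening roster whose sequential exclusions (fewer than three
D-dimer days: 227; re-admission: 197; interval > 14 days: 136; age <= 18:
41; cancer: 2; pregnancy: 1) leave 309 eligible, and the 4x2
group-by-mortality table (deaths/total 8/178, 8/87, 2/26, 5/18).

## Known limitations

* No covariates on class membership (no multinomial membership model) and
  no growth-mixture random effects.
* Wald intervals only by default; at the source study's scale (18 patients,
  5 deaths in the top group) Wald and profile intervals differ noticeably.
* The stage-1 "clinical plausibility" judgment is not automated; the
  parsimony margin is a crude stand-in.
* Exhaustive stage-2 search is O(3^G) fits; at G = 6 this is 729 fits and
  the greedy mode is recommended.
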
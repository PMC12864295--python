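# Methods

`hfrtrends` implements the statistical core of a wildlife-egg contaminant
monitoring analysis: long-running series of halogenated flame retardant
(HFR) concentrations in pooled herring gull eggs, analysed for temporal
breakpoints relative to Stockholm Convention regulatory milestones and for
spatial (regional) differences. This note records the models, the default
parameters and why they are set as they are, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Data model

The unit of observation is one pooled-egg homogenate x analyte measurement
(ng/g wet weight) with its method limit of detection (MLOD) and
quantification (MLOQ) and a detect flag. Limits vary by analyte and year,
so censoring metadata travels on every row. Non-detects never carry a
numeric concentration: they are left-censored observations whose only
usable datum is the limit itself. Four HFR classes are analysed: the
lower-brominated PBDE congener sum (proxy for the commercial penta- and
octa-BDE mixtures), BDE-209 (proxy for commercial deca-BDE, always kept
out of the congener sum), total alpha-HBCDD, and the sum of the syn- and
anti-isomers of Dechlorane Plus. A congener enters the PBDE sum only when
its study-wide detection fraction reaches 3% — re-derived from the data
rather than hard-coded, so the same rule generalises to other panels; on
the default panel it excludes BDE-190 and yields the familiar 11-congener
sum.

## Non-detect policy

Per colony and analyte (pooling years by default; a per-year grouping is a
config switch since either reading of "at each colony" is defensible):

* detection >= 50% (inclusive at the boundary — the boundary case is
  documented here because both "more than" and "fewer than" phrasings
  circulate): fit a log-normal by maximum likelihood where detected values
  contribute density terms and each censored value the normal CDF at its
  own ln limit. The m censored records then receive the m smallest
  plotting-position quantiles exp(mu + sigma * PhiInv(i/(n+1))), i=1..m.
  The i/(n+1) plotting position is chosen for symmetry with
  quantile-normal plotting; n is the group size. Replacement values are
  unique by construction and are assigned among the censored pools in
  ascending order of a frequently-detected reference analyte measured on
  the same pools (BDE-99 for PBDE congeners, syn-DP for HBCDD and
  anti-DP), falling back to deterministic pool-id order when the reference
  is missing. Ties in the reference break by pool id so reruns are
  identical. A fitted quantile at or above the record's MLOD is clamped
  just below the limit (and flagged): replacements must stay in (0, MLOD).
* detection < 50%: no replacement is estimable; non-detects are set to
  zero. A non-convergent ML fit is treated the same way and logged loudly,
  keeping the policy total.

Every value leaves the stage flagged `observed`, `imputed`,
`imputed-clamped` or `zeroed`. The estimator reduces exactly to the
ln-moment MLE with no censoring, and its bias shrinks as n grows (checked
at n = 50, 200, 1000 in the tests); `scipy.stats.CensoredData` is the
independent oracle in the test suite, not the implementation.

## Aggregation

Class values are summed per pool, then averaged arithmetically per
colony-year (a single pool passes through — pooled homogenates estimate
the mean of their eggs), then natural-log transformed. A colony-year whose
class mean is exactly zero (all pools zeroed) cannot enter ln-scale
fitting and is flagged and excluded rather than offset-adjusted; an
optional half-minimum offset was considered and rejected as the default
because it manufactures trend out of the censoring pattern. Egg volume
uses the Ryder formula v = 0.489 * l * d^2 (cm^3). Covariate screening
(egg mass, volume, percent lipid vs ln class means, per colony) uses
Pearson correlation, falling back to Spearman when Shapiro-Wilk rejects
normality of the straight-line residuals at alpha = 0.05 (the test is a
package choice; the screening convention named no test). Screening is
reported only — it never feeds back into the trend models.

## Segmented trends

Per colony x class the ln mean concentration is modelled as

    y_t = b0 + b1 * t + delta * (t - psi)_+ + e_t,    e_t ~ N(0, s^2)

with breakpoint psi, pre-break slope b1 and post-break slope b1 + delta.
Years enter uncentred so slopes are per calendar year. Estimation combines
the standard iterative linearisation (working covariates U = (t - psi)_+
and V = -1[t > psi]; update psi <- psi + gamma/delta) started from the
observed-year tertiles with an exact per-interval profile: between
adjacent observed years the point partition is fixed, so SSR(psi) is
smooth there and a bounded scalar minimisation finds each interval's
optimum; interior observed years enter as candidates directly. The best
admissible candidate by likelihood wins, ties toward the earlier
breakpoint. This makes the estimate a global least-squares optimum — the
test suite holds it to the SSR of an independent fine-grid oracle.
Admissibility requires at least two observed years strictly on each side
of psi (prevents boundary degeneracy; the minimum is configurable).

Point estimates, SSR, likelihood and AIC come from the continuous
three-column fit at the selected breakpoint — candidates must be ranked
on the model that is actually continuous. Standard errors come from the
augmented working model that adds the breakpoint-score column V: V is the
derivative of the mean with respect to psi, so its covariance
contribution propagates first-order breakpoint uncertainty into the
slope SEs, and psi's own SE is the delta-method ratio SE(gamma)/|delta|.
The residual variance and test df additionally charge one degree of
freedom for the estimated breakpoint (df = n - 5; four mean-structure
parameters b0, b1, delta, psi, matching the AIC parameter count of 5
with s^2). Without the V-column covariance and the df charge the slope
intervals are anti-conservative (conditional-on-psi coverage measures
86-90%); with them the 95% CI coverage sits at 94-96% in the recovery
suite. Reported per-row t and p follow the monitoring-table convention:
the t test of the first-segment slope for segmented fits, of the slope
for linear fits.

Model selection: a series shorter than 6 years is fit linearly. Otherwise
the segmented fit replaces the line only when it is admissible, improves
AIC, and the slope-change test is significant (each criterion separately
switchable, decision logged). The gate cannot be the naive t test of
delta at the *estimated* breakpoint: the breakpoint is absent under the
null and chosen by the fit, which makes that test anti-conservative
(measured ~10% at nominal 5% in this design). The default gate is
therefore an exact Monte-Carlo supremum test: the largest |t| of the
slope-change coefficient over a 10-point fixed breakpoint grid is
pivotal under the Gaussian no-breakpoint null (invariant to intercept,
slope and error scale), so its null distribution is simulated once per
year design (999 standard-normal draws, cached, deterministically seeded
from the design) and the p-value is exceedance-ranked — calibrated at
the nominal level up to Monte-Carlo discreteness. An analytic
Davies-bound alternative (`delta_gate="davies"`, t-process tail;
conservative, measured ~2-4%) and the conditional-t gate
(`delta_gate="conditional"`) remain available, and the conditional p is
always reported alongside.

## Milestone classification

Each fit maps to one of: IT (significant post-break increase), LI / NI /
EI (significant post-break decline with the breakpoint after listing /
after nomination up to listing / before nomination), CT (no breakpoint, a
significant monotone slope), or NS. Direction takes precedence: a
post-break increase is IT regardless of where the breakpoint falls. The
breakpoint is compared with milestones as a point estimate only (its SE
is reported, not used). Boundaries resolve inclusively upward (psi equal
to the listing or nomination year counts as the nomination-to-listing
window, NI) — boundary cases do not occur in the published table, so the
rule is documented rather than inferable. The registry defaults (PBDE sum
nominated 2005 — the earlier of the two commercial mixtures — listed
2009; HBCDD 2008/2013; BDE-209 2013/2017; DP 2019/2023) are a packaged
CSV and overridable in config. Percent annual change is
(exp(beta) - 1) x 100, with printed magnitudes rounded half away from
zero to integer percent; the rounding convention is validated against all
published conversions.

## Regional mixed model

For each HFR class the colony-year ln means y_ijk (colony j in region i,
year k) follow

    y_ijk = b0 + b_region(i) + u_ij + v_k + e_ijk

with sum-to-zero region contrasts (b0 is then the overall mean across
regions), u_ij ~ N(0, s2_colony), a crossed year effect v_k ~ N(0,
s2_year) and residual s2_resid. Colony-year means, not pool replicates,
are the observation unit — consistent with the trend stage; pool-level
fitting is a switch. Estimation profiles the (restricted) likelihood over
the two log variance ratios with a derivative-free simplex from three
deterministic starts, bounded at log-ratio +-20 so boundary fits (for
example one colony per region, which pins the colony variance at zero)
terminate cleanly and are flagged. The implementation is validated
against `statsmodels` MixedLM (variance components agree to ~1e-4 on
shared designs), which serves as the cross-check, never the fit path.

The region F test uses Satterthwaite denominator df via the standard
moment-matching construction: the contrast covariance is
eigen-decomposed into independent 1-df contrasts, each 1-df df is
2 f^2 / (g' A g) with f(theta) the contrast variance, g its numerical
gradient in the variance components and A the inverse observed REML
information (central finite differences), and the q contrasts combine
through E = sum nu_i/(nu_i - 2), ddf = 2E/(E - q). The region
likelihood-ratio test compares ML (never REML) fits of the full and
no-region models, chi-square with (regions - 1) df; the same routine
serves any nested fixed-effect pair (for example a lipid covariate vs its
reduced model). A caveat the test suite measures directly: with only 17
colonies carrying the between-region information, the chi-square
reference for a 3-df fixed effect is liberal — about 11% rejection at
nominal 5% under colony-label permutation (an independent mixed-model
implementation reproduces the same likelihoods, so this is a property of
the test, not of the fit). The Satterthwaite F is the calibrated route
(about 6-8% in the same check, within Monte-Carlo error of nominal) and
is what the summary tables report alongside the LRT. Marginal means per region are
b0 + b_region(i) on the ln scale, back-transformed by exp for points and
Wald interval ends — intervals of the *median* on the raw scale, not the
mean. Region-vs-overall comparisons are reported unadjusted and
Holm-adjusted (no multiplicity convention is standard here, so both are
given).

## Synthetic-data generator

The generator emulates the monitoring design: 17 colonies in four regions
(Great Lakes + Niagara, St. Lawrence, Atlantic, Arctic), years 2008-2023
(Arctic from 2010), annual chemistry for Great Lakes colonies and
alternate years after 2012 elsewhere, 1-5 pools per colony-year (uniform
by default — the programs report the range, not the distribution), 2-15
eggs per pool. Pool ln concentrations are additive: piecewise-linear
colony trend + region offset + shared year effect + colony-year deviate +
pool deviate. Class deviates are drawn with correlation rho = 0.7 between
each reference class and its dependents (the PBDE sum with BDE-209, whose
non-detects rank by BDE-99; SumDP with HBCDD, ranking by syn-DP).
Congeners are fixed shares of the class sum (BDE-47/-99 dominant, as in
gull eggs; BDE-190 at trace level so the 3% rule excludes it), so class
sums match the scenario mean exactly. Default intercepts put classes on
realistic scales (hundreds of ng/g for the PBDE sum down to a few ng/g
for DP); default variation is residual (colony-year) sd 0.3, pool sd 0.2,
year sd 0.15 on the ln scale — the within-colony-year pool variance is
unreported in the programs, so pool sd is a free parameter, not an
estimate. Region offsets default to +0.9/+1.1/-0.9/-1.1 ln units
(elevated Great Lakes and St. Lawrence, low remote regions). MLODs default
to fixed per-analyte values inside the programs' 0.01-1.0 ng/g range,
with BDE-209 at 5.0 ng/g in three analysis years, placed so minor
congeners and syn-DP show realistic non-detect fractions while major
analytes stay nearly fully detected.

A single seed drives everything; colony sub-streams derive from a hash of
the colony name, so one colony's draws do not depend on design order, and
year effects come from a dedicated stream shared across colonies. The
generator does **not** emulate: laboratory QA/QC and batch effects,
diet/migration processes, spatial covariance between nearby colonies,
temporal autocorrelation in the year effect, or congener-composition
drift over time. Passing recovery tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to those
real-data features.

## Monte-Carlo sizes and numerical tolerances

Recovery and calibration suites use 150-1500 replicates: breakpoint
recovery 1500 series (median breakpoint within +-1 year; slope CI
coverage required in [90%, 98%] — at 500 series the coverage band edge
sits within ~1.5 Monte-Carlo standard errors of the truth, too noisy to
measure the property reliably), null calibration 500 series against a
99% binomial band around 5%, censored-ML recovery at n = 1000 (+-0.05 on
both parameters), mixed-model variance-share recovery 200 replicates
(median within 5 points) with 150 label permutations for the level of
each region test. The
generative-model mean check runs 200 replicates on a 3-colony design
rather than the full 17-colony grid — the statistic is colony-local, so
the smaller grid tests the same property. Optimiser tolerances: breakpoint
iteration to 1e-8 years; censored-ML simplex to 1e-8/1e-10 with a sigma
floor of 1e-6 (all-equal values are flagged degenerate at the floor);
REML simplex to 1e-7/1e-10 with three starts.

## Known limitations

* One breakpoint per series; no Davies-style exact inference on psi
  itself, no autocorrelation-robust errors.
* Conditional slope SEs given the estimated breakpoint (with the df
  charge above); fully unconditional intervals would need bootstrap.
* The censored-ML replacement procedure is single imputation;
  Kaplan-Meier and regression-on-order-statistics alternatives, and
  multiple imputation, are out of scope.
* The mixed model assumes independent year effects and no spatial
  structure among colonies.
* Lipid normalisation, toxic-equivalent weighting and temporal
  interpolation of missing years are deliberately not provided.
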
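# Methods

This note documents the statistical machinery in `refmine`, the
assumptions behind it, and the choices made where the design was open.

## The estimation problem

Routine laboratory data for an analyte such as homocysteine are a
two-component mixture: a majority of non-pathological results and a
pathological fraction shifted in the clinically relevant direction
(upward, for Hcy). The goal is the reference interval of the healthy
component only — here one-sided, (0, P95] — without ever observing
component labels. All methods share one parametric premise: the healthy
component is Gaussian on a Box-Cox scale,

    t = (x^λ − 1)/λ  (λ ≠ 0),   t = ln x  (λ = 0),

with λ estimated by maximizing the profile log-likelihood
−(n/2)·ln σ̂²(λ) + (λ − 1)·Σ ln x over a bounded interval (default
[−5, 5]). Quantiles are always reported on the analyte scale via the
inverse transform, so every estimator reduces to producing (λ, μ, σ) of
the healthy component.

## Synthetic cohorts and what they do (not) emulate

The generator draws, per record: sex (default 1:1), an integer age from
a truncated normal (centre 47 y, spread 15 y, range 18–95 — the
mid-life-weighted age profile of a physical-examination population), a
component label (healthy with probability 0.88), and the analyte on the
transformed scale: healthy values from N(μ_sex(age), σ_sex(age)),
pathological values from N(μ_sex(age) + 0.5, 0.35), back-transformed
with λ = 0 (log-normal, the canonical shape for Hcy).

Location/scale curves are low-order polynomials in u = (age − 40)/30 on
the log scale. Defaults: female ln-median 2.3609 + 0.012·u + 0.06·u²
(a dip to a minimum near age 37, then a rise — the post-menopausal
pattern), male 2.5259 + 0.05·u (monotone rise, above the female curve
at every age in range); σ = 0.16 (female) and 0.15 (male), i.e. a
15–16% coefficient of variation. The log-scale sex gap (≈ 0.165 at
mid-life) and residual scale are set so the population exhibits the
textbook partitioning signal: SDR_sex ≈ 0.6–0.75 (clearly above the
0.375 threshold), SDR_age ≈ 0.25–0.3 (clearly below). The
contaminant's +0.5 log shift (≈ ×1.65) and its 12% prevalence are this
package's choice of a plausible hyperhomocysteinemia burden in an adult
examination population; no published quantitative description of the
pathological tail was available, so tests vary these rather than treat
them as fixed truths.

Covariates are drawn inside their reference ranges (scaled Beta(2.5,
2.5)) with a per-covariate probability of falling outside; for
pathological records that probability is multiplied by 4 (capped at
0.9), because elevated Hcy co-occurs with its causes — folate/B12
deficiency and impaired renal function. This coupling is what gives the
covariate cascade its real-world effect of depleting pathology (the
post-cascade contaminant fraction drops from 12% to ≈ 3%).

Not emulated: assay imprecision and detection-range censoring,
longitudinal repeat visits, covariate–covariate correlation, and any
site or seasonal effects. Passing tests therefore demonstrate correct
statistical behaviour under a clean mixture model, not robustness to
every artefact of real laboratory data.

`generate_two_level_sample` (for variance-component tests) realizes its
group effects *exactly* — residuals are centred within cells — so a
recovered SDR deviates from the target only through estimation error,
not through the luck of the simulated effects.

## Cleaning

The cascade applies, in order: a minimum-age rule, first-visit
deduplication (minimum visit index per subject), and inclusive
reference-range rules per covariate (sex-specific for ALT, AST and
creatinine), each logged as a waterfall row (n_before, n_excluded,
n_after) that must conserve counts. Outlier removal runs per subgroup
(sex × age band for the estimator track, sex only for the aging track):
refit λ, compute Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR on the
transformed values with linear-interpolation quartiles (the common
statistical-software default; no convention was prescribed), drop
flagged records, repeat until a pass removes nothing. λ is refitted at
every pass so the normality premise tracks the shrinking group; the
loop terminates because each iteration strictly shrinks the group or
stops. Equal-weighted subsampling draws the same number per sex × age
band stratum (default: the smallest stratum's size).

## Partitioning

Standardized coefficients come from OLS of the analyte on a sex
indicator and six age dummies (18–29 reference), β_j = b_j·SD(x_j)/SD(y).
The larger of |β_sex| and max|β_age| decides which factor sits on level
1 of a two-level nested variance-components model, estimated by
method-of-moments on the expected mean squares with the standard
unbalanced-design coefficients; negative components truncate to zero.
REML is available as an independent cross-check in the tests (the two
agree to well under 10% on balanced designs). SDRs use the strict rule
SDR > 0.375 for a partition verdict. The regression runs on
untransformed values by default, matching how such coefficients are
conventionally reported for Hcy.

## The five estimators

**Hoffmann.** Ordered transformed values against normal scores
z_i = Φ⁻¹((i − ½)/n). Contiguous windows covering ≥ 40% of the points
between the 10th and 90th percentile ranks are scanned; the window with
the best OLS R² wins (ties: wider, then more central). Slope and
intercept give (σ, μ). If no window reaches R² = 0.95 the fit aborts
and asks for a manual region — that diagnostic also marks the estimate
as unreliable under heavy contamination.

**Bhattacharya.** On a histogram of the transformed data (bin width
2·IQR·n^(−1/3), rounded to a tidy value), successive log-count ratios
y_i = ln(f_{i+1}/f_i) are linear in the bin midpoint with slope
−h/σ² and intercept hμ/σ² − h²/(2σ²) wherever a single Gaussian
dominates, so σ² = −h/b and μ = h/2 − a/b. The segment scan mirrors
Hoffmann's (weighted by the delta-method variance of y_i, minimum
width 40% of the usable run) and must contain the modal bin — the
healthy component carries the sample's dominant mode, and without that
constraint a pure-contaminant segment (same slope, different intercept)
could win the scan.

**EM.** Standard Gaussian-mixture EM on the transformed scale with a
monotone log-likelihood trace, deterministic quantile and
majority-healthy initializations plus random restarts, and a σ floor
(10⁻⁴ of the data SD) that discards degenerate runs. By default the
number of components is chosen from {1, …, k} by BIC: routine data may
be effectively homogeneous, and a forced two-component fit of a single
Gaussian is unidentifiable (its "largest" component is arbitrary).
The healthy component is the one with the largest mixing weight (ties:
smaller mean); its (μ, σ) give parametric quantiles.

**kosmic-type.** Grid search over λ (default {0, 0.5, 1}) and
truncation-quantile pairs q1 ∈ {0.05…0.30}, q2 ∈ {0.70…0.95} (step
0.05). In each cell, (μ, σ) start at the truncated-normal ML solution
(computed from sufficient statistics, so cost is independent of n) and
are polished by Nelder–Mead on the Kolmogorov–Smirnov distance between
the interval-renormalized fitted CDF and the empirical CDF restricted
to the interval. Cells are compared on KS divided by the fitted model's
mass inside the truncation interval: raw KS always favours the
narrowest window, and the mass penalty is the natural scale-free
counterweight. This routine implements the *objective* of the published
kosmic tool — minimize the distance between a parametric distribution
and a truncated part of the observed one — and is not a port; numeric
identity with that software is a non-goal.

**refineR-type.** For each λ on a coarse grid ({0, 0.25, …, 1.25}),
the transformed data are binned (60 equal-width bins); the main-peak
region is the contiguous run of bins with counts ≥ 10% of the modal
count (≥ 5 bins required); (μ, σ, amplitude) minimize a χ²-type
discrepancy Σ(O − E)²/max(E, 1) over that region; the λ with the lowest
per-bin cost wins. Confidence intervals come from a nonparametric
bootstrap (default 200 resamples) that re-selects λ among the grid
neighbours of the point estimate on every resample — λ uncertainty
dominates the interval and ignoring it produces severe undercoverage.
Percentile CIs are widened, if necessary, to contain the point estimate
(a documented invariant of the result type). Again a principled variant
of the published tool's stated objective, not a port; its bootstrap CI
is noticeably sharper than the published tool's conservative intervals.

All five report the same quantile grid and the one-sided interval
(0, P95]. A consistency table marks, per method and quantile, whether
the point estimate falls inside the reference method's bootstrap CI.

## Age-continuous percentiles

Per sex, the Box-Cox Cole–Green (LMS) model: z = [(y/M(t))^L − 1]/(L·S(t))
standard normal, with log-linked M(t) and S(t) and constant L. M and S
use regression splines over age (polynomial bases up to 3 df, cubic
B-splines with quantile-spaced knots beyond); the effective df is the
coefficient count, and the df grid for M(t) (default {2, …, 8}, S fixed
at 2) is selected by SBC = deviance + ln(n)·df. Constant L stabilizes
moderate-sample fits; unpenalized bases with df selected by an
information criterion are the classical LMS practice and keep the
effective df exact. Fitting alternates (backfits) L-BFGS blocks for the
M and S coefficients with a bounded scalar search for L until the
deviance changes by < 10⁻⁴ (cap: 200 outer iterations, error on
non-convergence). Percentile curves follow in closed form,
C_p(t) = M(t)·(1 + L·S(t)·z_p)^{1/L} (L ≠ 0) or M(t)·exp(S(t)·z_p);
non-crossing on the 1-year grid is asserted after every fit.

Validation: the data are split 70/30, stratified by sex and seeded. A
validation subject is outside the RI iff y > C₀.₉₅(age) (the lower
limit 0 cannot be violated by positive data). FOR is the percentage
outside per 1-year bin; the summary is the *unweighted* mean over
non-empty bins, with pass flags "mean < 10%" and "around 5%"
(within 2.5 points — the nominal exceedance of a P95 limit is 5%).

## Numerical choices and degenerate inputs

- Quantiles everywhere use linear interpolation of order statistics.
- Box-Cox requires strictly positive values; offending counts are
  reported. Fitting needs n ≥ 10; fences need n ≥ 4; per-method minimum
  n: Hoffmann 100, Bhattacharya 200, EM 30, kosmic/refineR-type 500.
- Window scans compare R² at 10⁻¹⁰ resolution so exact ties break by
  width, then centrality (this makes the noise-free Bhattacharya fit
  reproducible to machine precision).
- Bootstrap and EM restarts run off explicit integer seeds; the
  pipeline derives per-stage seeds from one master seed via SHA-256, so
  any stage can be rerun in isolation.
- Problem sizes in the test suite (2·10⁴ for estimator checks, 1.5·10⁴
  cohorts for the aging model, 100 replicates × 200 bootstraps for
  coverage) are chosen so the whole suite completes in minutes on one
  CPU while keeping Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

- The kosmic- and refineR-type routines share the spirit, not the code,
  of the published tools; their numbers will differ from those tools'.
- λ selection from a coarse grid leaves the kosmic-type P95 with a
  small non-vanishing wobble (≈ 0.1–0.3 μmol/L at n = 2·10⁴ on clean
  Gaussian data); the refineR-type CI absorbs the analogous uncertainty
  via bootstrap λ re-selection.
- The nested variance-components model supports exactly two levels (the
  partitioning question asked here); no interactions.
- One-sided intervals only; analytes whose low values are pathological
  need a different RI convention.
- FOR bins with no validation subjects are silently excluded from the
  mean; with very sparse validation data the mean FOR is noisy.
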
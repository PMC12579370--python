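# Methods

`tegma` models the relationship between the earliest available TEG6s
parameter — the citrated rapid thromboelastography reaction time (CRT-R,
minutes) — and the clot-strength parameters that only become available
30–60 minutes later (maximum amplitudes, mm), and converts that model into
clinically anchored early-warning thresholds. This note records the model,
the synthetic cohort it is validated on, the numerical choices, and the
known limitations.

## The model

For each maximum-amplitude (MA) outcome the mean structure is a
three-parameter exponential decay

    y = a · exp(−b · x) + c

with `x` the CRT-R in minutes, `a` the initial offset from the asymptote
(outcome units; negative for the one increasing relationship, CRT-R vs
CKH-R), `b` the decay rate per minute (`b > 0`), and `c` the asymptotic
outcome value. The relationship between CRT-R and TEG-ACT is linear
(`crt_r = slope · act + intercept`): the device derives ACT from the
reaction time by a fixed internal conversion, so the two are the same
quantity on different scales and the fit is essentially exact (r = 1.000).

Association strength is summarized by the signed Pearson correlation with a
two-sided t-based p-value (`t = r·√((n−2)/(1−r²))` on n−2 df), and fit
quality by R² = 1 − SS_res/SS_tot, MAE and RMSE of the fitted curve.

A clinical MA target `y*` maps to a reaction-time cutoff by inverting the
monotone fitted curve:

    x* = −(1/b) · ln((y* − c)/a),

defined whenever `(y* − c)/a > 0`. Default targets: CRT-MA = 48 mm (globally
weak clot) and CFF-MA = 12 mm (fibrinogen-deficient clot strength).
Uncertainty in `x*` comes from a nonparametric bootstrap: resample
measurement pairs with replacement (default 1,000 replicates), refit
(initialized at the full-sample estimate), re-invert, and summarize the
cutoff distribution by its 2.5/25/50/75/97.5 percentiles. The reported
cutoff is the bootstrap median; the full-sample inversion is reported
alongside as `point`. Replicates whose refit fails or whose refitted curve
cannot reach the target are discarded and counted; if fewer than 90% of
replicates succeed the procedure signals instability rather than reporting
a summary of a broken distribution.

At a cutoff, diagnostic performance treats a run as test-positive when
`crt_r > cutoff` (strict; a run exactly at the cutoff is negative) and
truly positive when `ma < y*` (strict). Sensitivity, specificity, PPV, NPV
and accuracy follow the usual 2×2 definitions; any metric with a zero
denominator is flagged undefined (`None`/JSON null) instead of erroring.

## Synthetic cohort

No patient-level data ship with the package; a generator reproduces the
statistical structure the analysis assumes.

* **CRT-R marginal.** Truncated log-normal on [0.3, 5.5] min with
  `μ = ln 0.7` and `σ = ln(0.9/0.5)/(2·z₀.₇₅) ≈ 0.4357`, calibrated by
  quantile inversion to a median of 0.7 min and an IQR of 0.5–0.9 min. Two
  caveats are intrinsic, not bugs: a log-normal satisfies Q1·Q3 = median²,
  so it can match the median and the quartile *ratio* (1.8) but not the
  printed quartile pair exactly (untruncated quartiles come out
  0.522/0.939); and truncating the lower 2.6% tail shifts the quantiles up
  slightly (theoretical truncated quartiles 0.536/0.710/0.948). Tests
  validate the sampler against these closed-form truncated quantiles.
* **MA channels.** Each channel's published decay equation plus additive
  homoscedastic Gaussian noise with sd equal to that channel's published
  residual RMSE (e.g. 5.0788 mm for CFF-MA), clipped to physical bounds
  afterwards. Bounds use the published observed range where one exists
  (CRT-MA 20.1–75.4 mm) and wide physical bounds otherwise (amplitudes
  ≥ 0, reaction times > 0). Homoscedastic Gaussian residuals are an
  assumption; the source analysis reports only an overall RMSE.
* **TEG-ACT.** Generated deterministically as the exact inverse of the
  linear map, so refitting recovers slope 0.0107 and intercept −0.5397 to
  round-off and r = 1.000 by construction.
* **Missingness.** Each record independently receives, with probability
  80/2453 ≈ 3.3%, one uniformly chosen blanked field (MCAR). No mechanism
  beyond MCAR is modeled.
* **Outliers.** With probability 24/2453 ≈ 1%, CRT-R is replaced by a
  uniform draw in (5.6, 15] min — a stalled/failed assay — and the
  dependent channels are regenerated at the new CRT-R so rows stay
  internally consistent. The lower bound deliberately exceeds the 5.5 min
  exclusion threshold so every injected outlier is removable.
* **Determinism.** One PRNG stream per cohort, seeded once; sub-stages draw
  in a fixed order (CRT-R, channel noise in config order, outliers,
  missingness). Identical config ⇒ bit-identical dataset.

What the generator does **not** emulate: within-patient correlation of
repeated runs (runs are i.i.d. here), heteroscedastic or skewed residuals,
and the real cohort's predictor tail. That last point is measurable: under
the calibrated truncated log-normal the population |r| for CRT-R vs CFF-MA
is ≈ 0.58 (variance decomposition r² = Var(mean curve)/(Var + sd²), with
the amplitude clip), below the 0.6224 observed in the real cohort — the
real CRT-R distribution is heavier-tailed within 0.3–5.5 than a log-normal
matched to its quantiles. Consistency tests therefore anchor on 0.58.
Passing tests show the pipeline recovers the structure the generator puts
in; they do not certify performance on real TEG6s exports.

## Preprocessing

Exclusions run in a fixed order: records with any missing required field
first, then records with CRT-R strictly greater than 5.5 min (five times
the upper limit of normal; a record at exactly 5.5 survives). A record that
is both missing and implausible counts as missing, which reproduces the
style of the study's accounting (2,453 → 80 missing, 24 outliers → 2,349).
`apply_exclusions` defaults to listwise completeness over all six channels —
that is what the printed accounting describes — and accepts a `required`
column subset for pairwise-complete analyses. Summaries use linear
interpolation between order statistics for all quantiles (numpy's default),
the same convention as the bootstrap percentiles.

## Numerical choices

* **Decay fit.** Levenberg–Marquardt on residuals over `(a, ln b, c)`; the
  log parameterization keeps `b > 0`, removing the (−a, −b) mirror family.
  Initial values: `c₀ = min(y)` and `a₀ = range(y)` for decreasing data
  (sign read off the raw correlation), mirrored for increasing data;
  `b₀ = 1/range(x)`. Cap of 200 iterations, relative SSE tolerance 1e-10;
  a non-converged solve raises a failure signal carrying the best-so-far
  parameters, which the bootstrap counts rather than silently drops.
* **Weak identifiability.** When the predictor mass is concentrated (as the
  calibrated marginal is, IQR 0.5–0.9 min), the curve is locally
  near-linear and `(a, b, c)` trade off strongly: at n = 300 with noise sd
  5 the asymptote `c` is effectively unidentified (its sampling
  distribution spans hundreds of units around a true value of 0.35). This
  is a property of the least-squares objective, not the optimizer — refits
  started at the generating truth converge to the same, lower-SSE point.
  The *cutoff* is unaffected because it evaluates the fitted curve inside
  the data-dense region: its 95% bootstrap interval shows ~95% coverage of
  the closed-form truth in simulation.
* **Degenerate inputs.** Zero-variance inputs raise a named degeneracy
  error for correlation and for an all-identical-x linear design; a
  constant outcome yields slope 0 with R² reported as 0 under a warning.
  Inversion at an unreachable target raises a no-solution signal distinct
  from fit failure.
* **Ties.** Classification is strict on both sides (`>` cutoff, `<`
  target).

## Pipeline and problem sizes

`run_analysis` executes acquire → preprocess → associate → threshold with a
fixed seed tree (one spawned child stream per bootstrap target, in sorted
channel order) and writes a JSON report validated against a published key
schema, plus curve and cutoff tables as CSV. Identical config and seed give
byte-identical reports; the provenance block is a faithful config echo
(including the output directory).

The test suite validates calibration at 50,000 draws; generator-consistency
checks run at the full cohort size (2,453); the parameter-recovery study
uses 100 cohorts of n = 300 at noise sd 5; the bootstrap coverage study
uses 200 cohorts of n = 300 with 200 replicates per bootstrap — sizes
chosen to keep the whole suite a few minutes long on one core while leaving
Monte-Carlo error well inside the asserted bands.

## Limitations

* The published cutoffs for the CRT-MA channel (bootstrap median 1.1858
  min) are not reproducible from the printed CRT-MA equation, which inverts
  to ≈ 1.308 min at 48 mm; the CFF channel is internally consistent
  (1.2841 closed-form vs 1.2832 printed bootstrap median), so worked
  examples anchor on CFF and on the ACT conversions.
* Real-cohort statistics (printed r, R², sensitivity/specificity) depend on
  the unavailable patient data and are not reproduction targets; the
  synthetic cohort reproduces structure, not those exact values.
* Bootstrap resampling is at the measurement level; patient-level
  clustering is out of scope.
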
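# Methods

This note documents the models, parameter choices and numerical decisions
behind the package; nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Questionnaire scoring

**SSQ.** Sixteen symptoms rated 0–3 load on three subscales (Nausea,
Oculomotor, Disorientation) following the published Kennedy et al. (1993)
assignment, shipped as a constant table in `vectsick.scales`.  Raw subscale
scores are unweighted sums; weighted subscales multiply by 9.54 / 7.58 /
13.92, and the Total Score is 3.74 × the sum of the three raw sums.  Five
symptoms load on two subscales and eleven on one, so the raw-sum total over
an all-maximal response is 63 and the TS ceiling is 235.62 (the "236-point
scale").  The 0–3 anchors of the original instrument are assumed.

**MSSQ-Short.**  Nine motion types per life section (child / adult), each
rated 0–3 or flagged never-experienced.  A section scores
`sum × 9 / (9 − n_not_experienced)` (Golding 2006); the total is the sum of
the two sections, range 0–54.  A section with all nine types flagged has no
defined score and raises.

**FMS.**  Stored as reported: integer 0–20 ratings on the 2-minute grid,
ending at 20 min or at the first rating ≥ 15 (the stop rule).  Only summary
statistics (peak, final, early-abort flag) are derived; FMS is not used in
the main model because its between-subject agreement with the SSQ is too
weak to treat it as the outcome.

## Vection features

Ratings below 0.05 are "no vection", above 0.95 "full vection", strict on
both boundaries (0.05 and 0.95 themselves are "partial").  FullVection and
the no-vection percentage count samples, which equals time-weighting under
the uniform sampling the knob recorder produces (the generator default is
10 Hz; any uniform rate is accepted).  SDdV is the population SD of the
consecutive-sample difference quotient of the **raw** rating, in 1/s, so
the feature is comparable across sampling rates.

## Beliefs and conflict

Certainties are normalized to [0, 1] at ingestion regardless of the
physical scale length.  RL = (signed certainty + 1)/2; the drum RL is
computed identically and carried as a screen predictor but plays no role in
Conflict_PB, and no drum-based conflict is defined.  Conflict_PB is the
absolute difference of two [0, 1] quantities and inherits that range.

## Oculomotor processing

Eye position is smoothed with a Gaussian kernel (SD 5 ms ≈ one 220 Hz
sample, configurable) — enough to suppress tracker quantization noise
while leaving saccadic acceleration far above the detection threshold —
then differentiated twice with the three-point central operator (one-sided
at the ends).  Fast phases seed wherever |acceleration| > 1200 deg/s²;
each seed extends outward until velocity re-enters a band around the local
slow-phase velocity (median of the flanking 100 ms, half-width 3 SD with a
2 deg/s floor), capped at 150 ms per side; intervals closer than 25 ms
merge.  The extension rule is a reconstruction of an acceleration-threshold
detector whose published details are not fully specified; window, band and
merge gap are exposed configuration and a documented departure risk.
Because the boundary samples mix one-sided differences with smoothing
padding, seeds within 50 ms of either end are ignored.

Desaccaded samples are left as gaps (never interpolated).  The surviving
velocity is median-filtered over a 0.25 s window and the scalar SPEV is the
median of that series, taken **with sign** (positive = stimulus direction,
which OKN slow phases follow).

Head angular velocity is low-passed at 10 Hz with a zero-phase
forward–backward Butterworth filter (zero-phase so latency cannot shift
event counts), rotated into the Earth frame when a static roll/pitch is
declared, and the Earth-horizontal magnitude is thresholded at 3 deg/s.
An "instance" (nHM) is a maximal contiguous above-threshold run; a
sample-counting alternative sits behind `count_samples=True` because the
original wording is ambiguous.

## Statistics

The screen computes two-tailed Spearman correlations of the ten candidate
predictors against SSQ-TS with Bonferroni correction fixed at m = 10 (the
screened set, not all pairwise tests).  Constant columns are flagged as
degenerate rather than given a rho.

The outcome is logit-transformed with scale constant 235.62 (the SSQ
ceiling) by default.  The constant is configurable because the original
analysis does not state it; it is the main reproduction risk for the
intercept.

Influence diagnostics use the closed-form hat-matrix identities
(externally studentized residual and DFFITS); the test suite verifies them
against brute-force leave-one-out refits and against an independent library
implementation.  Exclusion (cutoffs 1.96 / 1) is judged on the
two-predictor fit and applied in a **single identify–exclude–refit pass by
default**.  The iterated-until-stable variant is available
(`iterate_exclusion=True`) but is not the default: under approximately
normal residuals a 1.96 cutoff flags roughly the top 5% of cases on every
round, so iteration keeps trimming, shrinks the residual SD, flags again,
and at n ≈ 19 reliably cascades until the model is unfittable.  A
numerically exact fit (RSS at rounding level) yields zero diagnostics by
construction rather than noise-amplified ones.  If exclusion leaves fewer
than p + 2 cases the procedure raises.

Reported quantities: unstandardized coefficients with SEs and p-values;
standardized estimates `b × SD(x)/SD(y)` over retained cases; unadjusted R²
(with adjusted R² alongside, since "explained variance" wording does not
disambiguate) for the susceptibility-only and full models on retained
cases; the nested F-test between them (equal to the added coefficient's
squared t for one added predictor — asserted in tests); and an "overall"
R², the squared Pearson correlation between observed and predicted logit
outcome when the retained-case model is scored on every participant.

## Synthetic cohort

The generator states the study's conditions as defaults: 19 participants,
20-minute trials, 60 deg/s stimulus reached at 10 deg/s² (the acceleration
phase is not modeled; traces start at constant stimulus speed), FMS stop at
15, and outcome coefficients intercept −1.64, beta_mssq 0.02,
beta_conflict 2.15 on the logit scale.

* **Vection**: plateaus cycle no → partial → full → partial with
  exponential dwells (means 36 / 15 / 53 s, chosen so the cycle fractions
  give cohort-level FullVection ≈ 44% and no-vection ≈ 30%), 1.5 s linear
  ramps, partial plateau values uniform in (0.1, 0.9), knob noise SD 0.01.
  A per-participant latent z scales the full/no dwell ratio
  (log-scale spread 0.6), producing the between-subject FullVection SD in
  the vicinity of the reported 21 percentage points.
* **Beliefs**: a Gaussian copula couples the chair-belief latent to the
  vection latent with correlation −0.58, reproducing the reported negative
  perception–belief association; the RL maps through the normal CDF and is
  split back into the recorded Y/N + certainty.  The joint
  distribution beyond that single rank correlation is a modeling choice of
  this package, not a reported fact.  Drum belief uses a weak +0.2
  coupling.
* **OKN**: slow phases at gain × 60 deg/s (default gain 0.85, mid-range
  for stare nystagmus at this stimulus speed), raised-cosine resetting
  saccades at Poisson times (3 Hz beat rate, 100 ms refractory, peak
  500 deg/s), position noise SD 0.02 deg; programmed saccade intervals are
  returned as detector ground truth.
* **Head**: band-limited (2 Hz) noise at 0.5 deg/s per axis — far below
  the 3 deg/s threshold — plus a known number of 0.5 s, 6 deg/s
  raised-cosine transients (Poisson 0.25/min by default, or an exact
  count), the ground truth for nHM.
* **Outcomes**: the logit-linear model plus Gaussian noise
  (SD 0.40, chosen a priori so the deterministic signal variance at the
  stated predictor spreads puts model R² near the reported two-thirds;
  not tuned after measuring).  The target TS is realized as 16 item
  ratings by greedy allocation over item loadings, so re-scoring through
  the SSQ module reproduces the target within half a quantum (1.87
  points).  FMS is a monotone surrogate ramp truncated at the stop rule —
  no physiological nausea dynamics are claimed.  The sick flag thresholds
  TS at 80 (near the reported overall median).

A feature-level fast path (`generate_cohort_features`) draws FullVection
directly from its cohort marginal (mean 44, SD 21, clipped) with the same
copula and outcome model, for replicate-heavy studies where trace synthesis
would dominate runtime; the trace-level path is exercised end to end at
n = 19 in the tests.  Replicates for bias studies can be drawn as
antithetic residual pairs (`noise_sign=±1`): each twin is marginally an
ordinary cohort, but because negating the residuals flips every raw
residual exactly, the influence diagnostics — functions of |residual| —
flag the identical exclusion set, and the paired mean of the fitted
coefficients collapses onto the generative values, removing first-order
Monte-Carlo noise from the bias estimate.

What a green synthetic test does **not** establish: agreement with the
original cohort's actual numbers (that requires the deposited workbook via
the `reproduce` verb), realism of the FMS dynamics, or any claim about the
joint belief–vection distribution beyond the single programmed rank
correlation.

## Known limitations

* The fast-phase extension rule reconstructs an under-specified published
  algorithm; against real nystagmus data the interval boundaries may
  differ from the original implementation even though threshold seeding is
  identical.
* The logit scale constant and the single-pass exclusion policy are
  defensible readings of an under-specified analysis; both are
  configuration, and sensitivity to them should be reported alongside any
  reproduction.
* Head-trace ingestion supports only a static declared head tilt; a full
  orientation time series would require quaternion input the format does
  not carry.
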
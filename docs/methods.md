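# Methods

## The damage model

Winter leaf damage is summarised by the photosynthetic quantum yield QY ∈
[0, 1] and explained by a chilling accumulation unit CU computed from one
daily temperature statistic T ∈ {max, min, avg}:

- **day count** CU_d(d; Th, L) = #{δ ∈ window(d) : T(δ) < Th}
- **temperature sum** CU_t(d; Th, L) = Σ_{δ ∈ window(d), T(δ) < Th} (Th − T(δ))

where window(d) is the L-day interval **ending on and including** day d.
The response model is linear on the logit scale, logit(QY) = a·CU + b + ε
with Gaussian ε.  Key conventions, each of which was genuinely open:

- *Window alignment.* The window includes the observation day: damage
  visible on a sampling day plausibly reflects that day's cold.  (Only
  "the past L days" is determined by the problem; the off-by-one is a
  convention.)
- *Strict inequality* T < Th for "below the threshold".  Ties are
  measure-zero on continuous data and the 0.25 °C grid step makes the
  choice testable either way.
- *Deficit accumulation* for CU_t.  Summing the deficit (Th − T) rather
  than the raw temperatures is the standard chilling/degree-day
  convention; it keeps CU_t nonnegative and monotone in Th.  The raw-sum
  variant remains available (`temperature_sum_kind="raw"`).
- *Logit clamp* eps = 1e−3: QY readings of exactly 0 occur in deep winter
  and must map to a finite response, not −∞.

## Preprocessing

Station records are admitted when the missing-day rate of the used
statistic is ≤ 10 % (boundary inclusive).  A single missing day receives
the arithmetic mean of the neighbouring days; runs of k ≥ 2 missing days
receive linear interpolation between the flanking values — the natural
extension of the single-day rule.  Missing first/last days are rejected
rather than extrapolated.  Non-missing values are never altered.

## Model selection

The search grid holds 61 thresholds (15 °C span, 0.25 °C step, per-statistic
ranges max [0, 15], avg [−2.5, 12.5], min [−7, 8] — chosen to bracket each
family's selected optimum while honouring the common 15 °C span) × 70
windows (1–70 d) × 6 (type, statistic) families = 25,620 configurations.
For each, ordinary least squares gives (a, b); the likelihood uses the ML
variance σ² = RSS/n so that AIC = 6 − 2 logLik matches the Gaussian-GLM
convention with k = 3 free parameters.  (The alternative RSS/(n−2) would
shift all AICs nearly uniformly and rarely change the argmin; the ML form
is the one a Gaussian `glm` reports.)  Failed fits — constant CU over the
observation dates, as happens when Th sits below every recorded
temperature — carry +∞ AIC so the Th × L table stays rectangular for
heat-map export.  Ties within 1e−9 of the minimum are broken by
enumeration order (cu_type, then statistic in max/min/avg order, then Th,
then L ascending) and reported.

The search is vectorised (one cumulative sum per threshold yields all
window sums; closed-form simple OLS across the whole grid) but is
bit-for-bit the per-configuration fit; a literal double-loop brute force
is kept as an oracle in the test suite.

Responses default to the mean of the replicate leaves within line × date,
taken before the logit transform (`per_line_date_mean`); per-leaf
responses are available.  With two clonal lines, three seasons and
biweekly November–March sampling this gives 66 response points.

## Intervals and validation

Prediction uses the standard simple-regression intervals on the logit
scale with the **unbiased** variance s² = RSS/(n−2) and Student-t
quantiles: CI half-width t·s·√(1/n + (x−x̄)²/Sxx), PI adds +1 under the
root.  The inverse logit is strictly monotone, so endpoints map to
endpoints and coverage counts are scale-invariant.  The AIC machinery and
the interval machinery deliberately use different variance estimators:
the former for the GLM convention, the latter because exact 95 % coverage
of the t-intervals holds under it (verified empirically: PI coverage of
new observations ≈ 0.95 over 500 refit cycles).

Note the two bands answer different questions: the mean-response CI is
narrow (∝ 1/√n) and is *not* expected to contain individual observations;
observation-coverage counts of the kind "x of n points within the band"
are only meaningful against the prediction band, and the validation
driver reports both.

## Synthetic data

Daily mean temperature is a single cosine of the day of year with its
minimum anchored at day 25 (late January), plus N(0, σ_day) daily noise,
an optional linear warming term, and a fixed symmetric diurnal offset:
max/min = mean ± half-range.  Defaults (annual mean 14.7 °C, amplitude
11.6 °C, noise sd 2 °C, half-range 4.5 °C) emulate a humid-temperate
Kanto-plain climate with a January mean of 3.1 °C.  A configured fraction
of days loses all three statistics at once, emulating station outages.

QY observations are drawn from the model itself: QY =
inverse-logit(a·CU(date) + b + ε) with i.i.d. logit-scale ε per (date,
line, replicate).  The default generating model is the day count of daily
maxima below 9.5 °C over 46 days with a = −0.08, b = 0.85 (QY ≈ 0.70 with
no chill, ≈ 0.06 at saturation) and obs_sd = 0.1.

What this generator does *not* emulate — and hence what passing tests do
not establish about field data: temporally autocorrelated weather, cold
snaps sharper than the sinusoid + white noise, asymmetric or
temperature-dependent diurnal range, line-specific damage sensitivity,
within-canopy correlation of replicate leaves, and any model
misspecification (real QY does not follow an exact logit-linear CU
response).  One consequence of the fixed diurnal offset is worth
flagging: max, min and avg differ by exact constants, so the three
statistic families are exactly equivalent up to a threshold shift and the
selected *statistic* is decided by enumeration order; threshold and
window recovery, the quantities of interest, are unaffected.

## Geographic and warming simulations

A station is reduced to its **period-maximum CU** (worst winter on
record) after filter → impute → CU; an RBF support-vector regression (or
classification for binary suitability) on raw (lat, lon) degrees fills a
regular cell-centre grid with origin at the bounding box's south-west
corner.  Suitability: period-max CU ≤ 35 (inclusive — this chill level
corresponds to predicted QY ≈ 0.15), or annual-min predicted QY
strictly > 0.20 for the warming analysis ("exceeds" read literally; a 0.4
preset exists as a named alternative).

Per-site warming trends are OLS of the seasonal minimum of predicted QY
(season window 1 Oct – 31 Mar, labelled by start year) on the start year;
extrapolations are clamped into [0, 1].  SVM hyperparameters are exposed;
the library default (RBF, `scale` bandwidth) suits fields that vary on
the domain scale, but mapping a *narrow* suitability band with strongly
imbalanced classes needs a kernel length scale of the order of the
station spacing — the warming analysis therefore sets gamma = 0.5
(≈ 1.4° length scale).  With the domain-scale default the early-year map
degenerates to the majority class and no boundary exists.

## Problem sizes and determinism

The bundled experiments use: 3 training winters × 11 biweekly dates × 2
lines (66 responses) for selection; 10 replicate datasets for the
modal-recovery study; 500 refit cycles for interval calibration; a
97-station, 40-winter network at 0.03 °C yr⁻¹ for the warming study; 120
stations for the global map.  Every random quantity flows from one
explicit integer seed per call (NumPy `default_rng`); derived seeds come
from `SeedSequence` and stay below 2³¹.  The full 25,620-model search
takes well under a second on one core, so these sizes are chosen for
statistical adequacy, not necessity.

## Known limitations

- The linear trend extrapolation ignores climate-scenario forcing; it is
  a straight line through seven decades of annual minima.
- Raw-degree SVM interpolation distorts longitudinal distance at high
  latitude; a cos-latitude scaling flag exists but is off by default.
- No precipitation, radiation, humidity or elevation covariates; no
  hourly chilling models (Utah/Dynamic).
- Suitability thresholds (CU 35, QY 0.20/0.4) are taken as given, not
  re-derived from plantation maps.
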
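# Methods

## Emission model

The tier-3 areal flux follows a Boltzmann–Arrhenius response,
`M(T) = M15 · exp[(E_M/k_B)(1/T15 − 1/T)]`, applied with the pond's mean
monthly **air** temperature as the proxy for pond temperature. The exponent
sign is fixed so flux increases with temperature and equals `M15` exactly at
15 °C. All fluxes are stored in t CH4 ha⁻¹ yr⁻¹ (`M15 = 0.204`); kilogram
variants are an I/O conversion only. A month's emission is
`M(T_month) · area_month / 12` — the annual rate split evenly across twelve
months, since sub-monthly dynamics are not modelled. Tier 1 (fixed 0.183
t CH4 ha⁻¹ yr⁻¹) and tier 2 (five climate-zone factors) are retained as
comparison baselines; the tier-3/tier-1 ratio helper optionally rounds both
fluxes to two decimals first, which is how printed-value ratios (e.g. 2.7 at
30 °C) are conventionally quoted.

Parameters that matter: `M15` (t CH4 ha⁻¹ yr⁻¹, default 0.204, 95% CI
0.083–0.521) sets the overall scale and acts exactly linearly on every
inventory total; `E_M` (eV, default 0.43, CI 0.21–0.64) sets the temperature
sensitivity — about a 3.2-fold flux difference between 10 and 30 °C at the
default — and its effect on totals changes sign at 15 °C (raising `E_M`
increases totals on landscapes warmer than the standardisation temperature
and decreases them on cooler ones).

## Pond inventory and accumulation

Size and shape filters separate farm dams from natural waterbodies: ponds
above 10 ha are excluded, as are ponds with circularity ≤ 0.5. Circularity is
the standard isoperimetric form `4π·area/perimeter²` (1 for a circle); a pond
with no recorded perimeter passes the shape filter with a logged warning
rather than being discarded.

A pond's establishment year is the first calendar year in which the
within-year **median** monthly wet fraction reaches 25% of its maximum
surface — "consistently wet" is not otherwise defined, and the median is
robust to single wet months. Ponds below 0.27 ha (three 30 m pixels) are
treated as undetectable; their establishment years are imputed by assuming
they accumulate at the same relative rate as detectable ponds (cumulative
rounding of the implied growth curve, so the imputation is deterministic).

Regional accumulation is summarised by a relative rate — the geometric mean
of year-over-year cumulative-count ratios, chosen over the arithmetic mean so
that projection by compounding is its exact inverse (backcast → project is the
identity) — and an absolute rate (mean annual increment). Projection beyond
the observed window compounds the mean rate of a fallback window (default
2010–2015). Regions with too few ponds for a stable rate (default threshold
50) adopt the pooled national rate, mirroring inventory practice for sparsely
observed territories.

## Water-surface model

Features are the pond's maximum fill area plus 13 monthly lags each of mean
temperature and cumulative rainfall (lag 0 = the current month; the
alternative reading, lags 1–13, changes nothing structurally). Training uses
a 90:10 random split, excludes ponds above 2 ha, and searches learning rate
(0.1–0.5), number of estimators (10–700) and maximum depth (1–10) with 15
random trials followed by 30 guided by a Gaussian-process surrogate
(Matérn 5/2 + white noise, expected-improvement acquisition over 512 seeded
candidates per step). The 10 trials with the lowest validation MAE form the
ensemble; "soft voting" is the unweighted mean of member predictions, which
is then clipped to [0, max_area] — the clip is this package's choice for
handling negative or over-capacity raw predictions. Hold-out metrics are
Pearson r with a Fisher-z 95% CI, MAE (ha), and MAPE excluding zero-area
observations (a dry pond's percentage error is undefined). XGBoost runs
single-threaded with a fixed seed, so a given seed reproduces the search log
and predictions bit-for-bit. Model bundles persist each member through the
underlying booster (JSON) together with the search log and configuration.

## Aggregation

Financial years run 1 July–30 June and are labelled by the ending calendar
year. A pond contributes (to counts and emissions) from the financial year
matching its establishment calendar year; sub-year establishment timing is
not modelled. FY water surface is the mean of the 12 monthly totals (a dry
month counts as zero), and the reported mean flux is FY emissions divided by
FY mean water surface — consistent with emissions = flux × area arithmetic on
the reported rows. National rows are exact sums of regional rows. Relative
water capacity per FY is the national water surface divided by the total
maximum capacity of ponds established by that year; rainfall anomalies are FY
totals minus their long-term mean, averaged across regions. The correlation
between the two is reported with `t = r·√(df/(1−r²))`, `df = n−2`. Reported
totals can be partitioned 60:40 into manure and baseline components for
inventory bookkeeping; the split is presentational and always sums to the
total.

## Uncertainty

The spider analysis re-evaluates the national total with one parameter at a
time set to its 2.5% / 97.5% CI bound: `M15` and a multiplicative
water-surface error scale totals exactly linearly (no re-run needed), while
`E_M` re-weights every pond-month flux. Monte-Carlo propagation draws `M15`
from a log-normal matched to its asymmetric CI, `E_M` from a normal matched
to its symmetric CI, and a mean-one log-normal multiplicative water-surface
error with a default coefficient of variation of 0.42 (the surface model's
characteristic relative error; configurable). Distribution shapes are this
package's modelling choices — the positive-only, right-skewed quantities get
log-normals. Percentiles (2.5/50/97.5) are reported per financial year;
everything is reproducible from the seed. The 2.5% percentile of the
heavy-tailed `M15` log-normal converges slowly: of order 10⁴ draws are needed
before independent runs agree within a few percent, hence the default of
1000 draws is for exploration and stability checks use 8000+.

The coefficient of variation helper (`100·se/|mean|`) is exposed as the
standard way to compare parameter uncertainties; note that CIs and standard
errors are related only under a distributional assumption, so CVs quoted from
asymmetric CIs are not uniquely defined.

## Synthetic landscapes

The generators emulate the statistical structure the analysis assumes, not
any particular real landscape:

* **Ponds** — log-normal sizes (median 0.1 ha, σ = 1) truncated to
  [0.01, 10] ha; eight regions with fixed climate zones and shares;
  establishment years drawn from per-region exponential accumulation at
  1–2.5%/yr defaults (within the plausible 1–4% band), the pre-window stock
  sitting at the start year; a configurable fraction (default 5%) of
  irregular low-circularity shapes to exercise the filter.
* **Climate** — sinusoidal seasonal temperature (southern-hemisphere phase)
  with Gaussian noise; gamma monthly rainfall (shape 2, scale 30 mm)
  modulated by a multi-year sinusoidal anomaly cycle (amplitude 0.3, period
  6 yr).
* **Capacity** — on the logit scale, `eta = 0.45 + 0.7·z(rain13) −
  0.15·z(temp) + pond effect (sd 0.6) + noise (sd 0.75)`; capacity is
  `logistic(eta)`, bounded in (0,1) by construction, and zero before the
  pond's establishment year. Standardisation uses fixed reference moments
  (13-month rainfall 770 ± 221 mm; temperature 17.4 ± 6.1 °C) so capacity
  responds to the absolute climate regime — a wetter regime genuinely raises
  capacity. The default coefficients are calibrated once so the pooled
  capacity distribution approximates mean 0.62, median 0.59, Q1 0.38,
  Q3 0.74 (observed on a 3000-pond, 10-year run: 0.585 / 0.604 / 0.416 /
  0.768).

A master seed spawns independent sub-streams for the three generators.

What the generator does **not** emulate: satellite observation noise, cloud
gaps and biweekly revisit cadence; spatially correlated rainfall between
neighbouring ponds; pond disappearance/decommissioning; seasonal covariance
between establishment and climate. Passing tests therefore demonstrate that
the machinery recovers known structure (growth rates, establishment years,
monotone rainfall response, additivity), not that real-landscape accuracy
metrics would be attained.

## Problem sizes and numerical choices

Tests and the end-to-end check run on scaled-down landscapes chosen as the
package's own verification sizes: a 50-pond toy landscape for the brute-force
inventory oracle, 200 series for establishment-year detection, a
5000-example training set with a reduced search (8 random + 7 guided, top 5)
for parameter recovery, and a 2000-pond × 10-year full pipeline. Degenerate
inputs are handled explicitly: zero-variance series yield "absent"
correlations with a warning rather than NaN propagation; zero base values
yield absent relative changes; dry ponds are excluded from MAPE; empty pond
lists produce an empty inventory with a warning, not an error. Ties in the
hyperparameter search are broken by trial order (first minimum wins).

## Known limitations

* Air temperature proxies pond temperature; thermal inertia of water is
  ignored, which overstates winter/summer flux contrast slightly.
* The even 1/12 annualisation ignores within-year covariance between
  temperature and water area beyond what the monthly product captures.
* The tier-2 vs tier-3 comparison by zone-mean temperature is not
  implemented: representative zone temperatures are not defined here.
* Establishment uses calendar years; the financial-year scan would shift
  some detections by up to six months.
* GeoJSON input assumes planar coordinates in metres (an equal-area
  projection); geographic coordinates are not reprojected.
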
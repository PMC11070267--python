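# Methods

`dielflux` quantifies the diel (24 h) timing of high-altitude insect
migration from vertical-looking radar echo data. This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic data generator does and
does not emulate.

## Diel phases from solar geometry

Four diel phases are bounded by the *geometric* centre of the sun, without
refraction correction: crepuscular morning (nautical dawn → sunrise, sun
centre rising from −12° to 0°), day (sunrise → sunset), crepuscular evening
(sunset → nautical dusk, 0° to −12° setting) and night (nautical dusk →
next nautical dawn). A *diel day* is anchored at nautical dawn and runs to
the next nautical dawn, so the night interval is contiguous and belongs to
the anchor date of the dawn that opens it; this follows the phase ordering
morning → day → evening → night and avoids splitting night at midnight.

Solar elevation uses a low-accuracy NOAA/Meeus-class ephemeris (declination
and equation of time from Julian-century polynomials). Cross-checked
against an independent Astronomical Almanac formulation, elevations agree
to < 0.01° over 1950–2100; the design target is 0.2° elevation and 60 s on
event times, ample for phase bins tens of minutes long. Event instants are
found by a 60 s bracketing grid between the solar culminations (refined to
well below a second by root finding); solar noon/midnight by bounded scalar
minimisation.

High-latitude rules:

- **No nautical night** (sun stays above −12° all night, lat ≳ 54.5° near
  the solstice): the whole sunset → next-sunrise span is twilight; its
  first half (by clock time) is crepuscular evening, the second half
  crepuscular morning, and no night interval is emitted. The diel-day
  boundary becomes the twilight midpoint. The midpoint is split by clock
  time; splitting at solar midnight instead would move the boundary only by
  the equation-of-time drift across one night (seconds), so the choice is
  immaterial at the accuracy target but is fixed to clock time.
- **Polar day**: one 24 h `day` interval anchored at solar midnight.
- **Polar night with twilight**: rising-side twilight is morning,
  setting-side evening, split at solar noon.

Intervals are half-open `[start, end)`; a boundary instant belongs to the
later phase. Because all intervals share their breakpoints, phase durations
telescope exactly to the diel-day length.

## Migration traffic rates

An echo is kept as an insect when its insect class probability exceeds 0.4
*and* every other class probability (strict argmax), and its altitude is
within 50–500 m above the radar. Each retained echo contributes
`1/w(h)` insects per km, with the geometric −3 dB transect width

    w(h) = 2 h tan(17.5°/2)

at echo altitude `h` (the radar's nominal beam width is 17.5° at −3 dB).
The hourly migration traffic rate (MTR, insects·km⁻¹·h⁻¹) is
`Σ 1/w(h_i) × 60/effective_min`; a bin is missing when effective
short-pulse monitoring falls below 20 % (12 min of an hour). The 2°
antenna nutation offset is ignored in `w(h)`, and size-dependent detection
volume is out of scope; the synthetic generator thins detections with the
identical `w(h)`, so the estimator is exact in expectation by construction.

Rain is monitored time with zero insect traffic: echoes inside rain
intervals are discarded but the time stays in the denominator. Treating
rain as non-monitored would instead push rainy bins toward missing, which
contradicts zero-traffic semantics.

Phase aggregates (mean rate; total traffic = mean rate × phase duration)
are computed at echo level with exact phase boundaries rather than by
resampling hourly bins, avoiding fractional-hour allocation ambiguity;
hourly bins exist for the heatmaps. The same 20 % minimum-monitoring
fraction is applied per phase (configurable).

## Daily proportions and beta-regression ANOVA

Per diel day, proportional migration *intensity* is a phase's mean rate
divided by the sum of phase mean rates; proportional *traffic* divides
total traffic instead. Both sum to 1 across the phases of a day; a day is
missing when any phase aggregate is missing or the day total is zero.

Site comparisons use an "ANOVA with beta distributions", realised as beta
regression with a site factor: mean/precision parametrisation
(`a = μφ`, `b = (1−μ)φ`), logit mean link, a common precision φ, maximum
likelihood. The omnibus statistic is `2(ℓ_full − ℓ_null) ~ χ²(g−1)`;
post-hoc tests are two-group LRTs for every unordered site pair, with Holm
step-down correction applied within the family of C(g, 2) tests of one
diel phase (two measures × four phases = separate families; a pooled
family is available by passing all tests to `holm_adjust` at once).
Effect size is the signed difference of fitted pair means; magnitudes are
reported when direction is irrelevant.

Proportions are pulled off the {0, 1} boundary before fitting with
`y′ = (y(N−1) + 0.5)/N`, where `N` is the number of day-values entering
that phase's model (site exclusion is applied first, so `N` is computed on
retained sites).

Numerics: the beta likelihood depends on data only through per-group
`(Σ log y, Σ log(1−y), n)`, so fits run as a damped Newton iteration on
`(μ_1..μ_g, φ)` with an arrow-shaped Hessian solved in O(g), vectorised
over many independent problems — this makes 1000-replicate calibration
simulations take seconds. Multi-start on φ ∈ {1, 10, 100} with group
arithmetic means as initial μ; convergence at 10⁻⁸ on the log-likelihood;
φ capped at 10⁸ (degenerate zero-variance groups); LRT statistics floored
at 0. The general `fit_beta_groups` path and the vectorised pairwise path
are tested against each other.

## Synthetic generator

The generator produces echo-level data with the structure the analysis
assumes, plus integrated ground truth, so every stage is testable without
any external data.

Instantaneous flux (insects·km⁻¹·h⁻¹):

    λ(t) = S(doy) [ a_day max(0, sin e)^k
                    + a_dusk g(e) 1_setting + a_dawn g(e) 1_rising
                    + a_night 1_{e < −12°} ]

with `e` the solar elevation, `g` a Gaussian in elevation centred at −6°
(width 3°), and `S` a Gaussian seasonal envelope in day-of-year. Defaults
(`peak_flux` 400, centre mid-July, width 60 d; `a_day`=1, k=2,
`a_dusk`=2.5, `a_dawn`=0.5, `a_night`=0.15) encode the emulated diel
narrative: activity low after sunrise, peaking near midday, peaking again
— and hardest — during evening twilight, a smaller dawn peak, and a low
nocturnal floor. With these weights the evening mean *rate* exceeds the
day mean rate while the much longer day still carries the largest share of
*total* traffic, which is the intensity-vs-traffic contrast the analysis
is designed to resolve.

Event times are drawn by thinning a homogeneous Poisson candidate stream
against a 1 min-gridded envelope of λ (with a 5 % margin for between-grid
maxima); detection is thinned by `w(h)/w_max`. Altitudes are gamma
(shape 6, day mean 160 m) with an additive night shift (+40 m; half at
twilight), rejection-truncated to the 50–500 m band. RCS is lognormal
(day median 0.05 cm², σ_log 0.8) with a ×4 night median multiplier (×2 at
twilight). Insect class probabilities are beta-distributed but confined
above 0.5, so a truth insect always passes the threshold-and-argmax filter
and detection is governed by `w(h)` alone; contaminants (5 % birds, half
of them insect-ambiguous with p_insect in (0.4, 0.5) to exercise the
argmax rule, and 5 % non-biological clutter) never pass it. Insects do not
fly during simulated rain (λ is zeroed there in both the event stream and
the truth integration), matching the pipeline's rain rule. Rain
(0.3 d⁻¹, mean 2 h) and monitoring outages (0.05 d⁻¹, mean 3 h) are
Poisson interval processes.

Ground truth per site/diel-day/phase integrates λ on a 10 s Riemann grid
(verified against a 1 s reference within 0.1 % in the tests); RCS medians
and band-truncated altitude means/medians are computed from the regime
distributions. Per-site streams are sub-seeded from the master seed and a
CRC of the site id, so networks are reproducible and single sites stable
under reordering.

What the generator does **not** emulate: size-dependent detection volume,
wind/temperature drivers, taxon mixtures, temporal autocorrelation of
daily proportions, and classifier errors that remove true insects.
Passing recovery tests therefore demonstrate the pipeline's internal
consistency under its own assumptions, not field accuracy of the radar
classifier or detection model.

## Problem sizes and runtime choices

The bundled study uses a 14-site transect (43.5–59.1° N, one site per
1.2°) over 2021-08-20 … 2021-09-30, a window in which every site has
nautical night so all four phases occur everywhere and the post-hoc family
is complete (91 pairs per phase). The summer-pattern analysis uses one
mid-latitude June; estimator-recovery runs use a constant-flux
configuration (60 insects·km⁻¹·h⁻¹, no rain/outages, ~500 monitored
hours). Calibration simulations use 14 groups × 30 observations with
1000 replicates. These sizes keep the whole analysis in minutes on one
CPU while leaving Monte-Carlo error well below the tested tolerances.

## Known limitations

- The MTR normalisation is the geometric transect width; absolute rates
  from real radars calibrated with a different detectability model will
  differ by a size-dependent factor.
- The χ² reference for the LRT is asymptotic; at very small per-site day
  counts the omnibus test can be mildly anti-conservative (the calibration
  test pins it to [0.03, 0.07] at n = 30 per group).
- Solar event times are specified to 60 s; diel-phase boundaries inherit
  that tolerance, which is negligible against phase durations but matters
  for echoes within seconds of a boundary.
- Months in which a phase never occurs (no-night summer months at high
  latitude) get missing RCS shares rather than renormalised three-phase
  shares.
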
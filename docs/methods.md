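# Methods

## Model and procedure

`twilightfix` estimates positions from the *timing* of twilight events
only, never from raw light curves, so it applies to data from any logger
brand. One location step corresponds to one consecutive pair of twilight
events (dawn→dusk or dusk→dawn); with both pairings used, a full day
contributes two steps.

The estimator is a forward probability sampler. Within one iteration,
starting from the known release position, each step expands its twilight
pair into a cloud of candidate positions, weights the candidates, and
selects one at random with probability proportional to weight; the
selected particle anchors the speed constraint of the next step. A cloud
whose weights are all zero is discarded as implausible and the elapsed
time accumulates into the following step, so speed limits stay physical
across gaps. Iterations use independent RNG substreams spawned from one
seed (`numpy` `SeedSequence`), which makes runs reproducible bit for bit
and iterations statistically independent.

The reported track is the per-step *geographic medoid* of the selected
positions across iterations — the point minimising the summed
great-circle distance to the others. Unlike a mean it is always an
actually computed location and cannot fall onto land that every particle
avoided. Uncertainty is reported as empirical distance quantiles (50%,
95%) around the medoid plus central longitude/latitude intervals, and a
per-step retention fraction (share of iterations that kept the step)
replaces any hard inclusion rule: the sampler discards clouds, and how
often a step survived is information the user should see.

### Threshold geolocation core

Longitude comes from the pair midpoint read as local apparent noon
(dawn→dusk) or midnight (dusk→dawn), corrected by the equation of time.
Latitude must satisfy the twilight condition
`sinφ·sinδ + cosφ·cosδ·cosH = sin a` at both events, with per-event
declination δ and hour angle H. Summing the two conditions gives
`A·sinφ + B·cosφ = C`, solved in closed form; the two arcsin branches
are disambiguated by requiring the sun above the threshold angle at
local noon and below it at midnight, falling back to the smaller
day-length mismatch. When `|C| > √(A²+B²)` no latitude reproduces the
observed day length (the equinox degeneracy) and the fix carries a
defined longitude with an undefined latitude. Because the midpoint is
only local noon when the day is symmetric, the longitude is then refined
twice against the per-event hour angles at the solved latitude. The
closed form needs no iteration per particle and vectorises across whole
clouds; round-trip error against the package's own twilight predictor is
below 10⁻⁴ degrees away from the degenerate zone (the acceptance suite
asserts 0.3°).

Solar declination and the equation of time use the NOAA low-accuracy
(Meeus-style) polynomial series — no ephemeris files, valid well beyond
1990–2100 at the accuracy light-level geolocation can use. The test
suite cross-checks them against an independently implemented almanac
approximation and textbook envelope values (±0.05° declination, ±0.5 min
equation of time).

### Twilight error model

Shading can only hide the sun, not invent it, so twilight errors are
one-sided: observed sunrise late, observed sunset early. Offsets are
`LogNormal(shape, scale) − delay` minutes on the log scale
(default `2.49 / 0.94 / 0`, median `e^2.49 ≈ 12 min`, a structure
appropriate for open-habitat species). Cloud generation *subtracts* a
fresh signed draw from each observed event to propose candidate true
twilight times; the synthetic generator *adds* the same signed draws to
true twilights. `fit_twilight_error` fits the model to calibration
residuals at a known site by maximum likelihood on the log offsets.

Each particle also draws a solar elevation angle uniformly from a
configured range (default −7° to −1°), shared by the two events of its
pair since shading conditions correlate within a day
(`independent_pair_angles` exposes the alternative; the per-event angles
are then averaged for the closed-form solve).

### Boundary box and equinox windows

Particles outside the configured longitude/latitude box are removed
(boxes do not wrap the dateline). Inside equinox windows — by default 21
days either side of each equinox, a common field practice; the window is
fully configurable and should cover any period where day length is
uninformative for the species' latitude range — every particle keeps its
computed longitude and takes a uniform random latitude over the box.
Outside windows, fixes with undefined latitude get the same treatment
(switchable via `randomize_undefined_lat`) so near-window clouds stay
non-degenerate.

### Weighting

All weighting components return multiplicative factors, so application
order never matters and a single zero is absorbing:

- **Land** (`land_weight`): factor 0 on land in marine mode (inverted
  for terrestrial studies). Masks can be shapely polygons or boolean
  grids.
- **Speed** (`speed_weight`): required speed s = great-circle distance
  from the previously *selected* particle divided by elapsed time.
  Factor 1 up to the fastest most-likely speed `best`, Gaussian tail
  `exp(−(s−best)²/2sd²)` up to the hard cap `vmax`, 0 beyond. The
  `(best, sd, vmax)` triplet is the element-wise linear blend of the dry
  (flying; default 12/6/45 m s⁻¹) and wet (drifting with currents;
  default 1/1.3/5 m s⁻¹) priors by the wet fraction of the interval from
  the immersion record — the blend degrades gracefully and reduces to
  each pure regime at wet fractions 0 and 1. The plateau-then-tail shape
  encodes "fastest most likely / sd / maximum allowed" directly.
- **SST** (`sst_weight`): d = logger SST − satellite SST at the
  particle's nearest grid cell on the step's day. Factor
  `exp(−d²/2σ²)`, σ² = `sst_sd`² + cell error² (independent errors in
  quadrature; `sst_error_combine="add"` sums the sds instead), zeroed
  where |d| exceeds `max_sst_diff` (default 3 °C) or the cell is missing.
  Logger SST per step is the daily median of temperature samples taken
  while wet. Defaults: `sst_sd` 0.5 °C (thermistor accuracy). Steps
  without a logger value, and days outside the field's coverage, pass
  weights through unchanged — missing data must never zero a cloud.
  Lookup is nearest-cell without interpolation: the native grid
  resolution is the information floor of the product.

### East–west movement compensation

An animal moving in longitude between the two events of a pair distorts
the apparent day/night length by 4 min per degree. With the previous
selected longitude as reference, each particle's two event times are
shifted symmetrically by ±2·Δlon minutes (midpoint, hence longitude,
unchanged) and latitude is re-solved; for eastward movement this
lengthens the apparent dawn→dusk day and, by the same formula, the
dusk→dawn night. Δlon between steps is a proxy for the displacement
within the pair's interval, so the correction is partial by
construction; the test suite verifies the property that matters — on a
simulated steady eastward transit, latitude bias is smaller with the
compensation than without. The flag is on by default.

## Parameters (units, defaults, rationale)

| Parameter | Default | Meaning |
|---|---|---|
| `particle_number` | 10 000 | replicates per twilight pair |
| `iteration_number` | 200 | independent forward paths |
| `sunrise_err`, `sunset_err` | 2.49 / 0.94 / 0 | log-normal shape, scale (log-minutes), delay (min) |
| `solar_angle_range` | (−7°, −1°) | civil-twilight elevation band; no calibration |
| `boundary` | — (required) | plausible lon/lat box |
| `days_around_*_equinox` | 21 d | latitude-randomization window half-width |
| `speed_dry` | 12 / 6 / 45 m s⁻¹ | flight prior: best / sd / cap |
| `speed_wet` | 1 / 1.3 / 5 m s⁻¹ | drift prior (ocean-current speeds) |
| `sst_sd` | 0.5 °C | logger temperature accuracy |
| `max_sst_diff` | 3 °C | hard SST tolerance |
| `east_west_comp` | on | longitudinal movement compensation |
| `rng_seed` | 0 | master seed for all substreams |

Defaults describe wide-ranging pelagic seabirds; diving or forest
species need their own error model and speed priors.

## Synthetic data: what it emulates and what it does not

The generator produces a correlated random walk on the sphere (von Mises
headings, truncated-normal flight speed, drift while wet), twilights
computed at the position the animal occupies at each event and perturbed
by the same log-normal shading model the estimator assumes, a daily
0.25° SST field (base + 1 °C per degree latitude meridional gradient +
smoothed spatial noise + slow drift, clipped at the freezing point as
real high-latitude SST is), 4-hourly logger temperatures (field value at
the true position + thermistor noise), a two-state wet/dry record with
~30-min bout cycles, and optionally a small island polygon. Two default
deployments mirror the contrasting light regimes of a mid-December
(solstice) and a late-March (equinox) trip at 54° S in the Southwest
Atlantic.

Because generator and estimator share the twilight error model, passing
tests show the machinery is correct and self-consistent — not that the
error model fits any particular species, logger, or habitat. Real data
add model misspecification the synthetic tests cannot see: falsely
assigned twilight events, behaviour-dependent shading, SST fronts
sharper than the grid, and fewer wet samples than the duty cycle
assumes. The synthetic SST gradient is deliberately informative
(~1 °C/deg latitude); in regions with weak gradients the equinox rescue
will be correspondingly weaker.

## Numerical choices

- Great-circle distances: haversine on a sphere of radius 6371.0 km,
  used identically everywhere (speeds, medoid, quantiles, simulation).
- Longitudes half-open in [−180, 180); timestamps UTC throughout; UTC
  calendar days bound twilight prediction and logger-SST medians.
- Latitude branch selection tolerance 1e-12 on the feasibility
  inequalities; solutions confined to |φ| ≤ 89.9°.
- Twilight prediction refines declination and equation of time at the
  event times over three passes; polar day/night are distinct flags, not
  errors.
- Medoid ties break to the lowest input index; distance quantiles use
  numpy's default linear interpolation.
- Empty clouds are legal values: the sampler records the step as skipped
  and the path, ensemble and outputs all tolerate zero retained steps.

## Sensitivity metrics

Two error measures are reported when sweeping particle or iteration
counts: the medoid-track error (quality of the reported answer) and the
median distance from the *nearest* selected particle to the truth per
step (how well the iterated ensemble covers the truth). Particle count
chiefly moves the first; iteration count moves the second monotonically
— as an order statistic it keeps improving slowly with more iterations —
while the reported track stabilises much earlier, which is what the
acceptance suite's plateau check measures (stable by ≤ 60 iterations on
the equinox scenario).

## Known limitations

- No movement model *between* the two events of a pair beyond the
  east–west correction; fast meridional movement within a day is
  unmodelled.
- No backward smoothing: each iteration is a forward pass, so early
  steps ignore later information.
- Boundary boxes and SST grids do not wrap the antimeridian; tracks
  crossing it need a rotated frame.
- The latitude solve near the poles (|φ| > 89.9°) and within polar
  day/night is out of scope.
- Nearest-cell SST lookup means accuracy is floored by the grid
  resolution of the environmental product.
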
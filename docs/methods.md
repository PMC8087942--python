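# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of the `aidsim` framework: what each component assumes,
which knobs matter, and what passing tests do and do not demonstrate.

## Insulin kinetics

Subcutaneous insulin action is the two-parameter exponential model used by
both open-source AID ecosystems (see README for the closed form). The
parameterization requires the peak to fall in the first half of the action
window (`tpa − delay < (dia − delay)/2`); outside that region the time
constant is undefined and construction raises a `ParameterizationError`.
By construction the model satisfies `IOB(0) = 1`, `IOB(dia) = 0`, unit
activity integral, and a unique activity maximum at exactly `tpa` — the
test suite verifies each against quadrature rather than trusting the
algebra.

Defaults: the pig model is `(delay 0, tpa 25 min, dia 180 min)`, matching
the fast insulin kinetics of pigs; the Loop-variant curve is
`(15, 25, 180)` — the onset delay is used only by the Loop controller's
internal model, while the simulated animal always follows the
zero-delay curve. This deliberate 15-min plant–model mismatch is the only
model error the Loop controller faces.

Curve fitting (`fit_action_curve`) holds the onset delay fixed and fits
`tpa` and `dia` by least squares of the scaled activity shape against
peak-normalized concentration samples, parameterized as `(amplitude, tp,
dia/tp)` with `dia/tp ≥ 2.05` so every iterate is a valid curve.
Concentration is treated as proportional to activity; with samples only on
the rising/peak region the duration is weakly identified, which is why the
fit is validated on peak-time recovery.

## Virtual pig

The pig is a single-compartment mass-balance model chosen for exactness
rather than physiological detail:

* **Steady state by construction.** Net endogenous glucose production is
  `ISF·basal/60` mg/dl per minute, so delivering the configured basal
  holds glucose constant, mirroring how basal requirements are defined by
  overnight stability. The simulator pre-seeds one full curve-duration of
  basal dosing history so minute 0 is already at steady state.
* **Discrete kernels conserve mass exactly.** Dose effects use per-minute
  kernels built from IOB differences (they telescope to exactly 1), so the
  total glucose drop from a bolus is exactly `ISF·units` and a meal's
  total rise is exactly `CSF·grams` with `CSF = ISF/ICR`. The in-silico
  IV sensitivity test therefore recovers each pig's ISF to machine
  precision, and basal titration recovers the true rate — these are
  calibration checks of the generator, not of any estimator.
* **Absorption profiles.** Intravenous insulin acts over a 90-min triangle
  (peak 15 min), consistent with glucose stabilizing ~90 min after an IV
  bolus. Carbohydrate absorption is triangular: *fast* (sugared
  applesauce) peaks at 30 min and completes by 120 min; *mixed* (chow)
  peaks at 90 min and completes by 240 min. Real chow absorption is longer
  and far more variable; see Limitations.
* **CGM.** Readings every 5 min: truth plus a −3 mg/dl bias (the sensor
  class tends to under-read slightly) and Gaussian noise with SD 5 mg/dl,
  clamped to the 40–400 mg/dl reporting range. All noise flows through a
  seeded `numpy` generator; identical config + seed gives bit-identical
  traces.
* **Floor.** True glucose is clamped at 20 mg/dl (and the clamp logged) to
  keep pathological runs physical.

The in-silico basal titration steps the candidate rate toward smaller
overnight drift and stops when no neighbouring rate improves, provided the
drift is within the 30 mg/dl stability band; a perfectly stable night
returns immediately. Stepping only to the *first* rate inside the band
would stop at the band edge (up to 0.03 U/h from truth at these ISFs) —
descending to the drift minimum is what makes recovery exact to one step.

## oref1-style controller

Every 5-min reading the controller computes per-interval deviations
(observed ΔBG minus the change expected from net insulin activity alone;
intervals with >10-min gaps are skipped), then three forecasts on a 5-min
grid out to 240 min, each clamped at 39 mg/dl:

* **insulin-only** — remaining action of the net dose log;
* **zero-temp** — the same plus every future minute of scheduled basal
  counted as a withheld (negative) dose: the worst-case path if absorption
  ceases and delivery is suspended;
* **unannounced meal** — the deviation series extrapolated to zero and
  integrated on top of the insulin-only path. Extrapolation cases:
  falling deviations continue at their rate; deviations falling slower
  than the line reaching zero in 3 h are forced onto that line; rising
  deviations peak immediately and decay at one-third the rate they rose
  from their minimum over the last 60 min (never slower than the 3-h
  line, so every case reaches zero within 180 min).

The dosing floor is `minPredBG = max(min insulin-only forecast from 90 min
on, average of (min UAM forecast from 60 min on) and (min zero-temp
forecast))`, converted to `insulinReq = (minPredBG − target)/ISF`. Half of
a positive requirement is an SMB, capped by 30 min of scheduled basal and
by `max_iob` headroom and floored to the 0.05-U pump step; the remainder
(still headroom-capped) is a 30-min temp basal delivering it at
`basal + 2·remainder` U/h. Non-positive requirements become below-schedule
temp basals down to zero. Per-cycle headroom accounting makes IOB ≤
`max_iob` invariant under any command sequence.

Defaults: target 110 mg/dl (mid-range of the 70–180 band; the in-vivo
target is not reported), `max_iob` 2.0 U, `max_temp_basal` 35 U/h (the
pump ceiling), horizon 240 min. All insulin bookkeeping is net of
scheduled basal.

## Loop-style controller

A single forecast: current reading plus insulin effect (net dose log
through the 15-min-onset curve), glucose momentum (the four most recent
5-min deltas weighted 1:2:3:4, extrapolated and blended linearly to zero
over 30 min — the cumulative shift persists), and retrospective
correction. The carbohydrate component is identically zero: no meals are
announced.

Retrospective correction pairs each reading with the forecast issued one
correction window (30 min) earlier; the correction term is the mean of the
discrepancies recorded over the last window, and in integral mode adds
`gain × (exponentially forgotten running sum)` (gain 0.1, half-life one
window, clamped to ±3× the standard term) for faster adaptation to
sustained disturbances. The term is applied as a glucose *velocity* —
re-accrued over the coming window with the rate blended to zero by the
60-min decay horizon — so the forecast's eventual value shifts by
(approximately) the discrepancy itself. Two design points matter here:
pairing with the window-old forecast is what makes unannounced-meal
excursions visible at full size, and applying the term as a persisting
shift is what lets it influence dosing at all, since dosing reads only the
forecast's eventual value and minimum. A correction that merely decayed
inside the horizon would be invisible to both.

Dosing is temp-basal only (the command type has no bolus field). Any
actual or predicted glucose below the 70 mg/dl suspend threshold forces a
zero temp basal; otherwise
`units = min((eventual − target_mid)/ISF, (min predicted − suspend)/ISF)`
is delivered over 30 min as `basal + 2·units` U/h, clamped to [0, 35].
Target range 100–115 mg/dl. The controller retains its last 12 forecasts
(60 min) for discrepancy computation; the integral memory is a 48-entry
(4-h) discrepancy deque, effectively unbounded given the half-life.

## Challenge protocol

Days start at 01:00 at 120 mg/dl under steady basal. Meals: 66 g fast at
07:30, 132 g mixed at 13:30 and 19:00. Windows: breakfast 6 h, lunch and
dinner 5 h, overnight 01:00–07:00. The scored overnight window for a
pig-day is the one *following* that day's dinner: post-dinner carryover is
what overnight control is about, and scoring the same-day 01:00–07:00
interval would grade the steady-state initial condition instead. A run of
`days` days therefore simulates `days·1440 + 360` minutes, and the initial
(meal-free, steady-state) night is unscored.

Rescue carbohydrates (10 g, fast profile) are given when the CGM and a
confirmatory measure both read below 55 mg/dl or the CGM alone reads below
40; the simulation uses true glucose as the confirmatory "ear-prick"
measure, which the CGM's negative bias makes meaningful. After a rescue,
further rescue checks pause for 30 min while the sugar absorbs. Any rescue
flags the enclosing window as a severe hypoglycemic event. Windows whose
CGM record has a gap over 60 min are excluded; the default sensor never
drops out, so the rule is exercised only in tests with synthetic outages.

Metrics are computed on CGM readings: TIR is the percentage of 5-min
readings in [70, 180] (bounds inclusive), time-below-70 strictly below;
TIR + below + above partitions to 100%. Aggregation is mean ± SE across
pigs with each pig first averaged over its days, mirroring
repeated-measures weighting; inferential statistics (mixed models, GEE)
are out of scope.

Default problem sizes — six pigs, three days per arm — keep a full
challenge arm to a few seconds of compute while giving every pig multiple
scored windows per meal.

## What the simulator does and does not show

The generator reproduces the *statistical structure* the analysis assumes
(steady basal state, dose conservation, sensor noise and bias, the meal
schedule) but not the physiology of a live pig: no endogenous glucose
regulation beyond the constant production term, no absorption variability
between meals or days, no insulin-sensitivity drift, no sensor dropout.
Two consequences are worth stating plainly:

* Passing parameter-recovery tests shows the generator and protocols are
  self-consistent, not that the protocols would recover parameters in an
  animal.
* Because the controllers' internal models coincide with the plant (up to
  Loop's 15-min onset offset and CGM noise), both controllers regulate
  glucose back to target within ~2 h of the end of meal absorption. The
  oref1-style controller outperforms the Loop-style controller in every
  *meal* window (where the unannounced-meal machinery matters) and
  overall, but the overnight window — beginning 2 h after dinner
  absorption completes — is held fully in range by *both* controllers, so
  the large overnight separation observed in live animals (driven by
  prolonged, variable chow absorption and pharmacokinetic variability that
  the plant lacks) appears here only as a ceiling tie. The in-silico
  comparison is directional for the meal windows and conservative for the
  night.

## Numerical choices

* Continuous-time curve formulas; the simulator advances on a 1-min grid
  with kernels discretized by IOB differences (exact mass), controllers on
  a 5-min grid to a 240-min horizon.
* Forecast clamp at 39 mg/dl (oref1 arrays); simulator floor 20 mg/dl.
* SMB rounding floors to the 0.05-U pump step with a 1e-9 guard against
  float-edge truncation.
* Titration rates are rounded to 1e-6 U/h between steps to keep candidate
  grids exact; revisiting a candidate terminates the search.
* Seeds: per-pig generators are spawned from `SeedSequence([seed, pig_index])`,
  so herd composition changes do not perturb other pigs' streams.
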
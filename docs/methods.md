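# Methods

`valveflow` is a software twin of a compact pneumatic control box for
microvalve-enabled ("Quake-style") microfluidic assay chips, together with
the fluidic device it drives and the colorimetric readout that follows.
Everything runs without hardware: a simulated plant stands behind the same
hardware-abstraction contract a serial-attached control box would use, and
a synthetic micrograph renderer stands in for the microscope camera.  This
note records the models, their assumptions, the parameters that matter,
and what the simulations can and cannot say about real devices.

## Pneumatic plant

Each of the three pneumatic circuits (high pressure for microvalve
actuation; low positive and low negative for metering liquids) is a lumped
isothermal gas reservoir:

    dP/dt = (Q_pump - Q_vent) * P_atm / (60 * V)        [psi/s]

with standard flows Q in sccm, reservoir volume V in mL and
P_atm = 14.7 psi.  Pressures are gauge (0 = ambient) and clamped to
[-14.7, stall].  Flows are:

* **pump** (diaphragm, linear head curve): `Q = free_flow * max(0, 1 - head/stall)`,
  where head is the reservoir gauge pressure (its negation for the
  evacuating pump).  A linear curve is the standard first-order
  approximation for small diaphragm pumps; no data sheet is modelled.
* **vent** (solenoid orifice, laminar): `Q = conductance * P`, signed, so a
  negative reservoir vents inward.

Integration is fixed-step explicit Euler, default dt = 1 ms.  The step is
justified by an oracle test: charging the high reservoir is the linear ODE
`dP/dt = k (stall - P)` with closed form `P(t) = stall (1 - e^{-kt})`, and
the stepper agrees with it to <= 1e-3 psig over 1 s (the vent-discharge
exponential is checked the same way).  The plant update itself is
deterministic; all randomness lives in the sensor model (truth + Gaussian
read noise, rounded half-away-from-zero to the quantization step), driven
by one explicitly passed seeded generator per run.

Default plant (all configurable through `PlantConfig` / JSON):

| circuit       | pump (sccm / stall psig) | reservoir (mL) | vent (sccm/psi) |
|---------------|--------------------------|----------------|-----------------|
| high          | 2000 / 30                | 100 (accumulator) | 100          |
| low positive  | 50 / 8                   | 20 (accumulator)  | 30           |
| low negative  | 50 / 8 (evacuating)      | 5 (line volume; no accumulator) | 8 |

Sensor defaults: noise sd 0.05 psig, quantization 0.01 psig, sample period
10 ms.  The low-side figures were sized so that the modelled hardware can
do what the real unit's printed precision says it does: with a 2 slpm pump
on a 20 mL reservoir a single 10 ms actuation period moves the pressure by
~0.23 psi, which no controller could reconcile with 3% precision at
0.5 psig; 50 sccm metering pumps and small vent conductances put every
single-period actuation quantum below the regulation deadband at the
relevant setpoints.  The high side keeps the large pump: its deadband at
25 psig (0.125 psi) dwarfs the actuation quantum anyway.

Not modelled: thermal effects, pump pulsation, tubing elasticity, choked
flow, chip gas consumption (microvalve control lines are dead-ended and
liquid metering draws nL/s, negligible against reservoir volumes).

## Pressure regulation

The decision rule is a memoryless three-zone bang-bang with hysteresis
around the setpoint: band `delta = max(relative_deadband * |setpoint|,
min_deadband)`; below the band (toward atmosphere) the pump runs, beyond
it the vent opens, inside it both actuators hold closed (to spare the
solenoids; the accumulator needs no active hold because the plant is
leak-free).  Negative setpoints run the same rule on |P| with sign
bookkeeping.  Defaults: relative deadband 0.5%, absolute floor 0.005 psig,
so the band is 1% wide (+-0.5%) at large setpoints and +-1% of 0.5 psig at
the smallest one - half of each printed precision budget, leaving the
other half for actuation overshoot.

The execution loop around the rule handles a sensor whose read noise
(0.05 psig) is an order of magnitude larger than the smallest deadband.
Acting on raw samples chatters on noise; a long moving average limit-cycles
on its own lag (both were observed in simulation).  The loop therefore has
two regimes:

* **slew**: far from the setpoint (beyond 20 deadbands), continuous
  bang-bang on a short 8-sample average;
* **settle-and-measure**: near the setpoint the actuators hold closed
  while readings accumulate.  A closed, leak-free reservoir is strictly
  conservative, so the accumulating mean is an unbiased estimate of the
  true pressure with standard error `noise_sd / sqrt(n)`.  Once at least
  `confirm_samples` (200, i.e. 2 s) have been averaged and the mean sits
  outside the band by more than `margin_sigma` (2) standard errors, the
  regulator fires an actuation *burst* of `ceil(err / (q_hat *
  burst_caution))` periods, where `q_hat` is a per-actuator estimate of
  the pressure moved per period, learned from the observed response of
  previous bursts (updates only when the cumulative movement resolves
  above measurement noise, clamped to a 3x change per update).  Both pump
  and vent rates fall monotonically toward the target, so bursts
  systematically undershoot; the caution factor (1.5) means a burst only
  crosses the band if the mean estimate was off by more than a third of
  the true distance.  Internally the controller regulates into half the
  deadband, so a landing marginally outside the control band is still
  comfortably inside the reported one.

This is the kind of loop a microcontroller firmware actually runs for
"pump to setpoint, vent the excess" regulation.  With the default plant it
holds, worst case over many seeds of 60 s runs: ~0.1% at 25 psig, ~0.4% at
+-5 psig, and <= ~2% at 0.5 psig - inside the printed 1%/1%/3% figures
with margin.  With a noiseless sensor the post-settle trajectory is
confined to the deadband exactly.

**Precision metric.**  `precision()` reports the worst-case post-settle
deviation as a percent of the setpoint - the stricter reading of a
"percent precision" claim; the mean-absolute alternative is reported
alongside in trace summaries.  The settle clock starts when the true
pressure first enters the deadband (the standard settling-time definition)
and the scored window opens `settle_time` (5 s) later.  Counting settle
time from t = 0 instead would be meaningless here: charging the high
accumulator from ambient to 25 psig takes ~11 s of pumping by the plant's
own physics, and a metric that scored the charge transient would measure
the pump, not the regulator.

**HAL.**  The controller talks to any back-end through five operations:
`set_solenoid`, `set_pump`, `read_pressure`, `now`, `wait`.  `wait` is the
one addition over the obvious four - passing time must be explicit so the
simulator can integrate the plant while real hardware would sleep.  A
line-oriented serial protocol (`P <id> <0|1>`, `V <id> <0|1>`,
`R <label>`, `T`, `W <s>`) is provided for future hardware; tests drive it
through an in-process loopback and verify the controller produces an
identical actuation sequence either way.

## Protocols and scheduling

A protocol is an ordered list of steps, each fixing all six microvalve
states, per-circuit setpoints, which chip ports each circuit reaches, and
a duration; preparation steps must precede assay steps.  The compiler
expands steps into timestamped events (idempotent full valve
configuration + setpoint changes at each step start; one alternation event
per mixing half-period; terminal all-safe) and is deterministic.
Protocols serialize to versioned JSON and round-trip exactly.

The built-in glucose workflow: preparation = 25 psig valve fill (5 min)
plus a 10 min reagent-loading delay; assay = open the membrane-to-vacuum
path (2 s), pull plasma at -1 psig (30 s), fill sample + reagent chambers
at +1 psig (20 s), degas at +4 psig with outlets sealed (3 min),
depressurize the flow layer and sequester every unit (10 s, configurable),
then alternate V3/V5 every 1 s (configurable half-period) for 8 min,
ending with all valves activated except V3.  The assay phase totals 722 s,
inside the 15 min budget.  Every assay step keeps the high circuit
regulated at 25 psig - the microvalves hold only while their control lines
are pressurized, and the executor simulates exactly that (an early version
that dropped the high setpoint during mixing produced an immediate
cross-contamination failure, which is the model working as intended).
The built-in separation workflow is the two-step pull (-1 psig, 2 min) /
push-out (+1 psig, 60 s default).

The executor dispatches events on a 10 ms tick, runs one bang-bang
controller per active circuit, and, when a chip model is attached, applies
the step's fluid processes each tick using the circuits' *live* simulated
pressures (not the nominal setpoints) at the step's ports.

## Fluidic chip

The chip is a valve-gated undirected graph of lumped compartments with
hydraulic resistances.  A microvalve is closed when its control line is at
or above 20 psig (boundary closed by convention).  Flow between two ports
at different pressures follows the open path of least total resistance at
`Q = dP / sum(R)`; all edges default to 0.01 psi/(nL/s) because the
published device gives no channel dimensions - consequently fill
*completeness*, routing and isolation are contracts of the model, fill
*times* are not.  Pressurized ports also dead-end-fill open chambers that
have free capacity (air escapes by compression and permeation, which is
how degassed chambers top up with liquid).

Each node holds a FIFO queue of (species, volume) parcels rather than a
bare inventory: channels and chambers have spatial order, and first-in
first-out reproduces both directions of plug flow (a chamber's initial air
is displaced ahead of incoming liquid; air pushed in behind a liquid plug
expels the plug instead of tunnelling through it).  Parcels an edge cannot
pass - blood cells at the plasma-only membrane edge, trapped chamber
air - are skipped in place, like plasma filtering past the retained cell
cake.  Liquid volume is conserved exactly under flow; air leaves only by
degassing.

Chambers retain a trapped-air fraction (4% of capacity) that flow cannot
displace - without it plug flow would fill chambers to exactly 100% and
the fill and degas contracts would be vacuous.  Degassing is first-order
decay of chamber air with tau = 45 s, chosen so the published 3 min at
4 psig removes 98% of trapped air (10 nL -> 10 e^-4 ~ 0.18 nL); it is a
proxy for gas permeation through the chip body, not a permeation model.
Active mixing is per-cycle exchange: homogeneity `h -> 1 - (1-h)(1-f)^n`
with f = 0.02 per alternation, so the 480 alternations of the 8 min
regime saturate above 0.9999; the update is associative in cycle count
and refuses to run unless the unit is sequestered from every other unit
(checked by graph reachability).

Topology: the glucose chip has a membrane node (10 uL), a 1 uL collection
channel, air/reagent inlets, five outlets and four analysis units of two
50 nL chambers each.  The published description names only V3 (atop the
sample chambers), V4 (unit sequestration) and V5 (sample/reagent
separator); the remaining assignments (V1 = membrane inlet + vacuum
branch, V2 = the five outlets, V6 = reagent + air inlets) are this
package's convention and live in the topology builder, not in the engine.
Synthetic whole blood defaults to hematocrit 0.45, so 8 uL of blood
carries 4.4 uL of plasma, comfortably above the 1 uL the collection
channel holds.

## Imaging

The quantification pipeline is: Otsu-binarize the grayscale mean
(chambers image brighter than the chip background in brightfield), take
connected components above a minimum area, sort top-to-bottom, discard the
top (sample) chamber, round the reagent chamber's centroid
half-away-from-zero and cut an exact 100 x 300 px ROI (100 px across the
chamber, 300 along it; never clipped - a chamber smaller than the ROI is
an error), average each RGB channel over the ROI, convert the mean triple
to CMYK and keep magenta.  Averaging channels first and converting the
mean triple is the canonical order (the channel means are the measured
quantities); the per-pixel alternative is implemented and differs exactly
when the dominant channel varies across pixels - a unit test constructs
such a case.  Alignment between images of a run is integer-pixel
translation matching the reagent-chamber centroids; because detection and
ROI placement are themselves translation-covariant, the pipeline's
magenta estimate is invariant to shifts of up to tens of pixels with or
without alignment.

Calibration is ordinary least squares of magenta on concentration; a
non-positive slope is a hard error ("non-responsive assay").  The limit of
detection is `3.3 * sd(blank) / slope` - the ICH Q2 convention, adopted
because the published account reports an LOD without stating a formula
(for the same reason the experimental 0.134 mM figure is not treated as a
reproducible target).  Two-point quantification interpolates linearly
between 0 mM and 8 mM references measured on the same device; estimates
outside [0, 8] mM are returned as-is with an extrapolation flag.

**Renderer.**  Two stacked rectangles (160 x 400 px each) over a dark
background (gray 60): the sample chamber a fixed pale tone, the reagent
chamber drawn at level L = 250 as `R = B = L, G = L (1 - m)` with
`m = min(0.95, base + 0.08 * conc)`.  This construction converts back
through CMYK to exactly the set magenta, so the fitted calibration slope
on noiseless renders equals the 0.08 /mM gain to machine precision (the
strict 1e-6 check uses the renderer's float64 mode, since 8-bit
quantization alone perturbs a slope at the 1e-4 level; the defaults are
chosen so integer-mM concentrations land on exact 8-bit values anyway).
Gaussian pixel noise (default sd 2 intensity units) and a linear
illumination ramp are added per-seed, deterministically.

What the renderer does *not* emulate: absorbance physics and optical path
length, chamber edge artefacts and the rounded microvalve shadows that
motivated discarding the sample chamber, color-camera response, uneven
reagent mixing, focus.  Passing the end-to-end recovery test (1, 4, 8 mM
recovered within +-5% through two-point referencing at pixel noise sd 2,
ten seeds) therefore validates the pipeline's geometry, color arithmetic
and statistics - not assay chemistry on real micrographs.

## Problem sizes and reproducibility

Regulation runs are 60 s at a 10 ms control period and 1 ms plant step;
protocol executions run the full published durations (180 s separation,
722 s assay) at a 10 ms tick with the plant stepped at the same rate.
Acceptance figures use ten seeds per condition and report the worst seed.
Every stochastic component takes an explicit integer seed; identical seeds
give bit-identical traces, schedules, images and CSV/JSON outputs.

## Known limitations

* Hydraulics are lumped and resistances uniform; flow rates and fill
  times are order-of-magnitude plausibility, not predictions.
* The membrane never clogs and passes plasma regardless of hematocrit or
  throughput; hemolysis is out of scope.
* The regulator's measure-and-burst loop assumes a leak-free plant during
  holds; a leaky manifold would need the duty-cycle or PID extensions the
  bang-bang contract deliberately avoids.
* The serial HAL is exercised only through the loopback transport; timing
  jitter, latency and framing errors of a real link are not modelled.
* The renderer's noise is i.i.d. Gaussian per pixel; real cameras add
  shot noise, fixed-pattern noise and demosaicing correlations.
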
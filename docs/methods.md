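# Methods

This note documents the models and design choices behind the package: what
the simulated spectrometer does and does not emulate, how the on-the-fly
parameter computations are defined, the defaults and why, and what the
passing tests do and do not establish about behaviour on real hardware.

## The automation procedure

A series run processes samples in manifest order. Per sample the engine
performs: insert → deuterium lock on the declared solvent → optional probe
tune/match → shim → create the sample folder → run each experiment in its
declared order. Per experiment, parameter modifications are applied in a
fixed order so the modification ledger is deterministic and every
difference between the stored parameter set and the acquired-with
parameters is attributable to exactly one audited step:

1. **PROSOL merge** — pulse length (µs) and power (dB) replaced from the
   instrument profile's per-nucleus calibration table.
2. **NS multiplier** — NS′ = NS × m, m ≥ 1, per sample.
3. **Solvent-offset substitution** — if the series option is on, a
   dedicated low-NS 1D ¹H parameter set (named in the instrument profile,
   default `PROTON_QUICK`) is acquired once per sample before its
   experiment list; the tallest picked peak's position replaces the offset
   of every ¹H dimension in the queue.
4. **Adapted spectral width** — when an experiment completes that is the
   source of an adaptation rule (and its nucleus matches), its spectrum is
   peak-picked and the (SW, offset) result substituted into the rule's
   target dimension of every *later* experiment of the same sample.
5. **Receiver gain** — when gain optimization is on and the stored gain is
   `"auto"`, the ladder search below runs immediately before acquisition.

Error semantics: failures during insert or lock skip the sample (all its
experiments are marked `skipped`); failures during tune/match or shim are
audited and the sample continues unprepared; failures during load, gain
search or acquisition fail that one experiment. Anything outside the
instrument contract (an unexpected exception class) aborts the series with
a fatal audit entry and a partial result in which every remaining
experiment is still assigned a terminal outcome, so outcome conservation
(completed + failed + skipped = configured total) holds for every run.
Shimming happens once per sample, not between experiments of the same
sample.

## The simulated spectrometer

The simulator implements the same contract a hardware driver would
(insert, eject, lock, tune_match, shim, acquire, optimize_gain, plus
shim-routine and gain-ladder queries) over ground-truth
`SyntheticSample` objects (per-nucleus resonance lists; a solvent resonance
when the solvent is protonated, constrained to ≥ 10× the largest ¹H solute
line; ¹H–¹³C correlation pairs for 2D synthesis).

**Lineshape.** Spectra are sums of frequency-domain Lorentzians evaluated
on a descending ppm axis spanning [offset + SW/2, offset − SW/2] with
uniform step SW/(points − 1). There is no FID/FT round trip: the pipeline
consumes frequency-domain data, and time-domain simulation would add
nothing the automation can observe. The observed full width at half height
is natural linewidth × shim broadening factor (`shim_quality` ≥ 1, 1 =
perfect shims), converted from Hz to ppm by the nucleus base frequency.

**Amplitude and noise.** Peak amplitude scales as
NS × gain × concentration × tune-factor; additive white Gaussian noise has
σ = `noise_base` × √NS × gain (default `noise_base` 0.5 per point). Signal
linear in NS and noise ∝ √NS gives the standard S/N ∝ √NS law the scan
multiplier exploits. An untuned probe applies a uniform sensitivity factor
0.8. Amplitudes beyond the ADC full scale (2¹⁵ arbitrary units) clip and
set a flag. All randomness is seeded; identical (sample, parameters, state,
seed) give bit-identical spectra.

**Aliasing.** 1D resonances outside the spectral window are simply absent.
2D indirect-dimension (¹³C) resonances outside the window fold by
reflection off the window edges — the visible failure mode the adaptive-SW
feature exists to avoid. Indirect digital resolution is reported as
SW × base frequency / points (Hz/point); note the 1D axis step uses
points − 1 (fencepost of the sampled axis) while the indirect figure uses
points (resolution per increment) — both conventions are common and the
difference is immaterial at the point counts used.

**Shimming.** Each call of a shim routine moves the broadening factor
geometrically toward a routine-specific floor:
quality′ = max(floor, quality × factor). Defaults: `1d-quick` (factor 0.5,
floor 1.3) and `3d` (factor 0.35, floor 1.05), so the 3D routine converges
to narrower lines, and repeated calls are monotone non-increasing with
divergence impossible by construction. Inserting a new sample degrades the
retained shim state by a disturbance factor (1.5) capped at the cold-start
value (4.0) rather than resetting it — this is what makes a series
pre-shimmed on a water standard start every subsequent sample below the
cold-start broadening. A water-standard sample is shimmed with the `3d`
routine repeatedly until the quality converges. This shim model is a
deliberately simple stand-in that reproduces the *consequences* relevant to
the automation (monotone convergence, routine-dependent floors, carryover
between samples); it makes no claim about the mechanism of real shim
optimisation.

**Receiver gain.** The ladder is discrete powers of two from 1 to 4096.
The search runs one noiseless unit-gain trial (with the clip ceiling
lifted, so the true amplitude is seen) and selects the largest ladder gain
whose scaled peak stays at or below 90% of full scale. With a ×2 ladder a
two-sided amplitude target such as [0.5, 0.9] of full scale is not always
attainable — the admissible window is narrower than one ladder step — so
the rule implemented (and tested against an exhaustive per-gain trial
oracle) is the one-sided maximum, which lands the amplitude in
(0.45, 0.9] whenever any gain is admissible. If even the minimum gain
clips, the minimum is used and a warning audited.

## Peak analysis

* **Noise estimate:** 1.4826 × median absolute deviation of the
  point-to-point first differences, divided by √2 (differencing doubles the
  variance of white noise). Robust to a sparse set of peaks by
  construction; requires ≥ 64 points.
* **Peak picking:** every interior local maximum above
  `snr_threshold` × noise estimate (default threshold 6). Positions are
  refined by a three-point quadratic fit (flagged on the peak) — sub-grid
  accuracy for offset setting without claiming a lineshape-fitting
  procedure. Edge points are never returned; two peaks merged within a
  linewidth are reported as one (documented limitation).
* **Solvent offset:** the tallest picked peak; ties break toward higher
  ppm (downfield) — any fixed rule would do, this one is documented and
  deterministic. If no peak clears the threshold the parameter-set defaults
  are kept and a warning audited; an experiment is never failed for this.
  Note the detector has no notion of "solvent": with the option enabled on
  a sample without a dominant solvent line it will centre on the tallest
  solute peak.
* **Adaptive SW:** SW = (max − min) + 2 × margin over the picked peak
  *centers*, offset = midpoint. Default margin is 5% of the detected range
  with a 1 ppm minimum; SW never shrinks below a 2 ppm floor (degenerate
  single-peak lists). Peak centers + margin were chosen over peak edges;
  the margin default absorbs the half-linewidth difference in practice.

## Manifest dialect and wizard

One STAR data block; series options as flat `_series.<key>` tags; samples
as a `_sample.*` loop (name, solvent, rack, comma-separated experiment
sets, NS multiplier, notes, water-standard flag); adaptation rules as an
`_adapt.*` loop. Values with whitespace (or that would read as tags or
keywords) are quoted; `.` is an absent value; unknown tags are warnings for
forward compatibility. Absent options take the minimal-run defaults (all
flags off, folder format `{name}_{index}`, shim `1d-quick`). The writer
emits tags in a fixed order, making write ∘ parse ∘ write byte-stable, and
parse ∘ write is the identity on valid configs (property-tested). Values
containing both quote characters cannot be represented in a single-line
dialect and are rejected by validation.

The wizard asks for the same content in a fixed prompt order (water
standard first, then requisite sample details, then the optional features,
then review). `back`/`quit` are reserved words standing in for window
buttons; revisited steps present the previous answer as the default.
Validation runs per step, so the wizard cannot produce an invalid config;
the review step re-validates the assembled whole before confirming.

Solvent vocabulary (extensible via the instrument profile): D2O, H2O+D2O,
CDCl3, DMSO-d6, CD3OD, acetone-d6 — each with a deuterium lock shift and,
for protonated solvents, the ¹H line position. Rack codes are
letter+number (A1–E96 style). Audit lines are ISO-8601 timestamp, scope,
level, message, optional JSON payload, tab-separated; `error_summary`
round-trips them and counts (rather than fails on) corrupt lines.

## Problem sizes and defaults

Defaults were fixed once, from what is typical for the instruments being
emulated, before any acceptance measurement: ¹H base frequency 500.13 MHz
(¹³C 125.76 MHz); 1D parameter sets with 4096–8192 points over 20–240 ppm;
the general HSQC with 256 indirect points over a 200 ppm ¹³C window; NS
8–16 for 1D sets, 1 for the pre-scan. The acceptance script uses 1000
random peak lists, 200 random manifests, 50-seed Monte-Carlo estimates for
the recovery and S/N rates, 100 random samples for the gain search, 20
paired seeds for the water-standard comparison, and a 3 × 3 series for
fault injection (15 injection points) — sizes at which every quantity is
stable to well under its tolerance while the whole script runs in seconds.

## Limitations

* The simulator omits pulse-sequence physics, relaxation, phase and
  baseline artifacts, temperature effects, and radiation damping; 2D
  spectra are idealized positive crosspeaks (no anti-phase or negative
  contours). Passing tests therefore validate the *automation logic* —
  ordering, bookkeeping, parameter arithmetic, error handling — and the
  scaling laws the simulator encodes, not spectral fidelity on real
  hardware.
* Narrow lines on coarse grids (e.g. a 5 Hz ¹³C line sampled at
  ~50 Hz/point in an HSQC indirect dimension) are point-sampled, not
  bin-integrated, so their sampled amplitude understates a real processed
  spectrum; deterministic position checks are unaffected.
* The shim and tune models are behavioural stand-ins with configured
  constants, not physical models.
* Timing is recorded per step but carries no meaning in simulation and is
  never asserted.
* The manifest dialect is deliberately not a general STAR/CIF parser: one
  data block, no save frames, single-line values only.
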
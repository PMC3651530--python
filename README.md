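# nmrbot

Automated, high-throughput acquisition of solution-state NMR data on large,
heterogeneous sample series — with the parameter decisions an experienced
spectroscopist would make per sample taken on the fly by the software.

Setting up NMR experiments for dozens of samples is slow and error-prone:
each sample needs a deuterium lock on its own solvent, probe tuning and
matching, shimming, a sensible receiver gain, and — harder to know a
priori — a transmitter offset sitting on the dominant solvent resonance and
a spectral width (SW) that covers the observable peaks and nothing more.
`nmrbot` orchestrates all of this over a pluggable instrument contract and
ships a simulated spectrometer backend with ground-truth synthetic samples,
so every stage of the automation runs, and is tested, without a magnet.

## What it does

* **Series description, two equivalent ways.** A STAR-format text manifest
  (samples as a `loop_`, series options as flat `_series.*` tags) or an
  interactive setup wizard whose finished session is emitted as exactly
  that manifest — so any manual setup is replayable as a text file later.
  All input is validated before acquisition starts, and every problem is
  reported at once, not just the first.
* **Per-sample instrument preparation.** Insert → lock (solvent-specific,
  works across solvent changes within a series) → optional tune/match →
  shim. An optional water-standard sample (90% H₂O / 10% D₂O) runs first
  and establishes converged three-dimensional shims that seed the rest of
  the series.
* **On-the-fly parameter optimization.**
  * *Solvent offset:* a quick 1D ¹H pre-scan is peak-picked and the tallest
    line's position becomes the ¹H offset (O1p) for every later experiment
    of that sample.
  * *Adaptive spectral width:* peaks picked from a designated 1D experiment
    define the observed shift range; flagged later experiments get
    SW = range + 2·margin and the offset centered on it. With the point
    count fixed, digital resolution (Hz/point) improves by exactly the SW
    ratio — the classic win is the indirect ¹³C dimension of an HSQC.
  * *NS multiplier:* per-sample scan multiplication for dilute samples;
    S/N grows as √NS.
  * *Receiver gain:* deterministic search over the instrument's discrete
    gain ladder for the largest gain that does not clip the digitizer.
  * *PROSOL:* calibrated pulse length/power merged from the instrument
    profile in place of the stored parameter-set values.
* **Continue-on-error.** A failed lock skips the sample; a failed
  experiment fails that experiment; everything downstream still runs. Every
  step, parameter modification and failure is appended to three audit
  scopes (console, per-sample `audit.txt`, series `series_audit.txt`) in a
  machine-parseable tab-separated format.

## Worked example

Describe a two-sample series in a STAR manifest (`series.star`) — an
aqueous metabolite mix that wants solvent-offset detection and a
¹³C-1D-driven HSQC window, and a dilute organic sample with 4× scans:

```
data_nmrbot_series

_series.find_solvent_offset      yes
_series.use_gain_optimization    yes

loop_
   _adapt.source_experiment
   _adapt.source_nucleus
   _adapt.target_experiments
   _adapt.target_dimension
   C13CPD  13C  HSQC  2
stop_

loop_
   _sample.name
   _sample.solvent
   _sample.rack
   _sample.experiments
   _sample.ns_multiplier
   _sample.notes
   _sample.water_standard
   mix_a  H2O+D2O  A2  PROTON,C13CPD,HSQC  1  'pH 7.4'  no
   org_a  CDCl3    A4  PROTON              4  .         no
stop_
```

Validate it, then run it against the simulated backend (`rack/` holds one
synthetic-sample definition file per rack position):

```bash
$ nmrbot lint --manifest series.star
OK: no issues
2 sample(s); runnable

$ nmrbot run --manifest series.star --outdir out --seed 1 --rack rack
...
done: 4 completed, 0 failed, 0 skipped; audit at out/series/series_audit.txt
```

The audit trail shows the on-the-fly decisions:

```
mix_a    info  solvent offset detected                     {"offset_ppm": 4.71968}
mix_a/1  info  receiver gain optimized                     {"receiver_gain": 32.0}
mix_a/2  info  receiver gain optimized                     {"receiver_gain": 256.0}
mix_a/2  info  adapted SW from C13CPD applied to ['HSQC']  {"offset_ppm": 70.000012, "sw_ppm": 105.6067}
```

Reading the numbers: the sample's true water line was at 4.72 ppm and the
pre-scan recovered 4.71968 ppm (within one digital step), which became the
¹H offset of all three experiments. The six ¹³C lines picked from the
C13CPD 1D span 22–118 ppm, so the HSQC's indirect dimension was narrowed
from the general 200 ppm default to 105.6 ppm centered at 70 ppm — a 1.89×
gain in ¹³C digital resolution at the same number of increments, with every
crosspeak still inside the window (nothing folds). `nmrbot errors --series
out/series` prints an empty summary for this clean run; inject a fault and
it names the failing experiment with its timestamp and scope.

The same series can be set up interactively with `nmrbot wizard`, which
writes an equivalent manifest after the review screen.

## Layout

| module | role |
| --- | --- |
| `nmrbot.manifest` | STAR manifest parse/validate/emit, `RunConfig` types |
| `nmrbot.wizard` | interactive setup over an abstract prompt channel |
| `nmrbot.profile` | instrument profiles and the parameter-set library |
| `nmrbot.simulate` | simulated spectrometer backend and synthetic samples |
| `nmrbot.peaks` | noise estimation, peak picking, offset and SW adaptation |
| `nmrbot.engine` | series orchestration, modification ledger, outcomes |
| `nmrbot.audit` | three-scope append-only audit trails and error summaries |
| `nmrbot.synthesis` | random config and ground-truth sample generators |
| `nmrbot.cli` | `nmrbot lint / wizard / run / peaks / adapt-sw / errors` |

See `docs/methods.md` for the simulator's physical model, the default
parameter choices and the known limitations.
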
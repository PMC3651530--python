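"""Simulated spectrometer backend.

Implements the instrument contract the acquisition engine drives — insert,
eject, lock, tune/match, shim, acquire, receiver-gain optimization — over
ground-truth synthetic samples, so every stage of the automation is testable
without hardware.

The physical model is deliberately minimal but honest about the quantities
the automation manipulates:

* spectra are sums of frequency-domain Lorentzians (no FID/FT round trip);
* observed half-width = natural linewidth x shim broadening factor, so
  shimming visibly narrows lines;
* peak amplitude scales linearly with NS, receiver gain and concentration,
  while additive Gaussian noise scales with sqrt(NS) x gain, so S/N grows
  as sqrt(NS);
* 1D resonances outside the spectral window are simply not observed, while
  2D indirect-dimension resonances fold back by reflection off the window
  edges — the visible failure mode that adaptive spectral width manages;
* amplitudes beyond the ADC full scale clip and set a flag, giving
  receiver-gain optimization something real to optimize.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    GainClippedAtMinimumError,
    InstrumentContractError,
    LockError,
)
from .profile import ExperimentParams, InstrumentProfile, default_profile

__all__ = [
    "Resonance",
    "Correlation",
    "SyntheticSample",
    "InstrumentState",
    "Spectrum1D",
    "Spectrum2D",
    "SimulatedSpectrometer",
    "FaultInjectingBackend",
    "synthesize_spectrum",
    "acquire_2d",
    "fold_into_window",
    "read_sample",
    "write_sample",
    "write_spectrum",
    "read_spectrum",
]


@dataclass(frozen=True)
class Resonance:
    shift: float  # ppm
    intensity: float  # relative, > 0
    linewidth: float  # natural full width at half height, Hz, > 0

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("resonance intensity must be positive")
        if self.linewidth <= 0:
            raise ValueError("resonance linewidth must be positive")


@dataclass(frozen=True)
class Correlation:
    """A 1H-13C pair giving one crosspeak in a 2D heteronuclear spectrum."""

    h_shift: float
    c_shift: float
    intensity: float = 1.0
    h_linewidth: float = 2.0
    c_linewidth: float = 4.0


@dataclass(frozen=True)
class SyntheticSample:
    """Ground truth for the simulator: what is actually in the tube."""

    name: str
    solvent: str
    resonances: dict[str, tuple[Resonance, ...]] = field(default_factory=dict)
    solvent_resonance: Resonance | None = None
    concentration_scale: float = 1.0
    correlations: tuple[Correlation, ...] = ()

    def __post_init__(self):
        if self.concentration_scale <= 0:
            raise ValueError("concentration_scale must be positive")

    def all_1h(self) -> tuple[Resonance, ...]:
        res = self.resonances.get("1H", ())
        if self.solvent_resonance is not None:
            res = res + (self.solvent_resonance,)
        return res


def validate_sample(sample: SyntheticSample, profile: InstrumentProfile) -> None:
    """Enforce sample-level invariants that need the solvent table."""
    info = profile.solvents.get(sample.solvent)
    if info is None:
        return  # unknown solvent surfaces later as a lock failure
    protonated = info.proton_shift is not None
    if protonated and sample.solvent_resonance is None:
        raise ValueError(
            f"sample {sample.name!r}: protonated solvent {sample.solvent!r} "
            "declared but no solvent resonance defined"
        )
    if not protonated and sample.solvent_resonance is not None:
        raise ValueError(
            f"sample {sample.name!r}: solvent resonance defined for "
            f"non-protonated solvent {sample.solvent!r}"
        )
    if sample.solvent_resonance is not None:
        solutes = sample.resonances.get("1H", ())
        if solutes:
            biggest = max(r.intensity for r in solutes)
            if sample.solvent_resonance.intensity < 10.0 * biggest:
                raise ValueError(
                    f"sample {sample.name!r}: solvent resonance must be at "
                    "least 10x the largest 1H solute resonance"
                )


@dataclass
class InstrumentState:
    """Mutable spectrometer condition manipulated by the preparation steps."""

    inserted_sample: SyntheticSample | None = None
    locked_solvent: str | None = None
    tuned: bool = False
    shim_quality: float = 4.0  # line-broadening factor, >= 1; 1 = perfect
    receiver_gain: float = 16.0

    def require_acquirable(self) -> None:
        if self.inserted_sample is None:
            raise InstrumentContractError("acquire requires an inserted sample")
        if self.locked_solvent is None:
            raise InstrumentContractError("acquire requires an established lock")


@dataclass(frozen=True)
class Spectrum1D:
    """Acquired frequency-domain data on a descending ppm axis."""

    axis: np.ndarray  # ppm, strictly descending, uniform step
    intensity: np.ndarray
    nucleus: str
    sw: float  # ppm
    offset: float  # ppm, window center
    noise_sigma: float
    clipped: bool = False

    @property
    def points(self) -> int:
        return len(self.axis)

    @property
    def step(self) -> float:
        """Digital resolution in ppm per point."""
        return self.sw / (self.points - 1)


@dataclass(frozen=True)
class Spectrum2D:
    """2D matrix, shape (indirect points, direct points)."""

    matrix: np.ndarray
    direct_axis: np.ndarray  # ppm, descending (typically 1H)
    indirect_axis: np.ndarray  # ppm, descending (typically 13C)
    direct_nucleus: str
    indirect_nucleus: str
    direct_sw: float
    indirect_sw: float
    direct_offset: float
    indirect_offset: float
    noise_sigma: float
    indirect_hz_per_point: float
    clipped: bool = False


def _ppm_axis(sw: float, offset: float, points: int) -> np.ndarray:
    """Descending ppm axis spanning [offset + SW/2, offset - SW/2]."""
    return np.linspace(offset + sw / 2.0, offset - sw / 2.0, points)


def _lorentzian(axis: np.ndarray, shift: float, fwhm_ppm: float) -> np.ndarray:
    hw = fwhm_ppm / 2.0
    return 1.0 / (1.0 + ((axis - shift) / hw) ** 2)


def _signal_scale(params: ExperimentParams, state: InstrumentState,
                  profile: InstrumentProfile, gain: float) -> float:
    sample = state.inserted_sample
    tune = 1.0 if state.tuned else profile.tune_penalty
    return params.ns * gain * sample.concentration_scale * tune


def _resolve_gain(params: ExperimentParams, state: InstrumentState) -> float:
    if params.receiver_gain == "auto":
        return state.receiver_gain
    return float(params.receiver_gain)


def synthesize_spectrum(
    sample: SyntheticSample,
    params: ExperimentParams,
    state: InstrumentState,
    seed: int,
    profile: InstrumentProfile | None = None,
) -> Spectrum1D:
    """Simulate a 1D acquisition.

    Deterministic for a fixed seed.  Resonances outside the spectral window
    are excluded (not folded).  The clipped flag is set when any raw
    amplitude exceeds the ADC full scale; the stored trace is clipped.
    """
    profile = profile or default_profile()
    state.require_acquirable()
    if params.dimensionality != 1:
        raise ValueError("synthesize_spectrum handles 1D parameter sets only")

    dim = params.dims[0]
    axis = _ppm_axis(dim.sw, dim.offset, dim.points)
    lo, hi = dim.offset - dim.sw / 2.0, dim.offset + dim.sw / 2.0
    base_mhz = profile.base_frequency[dim.nucleus]
    gain = _resolve_gain(params, state)
    amp = _signal_scale(params, state, profile, gain)

    if dim.nucleus == "1H":
        resonances = sample.all_1h()
    else:
        resonances = sample.resonances.get(dim.nucleus, ())

    signal = np.zeros(dim.points)
    for res in resonances:
        if not (lo <= res.shift <= hi):
            continue  # outside the window: not observed in 1D
        fwhm_ppm = res.linewidth * state.shim_quality / base_mhz
        signal += amp * res.intensity * _lorentzian(axis, res.shift, fwhm_ppm)

    sigma = profile.noise_base * np.sqrt(params.ns) * gain
    rng = np.random.default_rng(seed)
    trace = signal + rng.normal(0.0, sigma, dim.points)

    clipped = bool(np.any(np.abs(trace) > profile.full_scale))
    trace = np.clip(trace, -profile.full_scale, profile.full_scale)
    return Spectrum1D(
        axis=axis,
        intensity=trace,
        nucleus=dim.nucleus,
        sw=dim.sw,
        offset=dim.offset,
        noise_sigma=sigma,
        clipped=clipped,
    )


def fold_into_window(shift: float, lo: float, hi: float) -> float:
    """Aliased position of a resonance in a window it falls outside of.

    Out-of-window frequencies reflect off the window edges (fold), the
    characteristic indirect-dimension artifact when the spectral width is
    too narrow.
    """
    width = hi - lo
    t = (shift - lo) % (2.0 * width)
    return lo + (width - abs(t - width))


def acquire_2d(
    sample: SyntheticSample,
    params: ExperimentParams,
    state: InstrumentState,
    seed: int,
    profile: InstrumentProfile | None = None,
) -> Spectrum2D:
    """Simulate a 2D heteronuclear acquisition from the correlation pairs.

    Direct-dimension (dim 1) resonances outside the window are dropped;
    indirect-dimension (dim 2) resonances fold.  Indirect digital
    resolution is SW x base frequency / points (Hz per point).
    """
    profile = profile or default_profile()
    state.require_acquirable()
    if params.dimensionality != 2:
        raise ValueError("acquire_2d requires a 2D parameter set")

    d1, d2 = params.dims
    ax1 = _ppm_axis(d1.sw, d1.offset, d1.points)
    ax2 = _ppm_axis(d2.sw, d2.offset, d2.points)
    lo1, hi1 = d1.offset - d1.sw / 2.0, d1.offset + d1.sw / 2.0
    lo2, hi2 = d2.offset - d2.sw / 2.0, d2.offset + d2.sw / 2.0
    f1 = profile.base_frequency[d1.nucleus]
    f2 = profile.base_frequency[d2.nucleus]
    gain = _resolve_gain(params, state)
    amp = _signal_scale(params, state, profile, gain)

    matrix = np.zeros((d2.points, d1.points))
    for pair in sample.correlations:
        if not (lo1 <= pair.h_shift <= hi1):
            continue
        c_pos = pair.c_shift
        if not (lo2 <= c_pos <= hi2):
            c_pos = fold_into_window(c_pos, lo2, hi2)
        line1 = _lorentzian(ax1, pair.h_shift,
                            pair.h_linewidth * state.shim_quality / f1)
        line2 = _lorentzian(ax2, c_pos,
                            pair.c_linewidth * state.shim_quality / f2)
        matrix += amp * pair.intensity * np.outer(line2, line1)

    sigma = profile.noise_base * np.sqrt(params.ns) * gain
    rng = np.random.default_rng(seed)
    matrix = matrix + rng.normal(0.0, sigma, matrix.shape)
    clipped = bool(np.any(np.abs(matrix) > profile.full_scale))
    matrix = np.clip(matrix, -profile.full_scale, profile.full_scale)

    return Spectrum2D(
        matrix=matrix,
        direct_axis=ax1,
        indirect_axis=ax2,
        direct_nucleus=d1.nucleus,
        indirect_nucleus=d2.nucleus,
        direct_sw=d1.sw,
        indirect_sw=d2.sw,
        direct_offset=d1.offset,
        indirect_offset=d2.offset,
        noise_sigma=sigma,
        indirect_hz_per_point=d2.sw * f2 / d2.points,
        clipped=clipped,
    )


class SimulatedSpectrometer:
    """Stateful simulated instrument satisfying the engine's backend contract.

    Shim state persists across samples: inserting a new sample degrades the
    current shim quality by a disturbance factor (capped at the cold-start
    value) rather than resetting it, so a series pre-shimmed on a water
    standard starts every subsequent sample closer to optimal.
    """

    def __init__(self, profile: InstrumentProfile | None = None,
                 rack: dict[str, SyntheticSample] | None = None):
        self.profile = profile or default_profile()
        self.rack: dict[str, SyntheticSample] = {}
        self.state = InstrumentState(
            shim_quality=self.profile.cold_start_shim_quality,
            receiver_gain=self.profile.gain_ladder[len(self.profile.gain_ladder) // 2],
        )
        self._ever_shimmed = False
        if rack:
            self.load_rack(rack)

    # -- rack ------------------------------------------------------------
    def load_rack(self, mapping: dict[str, SyntheticSample]) -> None:
        for sample in mapping.values():
            validate_sample(sample, self.profile)
        self.rack.update(mapping)

    # -- contract queries -------------------------------------------------
    @property
    def shim_routine_names(self) -> tuple[str, ...]:
        return tuple(self.profile.shim_routines)

    @property
    def gain_ladder(self) -> tuple[float, ...]:
        return self.profile.gain_ladder

    # -- sample handling --------------------------------------------------
    def insert(self, rack_position: str) -> None:
        sample = self.rack.get(rack_position)
        if sample is None:
            raise InstrumentContractError(
                f"no sample in rack position {rack_position!r}"
            )
        self.state.inserted_sample = sample
        self.state.locked_solvent = None
        self.state.tuned = False
        cold = self.profile.cold_start_shim_quality
        if self._ever_shimmed:
            self.state.shim_quality = min(
                cold, self.state.shim_quality * self.profile.insertion_disturbance
            )
        else:
            self.state.shim_quality = cold

    def eject(self) -> None:
        self.state.inserted_sample = None
        self.state.locked_solvent = None
        self.state.tuned = False

    # -- preparation ------------------------------------------------------
    def lock(self, solvent: str) -> None:
        """Establish the deuterium lock on the stated solvent.

        Succeeds regardless of the previous sample's solvent; the lock
        table, not history, decides.
        """
        if self.state.inserted_sample is None:
            raise InstrumentContractError("lock requires an inserted sample")
        if solvent not in self.profile.solvents:
            raise LockError(f"no lock parameters for solvent {solvent!r}")
        self.state.locked_solvent = solvent

    def tune_match(self) -> None:
        if self.state.inserted_sample is None:
            raise InstrumentContractError("tune/match requires an inserted sample")
        self.state.tuned = True

    def shim(self, command: str) -> float:
        """Run one shim routine pass; returns the new broadening factor.

        quality' = max(floor, quality x factor): monotone non-increasing,
        never below the routine's floor, divergence impossible.
        """
        if self.state.inserted_sample is None:
            raise InstrumentContractError("shim requires an inserted sample")
        routine = self.profile.shim_routines.get(command)
        if routine is None:
            raise InstrumentContractError(
                f"unknown shim routine {command!r}; advertised: "
                + ", ".join(self.shim_routine_names)
            )
        self.state.shim_quality = max(
            routine.floor, self.state.shim_quality * routine.factor
        )
        self._ever_shimmed = True
        return self.state.shim_quality

    # -- acquisition ------------------------------------------------------
    def acquire(self, params: ExperimentParams, seed: int):
        if params.dimensionality == 1:
            return synthesize_spectrum(
                self.state.inserted_sample, params, self.state, seed, self.profile
            )
        return acquire_2d(
            self.state.inserted_sample, params, self.state, seed, self.profile
        )

    def optimize_gain(self, params: ExperimentParams) -> float:
        """Deterministic receiver-gain search over the discrete ladder.

        Runs a noiseless trial at unit gain, then selects the largest ladder
        gain whose scaled peak amplitude stays at or below 90% of ADC full
        scale.  Raises GainClippedAtMinimumError when even the minimum gain
        would clip (callers audit the warning and fall back to minimum gain).
        """
        self.state.require_acquirable()
        trial = replace(params, receiver_gain=1.0, ns=params.ns)
        unit_peak = self._noiseless_peak(trial)
        target = 0.9 * self.profile.full_scale
        best = None
        for gain in sorted(self.profile.gain_ladder):
            if unit_peak * gain <= target:
                best = gain
        if best is None:
            min_gain = min(self.profile.gain_ladder)
            if unit_peak * min_gain > self.profile.full_scale:
                raise GainClippedAtMinimumError(min_gain)
            best = min_gain
        return best

    def _noiseless_peak(self, params: ExperimentParams) -> float:
        """Maximum unclipped signal amplitude at the given parameters.

        Full scale is lifted for the trial so the true amplitude is seen
        even where a real acquisition would clip.
        """
        quiet = replace(self.profile, noise_base=0.0, full_scale=float("inf"))
        if params.dimensionality == 1:
            spec = synthesize_spectrum(
                self.state.inserted_sample, params, self.state, 0, quiet
            )
            return float(np.max(np.abs(spec.intensity)))
        spec2 = acquire_2d(
            self.state.inserted_sample, params, self.state, 0, quiet
        )
        return float(np.max(np.abs(spec2.matrix)))


class FaultInjectingBackend:
    """Backend wrapper that raises on the N-th call of one contract method.

    Used to exercise continue-on-error semantics: the engine must log the
    failure and carry on with the remaining experiments and samples.
    """

    METHODS = ("insert", "lock", "tune_match", "shim", "acquire", "optimize_gain")

    def __init__(self, backend, fail_method: str, fail_call: int):
        if fail_method not in self.METHODS:
            raise ValueError(f"cannot inject into {fail_method!r}")
        self._backend = backend
        self.fail_method = fail_method
        self.fail_call = fail_call
        self.calls = {m: 0 for m in self.METHODS}

    def __getattr__(self, name):
        attr = getattr(self._backend, name)
        if name not in self.METHODS:
            return attr

        def wrapped(*args, **kwargs):
            self.calls[name] += 1
            if name == self.fail_method and self.calls[name] == self.fail_call:
                raise InstrumentContractError(
                    f"injected fault: {name} call {self.fail_call}"
                )
            return attr(*args, **kwargs)

        return wrapped


# ---------------------------------------------------------------------------
# synthetic-sample file format
#
# Plain text, one sample per file:
#
#   name        my_sample
#   solvent     H2O+D2O
#   concentration_scale 1.0
#
#   [resonances 1H]        # shift_ppm  intensity  linewidth_hz
#   4.70   100.0  1.2
#
#   [solvent_resonance]    # shift_ppm  intensity  linewidth_hz
#   4.70   1000.0  2.0
#
#   [correlations]         # h_ppm c_ppm intensity h_lw_hz c_lw_hz
#   3.20   55.1   1.0  2.0  4.0


def read_sample(text: str) -> SyntheticSample:
    """Parse a synthetic-sample definition file."""
    name = ""
    solvent = ""
    conc = 1.0
    resonances: dict[str, list[Resonance]] = {}
    solvent_res: Resonance | None = None
    correlations: list[Correlation] = []
    section: tuple[str, ...] | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = tuple(line.strip("[]").split())
            continue
        parts = line.split()
        if section is None:
            key, value = parts[0], " ".join(parts[1:])
            if key == "name":
                name = value
            elif key == "solvent":
                solvent = value
            elif key == "concentration_scale":
                conc = float(value)
            else:
                raise ValueError(f"line {lineno}: unknown key {key!r}")
        elif section[0] == "resonances":
            nucleus = section[1]
            shift, inten, lw = (float(x) for x in parts[:3])
            resonances.setdefault(nucleus, []).append(Resonance(shift, inten, lw))
        elif section[0] == "solvent_resonance":
            shift, inten = float(parts[0]), float(parts[1])
            lw = float(parts[2]) if len(parts) > 2 else 2.0
            solvent_res = Resonance(shift, inten, lw)
        elif section[0] == "correlations":
            vals = [float(x) for x in parts]
            correlations.append(Correlation(*vals))
        else:
            raise ValueError(f"line {lineno}: unknown section {section}")

    return SyntheticSample(
        name=name,
        solvent=solvent,
        resonances={k: tuple(v) for k, v in resonances.items()},
        solvent_resonance=solvent_res,
        concentration_scale=conc,
        correlations=tuple(correlations),
    )


def write_sample(sample: SyntheticSample) -> str:
    lines = [
        f"name {sample.name}",
        f"solvent {sample.solvent}",
        f"concentration_scale {sample.concentration_scale!r}",
    ]
    for nucleus, res in sample.resonances.items():
        lines.append("")
        lines.append(f"[resonances {nucleus}]")
        lines.extend(f"{r.shift!r} {r.intensity!r} {r.linewidth!r}" for r in res)
    if sample.solvent_resonance is not None:
        r = sample.solvent_resonance
        lines += ["", "[solvent_resonance]",
                  f"{r.shift!r} {r.intensity!r} {r.linewidth!r}"]
    if sample.correlations:
        lines.append("")
        lines.append("[correlations]")
        lines.extend(
            f"{c.h_shift!r} {c.c_shift!r} {c.intensity!r} "
            f"{c.h_linewidth!r} {c.c_linewidth!r}"
            for c in sample.correlations
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# spectrum text export: two-column ppm/intensity (1D) or TSV matrix (2D)
# plus a JSON metadata sidecar


def write_spectrum(spectrum, base_path) -> None:
    """Write a spectrum as text next to a .json metadata sidecar.

    1D: ``<base>.txt`` with ``ppm<TAB>intensity`` rows.
    2D: ``<base>.tsv`` matrix (rows = indirect axis) and the axes in the
    sidecar.
    """
    import json
    from pathlib import Path

    base = Path(base_path)
    if isinstance(spectrum, Spectrum1D):
        data = "\n".join(
            f"{p:.6f}\t{y:.6f}" for p, y in zip(spectrum.axis, spectrum.intensity)
        )
        base.with_suffix(".txt").write_text(data + "\n")
        meta = {
            "kind": "1d",
            "nucleus": spectrum.nucleus,
            "sw_ppm": spectrum.sw,
            "offset_ppm": spectrum.offset,
            "points": spectrum.points,
            "noise_sigma": spectrum.noise_sigma,
            "clipped": spectrum.clipped,
        }
    else:
        rows = "\n".join(
            "\t".join(f"{v:.6f}" for v in row) for row in spectrum.matrix
        )
        base.with_suffix(".tsv").write_text(rows + "\n")
        meta = {
            "kind": "2d",
            "direct_nucleus": spectrum.direct_nucleus,
            "indirect_nucleus": spectrum.indirect_nucleus,
            "direct_sw_ppm": spectrum.direct_sw,
            "indirect_sw_ppm": spectrum.indirect_sw,
            "direct_offset_ppm": spectrum.direct_offset,
            "indirect_offset_ppm": spectrum.indirect_offset,
            "indirect_hz_per_point": spectrum.indirect_hz_per_point,
            "noise_sigma": spectrum.noise_sigma,
            "clipped": spectrum.clipped,
        }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_spectrum(base_path) -> Spectrum1D:
    """Read back a 1D spectrum written by :func:`write_spectrum`."""
    import json
    from pathlib import Path

    base = Path(base_path)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("kind") != "1d":
        raise ValueError("read_spectrum only handles 1D spectra")
    data = np.loadtxt(base.with_suffix(".txt"))
    return Spectrum1D(
        axis=data[:, 0],
        intensity=data[:, 1],
        nucleus=meta["nucleus"],
        sw=meta["sw_ppm"],
        offset=meta["offset_ppm"],
        noise_sigma=meta["noise_sigma"],
        clipped=meta["clipped"],
    )
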
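"""Instrument profiles and experiment parameter sets.

A profile bundles everything about one (simulated) spectrometer that the
acquisition engine must know without touching hardware internals: base
frequencies per nucleus, the receiver-gain ladder, the advertised shim
routines with their convergence behaviour, the sensitivity penalty for an
untuned probe, the solvent vocabulary with lock/residual-proton data, the
PROSOL pulse-calibration lookup, and the named parameter-set library.

Acquisition parameters follow the usual conventions: SW (spectral width)
and the offset (window center) are in ppm, points is the per-dimension
complex point count, NS the number of summed scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "DimensionParams",
    "ExperimentParams",
    "ShimRoutine",
    "SolventInfo",
    "InstrumentProfile",
    "default_profile",
    "default_parameter_sets",
    "load_profile",
]


@dataclass(frozen=True)
class DimensionParams:
    """One spectral dimension: nucleus, window, and digitization."""

    nucleus: str  # e.g. "1H", "13C"
    sw: float  # spectral width, ppm
    offset: float  # window center, ppm
    points: int  # complex points (power of two, >= 256)

    def __post_init__(self):
        if self.sw <= 0:
            raise ValueError(f"SW must be positive, got {self.sw}")
        if self.points < 256 or self.points & (self.points - 1):
            raise ValueError(f"points must be a power of two >= 256, got {self.points}")


@dataclass(frozen=True)
class ExperimentParams:
    """A named, self-contained acquisition parameter bundle.

    ``receiver_gain`` is a number or the string ``"auto"`` (resolved by the
    gain-optimization step at run time).
    """

    parameter_set_name: str
    dims: tuple[DimensionParams, ...]
    ns: int = 8
    receiver_gain: float | str = 16.0
    pulse_length: float = 10.0  # us
    pulse_power: float = 0.0  # dB

    def __post_init__(self):
        if self.ns < 1:
            raise ValueError(f"NS must be >= 1, got {self.ns}")
        if self.dimensionality not in (1, 2):
            raise ValueError("only 1D and 2D experiments are supported")

    @property
    def dimensionality(self) -> int:
        return len(self.dims)

    def with_dim(self, index: int, *, sw: float, offset: float) -> "ExperimentParams":
        """Copy with dimension ``index`` (1-based) given a new window."""
        dims = list(self.dims)
        dims[index - 1] = replace(dims[index - 1], sw=sw, offset=offset)
        return replace(self, dims=tuple(dims))


@dataclass(frozen=True)
class ShimRoutine:
    """Geometric shim convergence: each call moves the broadening factor
    toward ``floor`` by ``factor`` (quality' = max(floor, quality*factor))."""

    factor: float
    floor: float


@dataclass(frozen=True)
class SolventInfo:
    """Lock and residual-proton data for one solvent.

    ``proton_shift`` is the 1H shift (ppm) of the dominant solvent resonance
    for protonated solvents, None for fully deuterated ones.
    """

    lock_shift: float  # 2H lock resonance, ppm
    proton_shift: float | None = None


def default_parameter_sets() -> dict[str, ExperimentParams]:
    """The stock library: conventional 1D sets, an HSQC, and the quick
    low-NS 1H set used by the solvent-offset pre-scan."""
    return {
        "PROTON": ExperimentParams(
            "PROTON",
            dims=(DimensionParams("1H", sw=20.0, offset=6.0, points=4096),),
            ns=8,
            receiver_gain="auto",
            pulse_length=10.0,
            pulse_power=0.0,
        ),
        "PROTON_QUICK": ExperimentParams(
            "PROTON_QUICK",
            dims=(DimensionParams("1H", sw=20.0, offset=6.0, points=4096),),
            ns=1,
            receiver_gain=4.0,
            pulse_length=10.0,
            pulse_power=0.0,
        ),
        "C13CPD": ExperimentParams(
            "C13CPD",
            dims=(DimensionParams("13C", sw=240.0, offset=110.0, points=8192),),
            ns=16,
            receiver_gain="auto",
            pulse_length=9.0,
            pulse_power=-2.0,
        ),
        # general HSQC: 200 ppm indirect 13C window
        "HSQC": ExperimentParams(
            "HSQC",
            dims=(
                DimensionParams("1H", sw=13.0, offset=5.0, points=1024),
                DimensionParams("13C", sw=200.0, offset=100.0, points=256),
            ),
            ns=4,
            receiver_gain="auto",
            pulse_length=10.0,
            pulse_power=0.0,
        ),
    }


@dataclass(frozen=True)
class InstrumentProfile:
    name: str = "default"
    base_frequency: dict[str, float] = field(
        default_factory=lambda: {"1H": 500.13, "13C": 125.76}
    )
    gain_ladder: tuple[float, ...] = tuple(float(2**k) for k in range(13))
    shim_routines: dict[str, ShimRoutine] = field(
        default_factory=lambda: {
            "1d-quick": ShimRoutine(factor=0.5, floor=1.3),
            "3d": ShimRoutine(factor=0.35, floor=1.05),
        }
    )
    tune_penalty: float = 0.8  # sensitivity factor when the probe is untuned
    full_scale: float = float(2**15)  # ADC full scale, arbitrary units
    cold_start_shim_quality: float = 4.0
    #: shim degradation factor applied to the retained shim state when a new
    #: sample is inserted (capped at cold start)
    insertion_disturbance: float = 1.5
    noise_base: float = 0.5  # per-scan, per-unit-gain noise sigma
    solvents: dict[str, SolventInfo] = field(
        default_factory=lambda: {
            "D2O": SolventInfo(lock_shift=4.70),
            "H2O+D2O": SolventInfo(lock_shift=4.70, proton_shift=4.70),
            "CDCl3": SolventInfo(lock_shift=7.26),
            "DMSO-d6": SolventInfo(lock_shift=2.50),
            "CD3OD": SolventInfo(lock_shift=3.31),
            "acetone-d6": SolventInfo(lock_shift=2.05),
        }
    )
    prosol: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"1H": (9.8, -1.0), "13C": (8.7, -3.5)}
    )
    prescan_parameter_set: str = "PROTON_QUICK"
    parameter_sets: dict[str, ExperimentParams] = field(
        default_factory=default_parameter_sets
    )


def default_profile() -> InstrumentProfile:
    return InstrumentProfile()


def load_profile(path: str | Path) -> InstrumentProfile:
    """Load a profile from a JSON file; absent keys keep defaults.

    Recognised keys mirror the InstrumentProfile fields; ``solvents`` maps
    name -> {lock_shift, proton_shift}; ``shim_routines`` maps
    name -> {factor, floor}; ``parameter_sets`` maps name -> {dims: [...],
    ns, receiver_gain, pulse_length, pulse_power}.
    """
    raw = json.loads(Path(path).read_text())
    base = default_profile()
    kwargs: dict = {"name": raw.get("name", Path(path).stem)}
    for scalar in (
        "tune_penalty",
        "full_scale",
        "cold_start_shim_quality",
        "insertion_disturbance",
        "noise_base",
        "prescan_parameter_set",
    ):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    if "base_frequency" in raw:
        kwargs["base_frequency"] = {**base.base_frequency, **raw["base_frequency"]}
    if "gain_ladder" in raw:
        kwargs["gain_ladder"] = tuple(float(g) for g in raw["gain_ladder"])
    if "shim_routines" in raw:
        kwargs["shim_routines"] = {
            name: ShimRoutine(**spec) for name, spec in raw["shim_routines"].items()
        }
    if "solvents" in raw:
        merged = dict(base.solvents)
        merged.update(
            {name: SolventInfo(**spec) for name, spec in raw["solvents"].items()}
        )
        kwargs["solvents"] = merged
    if "prosol" in raw:
        kwargs["prosol"] = {k: tuple(v) for k, v in raw["prosol"].items()}
    if "parameter_sets" in raw:
        sets = dict(base.parameter_sets)
        for name, spec in raw["parameter_sets"].items():
            dims = tuple(DimensionParams(**d) for d in spec.pop("dims"))
            sets[name] = ExperimentParams(name, dims=dims, **spec)
        kwargs["parameter_sets"] = sets
    return InstrumentProfile(**kwargs)
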
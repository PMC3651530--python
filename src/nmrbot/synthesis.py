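"""Generators for synthetic study material: randomized run configurations
(for fuzzing the manifest round trip) and ground-truth sample/rack builders
for the simulated spectrometer.

The demo samples emulate what the automation is for: aqueous metabolite
mixtures with a dominant water line (solvent-offset detection), dilute
samples (scan multiplication), and 1H/13C-correlated small molecules whose
13C shifts span only part of a general HSQC window (adaptive spectral
width).
"""

from __future__ import annotations

import numpy as np

from .manifest import AdaptationRule, RunConfig, SampleSpec, SeriesOptions
from .profile import InstrumentProfile, default_profile
from .simulate import Correlation, Resonance, SyntheticSample

__all__ = [
    "random_run_config",
    "random_peak_positions",
    "water_standard_sample",
    "aqueous_metabolite_sample",
    "organic_sample",
    "hsqc_demo_sample",
    "demo_rack",
]

_NAME_CHARS = list("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_- '")
_RACK_SLOTS = [f"{letter}{number}" for letter in "ABCDE" for number in range(1, 97)]
_FOLDER_TEMPLATES = (
    "{name}_{index}",
    "{date}-{name}",
    "{rack}_{solvent}_{index}",
    "{index}",
)


def _random_text(rng: np.random.Generator, min_len=1, max_len=12) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(_NAME_CHARS) for _ in range(n))


def random_run_config(
    rng: np.random.Generator, profile: InstrumentProfile | None = None
) -> RunConfig:
    """A random valid RunConfig exercising the whole manifest surface:
    quoted names and notes, water standards, NS multipliers, every option
    flag, and (sometimes) an adaptive-SW rule."""
    profile = profile or default_profile()
    solvent_names = sorted(profile.solvents)
    shim_names = sorted(profile.shim_routines)

    n = int(rng.integers(1, 6))
    use_ws = bool(rng.integers(0, 2))
    names: set[str] = set()
    while len(names) < n:
        names.add(_random_text(rng))
    name_list = sorted(names)
    racks = rng.choice(len(_RACK_SLOTS), size=n, replace=False)

    # experiment names unique across the config so adaptation-rule ordering
    # constraints cannot conflict between samples
    exp_counter = 0
    samples: list[SampleSpec] = []
    rule: AdaptationRule | None = None
    for i in range(n):
        is_ws = use_ws and i == 0
        if is_ws:
            exps: tuple[str, ...] = ()
        else:
            k = int(rng.integers(1, 5))
            exps = tuple(f"EXP{exp_counter + j}" for j in range(k))
            exp_counter += k
        notes = _random_text(rng, 0, 20) if rng.integers(0, 2) else None
        samples.append(
            SampleSpec(
                name=name_list[i],
                solvent="H2O+D2O" if is_ws else str(rng.choice(solvent_names)),
                rack_position=_RACK_SLOTS[racks[i]],
                experiment_sets=exps,
                ns_multiplier=int(rng.integers(1, 17)),
                condition_notes=notes,
                is_water_standard=is_ws,
            )
        )
        if rule is None and len(exps) >= 2 and rng.integers(0, 2):
            targets = tuple(
                e for e in exps[1:] if rng.integers(0, 2)
            ) or (exps[-1],)
            rule = AdaptationRule(
                source_experiment=exps[0],
                source_nucleus=str(rng.choice(["1H", "13C"])),
                target_experiments=targets,
                target_dimension=1,
            )

    options = SeriesOptions(
        use_water_standard=use_ws,
        folder_name_format=str(rng.choice(_FOLDER_TEMPLATES)),
        use_prosol=bool(rng.integers(0, 2)),
        find_solvent_offset=bool(rng.integers(0, 2)),
        tune_match_each_sample=bool(rng.integers(0, 2)),
        shim_command=str(rng.choice(shim_names)),
        use_gain_optimization=bool(rng.integers(0, 2)),
        sw_adaptation=(rule,) if rule is not None else (),
    )
    return RunConfig(samples=tuple(samples), options=options)


def random_peak_positions(
    rng: np.random.Generator, max_peaks: int = 40, lo: float = -20.0, hi: float = 220.0
) -> np.ndarray:
    """Random chemical-shift lists for exercising window adaptation."""
    n = int(rng.integers(1, max_peaks + 1))
    return rng.uniform(lo, hi, size=n)


# ---------------------------------------------------------------------------
# ground-truth samples


def water_standard_sample() -> SyntheticSample:
    """90% H2O / 10% D2O: nothing but a huge water line, used to establish
    three-dimensional shims at the start of a series."""
    return SyntheticSample(
        name="water_standard",
        solvent="H2O+D2O",
        solvent_resonance=Resonance(shift=4.70, intensity=1000.0, linewidth=2.0),
    )


def aqueous_metabolite_sample(
    name: str = "metabolite_mix",
    solvent_shift: float = 4.72,
    concentration_scale: float = 1.0,
    n_solutes: int = 6,
    rng: np.random.Generator | None = None,
) -> SyntheticSample:
    """Aqueous mixture: dominant water resonance (>= 10x solutes) plus a
    handful of solute lines between 0.8 and 8.5 ppm."""
    rng = rng or np.random.default_rng(0)
    solutes = tuple(
        Resonance(
            shift=float(rng.uniform(0.8, 8.5)),
            intensity=float(rng.uniform(1.0, 8.0)),
            linewidth=float(rng.uniform(0.8, 2.5)),
        )
        for _ in range(n_solutes)
    )
    return SyntheticSample(
        name=name,
        solvent="H2O+D2O",
        resonances={"1H": solutes},
        solvent_resonance=Resonance(
            shift=solvent_shift,
            intensity=10.0 * max(r.intensity for r in solutes) * 2.0,
            linewidth=3.0,
        ),
        concentration_scale=concentration_scale,
    )


def organic_sample(
    name: str = "organic", solvent: str = "CDCl3",
    concentration_scale: float = 1.0,
) -> SyntheticSample:
    """Small molecule in a deuterated organic solvent (no solvent line)."""
    return SyntheticSample(
        name=name,
        solvent=solvent,
        resonances={
            "1H": (
                Resonance(1.25, 6.0, 1.0),
                Resonance(3.60, 2.0, 1.2),
                Resonance(7.30, 3.0, 1.5),
            ),
            "13C": (
                Resonance(14.1, 3.0, 2.0),
                Resonance(62.3, 2.0, 2.5),
                Resonance(128.4, 4.0, 3.0),
            ),
        },
        concentration_scale=concentration_scale,
    )


def hsqc_demo_sample(
    name: str = "hsqc_demo",
    c_shifts: tuple[float, ...] = (22.0, 35.5, 55.0, 72.4, 98.0, 118.0),
    h_shifts: tuple[float, ...] = (0.9, 1.6, 3.1, 3.9, 5.3, 6.8),
) -> SyntheticSample:
    """1H/13C-correlated sample whose 13C shifts span roughly half of a
    general 200 ppm indirect window — the textbook case where adapting the
    spectral width to the observed 13C range buys digital resolution."""
    c13 = tuple(Resonance(c, 5.0, 2.5) for c in c_shifts)
    h1 = tuple(Resonance(h, 4.0, 1.2) for h in h_shifts)
    pairs = tuple(
        Correlation(h, c, intensity=2.0) for h, c in zip(h_shifts, c_shifts)
    )
    return SyntheticSample(
        name=name,
        solvent="D2O",
        resonances={"1H": h1, "13C": c13},
        correlations=pairs,
    )


def demo_rack() -> dict[str, SyntheticSample]:
    """A small heterogeneous rack covering the optional features."""
    return {
        "A1": water_standard_sample(),
        "A2": aqueous_metabolite_sample("mix_a", solvent_shift=4.72),
        "A3": aqueous_metabolite_sample(
            "dilute_mix", solvent_shift=4.68, concentration_scale=0.05,
            rng=np.random.default_rng(7),
        ),
        "A4": organic_sample("organic_a"),
        "A5": hsqc_demo_sample(),
    }
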
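"""Shared fixtures: instrument profile, synthetic samples, backends."""

from dataclasses import replace

import numpy as np
import pytest

from nmrbot import (
    DimensionParams,
    ExperimentParams,
    Resonance,
    RunConfig,
    SampleSpec,
    SimulatedSpectrometer,
    SyntheticSample,
    default_profile,
)


@pytest.fixture
def profile():
    return default_profile()


@pytest.fixture
def quiet_profile(profile):
    """Profile with the noise turned off, for closed-form checks."""
    return replace(profile, noise_base=0.0)


@pytest.fixture
def single_line_sample():
    """One 1 Hz resonance at 4.70 ppm in D2O."""
    return SyntheticSample(
        name="single",
        solvent="D2O",
        resonances={"1H": (Resonance(shift=4.70, intensity=10.0, linewidth=1.0),)},
    )


@pytest.fixture
def narrow_1h_params():
    """Fine digital resolution (~0.24 Hz/point at 500 MHz) around water."""
    return ExperimentParams(
        "NARROW1H",
        dims=(DimensionParams("1H", sw=2.0, offset=4.7, points=4096),),
        ns=1,
        receiver_gain=1.0,
    )


def make_ready_backend(profile, sample, rack_position="A1", shim_quality=1.0):
    """Backend with the sample inserted, locked, tuned, and shims set."""
    backend = SimulatedSpectrometer(profile, {rack_position: sample})
    backend.insert(rack_position)
    backend.lock(sample.solvent)
    backend.tune_match()
    backend.state.shim_quality = shim_quality
    return backend


@pytest.fixture
def ready_backend(quiet_profile, single_line_sample):
    return make_ready_backend(quiet_profile, single_line_sample)


@pytest.fixture
def minimal_config():
    return RunConfig(
        samples=(SampleSpec("s1", "D2O", "A1", ("PROTON",)),)
    )


def measure_fwhm_hz(spectrum, base_mhz=500.13):
    """Half-height crossing width of the tallest feature, in Hz."""
    y = spectrum.intensity
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = i
    while left > 0 and y[left] > half:
        left -= 1
    right = i
    while right < len(y) - 1 and y[right] > half:
        right += 1
    # linear interpolation of the exact half crossings
    def cross(a, b):
        if y[b] == y[a]:
            return float(b)
        return a + (half - y[a]) / (y[b] - y[a]) * (b - a)

    x_left = cross(left, left + 1) if left < i else float(i)
    x_right = cross(right, right - 1) if right > i else float(i)
    width_points = abs(x_right - x_left)
    return width_points * spectrum.step * base_mhz
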
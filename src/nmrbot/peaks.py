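"""Peak picking and the two on-the-fly parameter computations.

Given an acquired 1D spectrum this module finds peaks above a
signal-to-noise threshold and derives from them either (a) the transmitter
offset that centers the carrier on the dominant solvent resonance, or (b)
an adapted spectral width spanning the observed peak range with the offset
at its center — the mechanism that lets a later experiment (typically the
indirect 13C dimension of an HSQC) trade unused spectral width for digital
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import argrelextrema

from .errors import NoSolventPeakError
from .manifest import AdaptationRule
from .profile import ExperimentParams
from .simulate import Spectrum1D

__all__ = [
    "Peak",
    "PeakList",
    "estimate_noise",
    "pick_peaks",
    "find_solvent_offset",
    "adapt_sw",
    "apply_adaptation",
    "DEFAULT_SNR_THRESHOLD",
    "DEFAULT_SW_FLOOR",
    "default_margin",
]

#: default signal-to-noise threshold for peak detection
DEFAULT_SNR_THRESHOLD = 6.0
#: adapted spectral widths never shrink below this (ppm)
DEFAULT_SW_FLOOR = 2.0


@dataclass(frozen=True)
class Peak:
    position: float  # ppm
    height: float
    interpolated: bool = False  # position refined by local quadratic fit


@dataclass(frozen=True)
class PeakList:
    """Picked peaks ordered by descending ppm, with spectrum provenance."""

    peaks: tuple[Peak, ...]
    nucleus: str
    sw: float
    offset: float
    noise_sigma: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])


def estimate_noise(spectrum: Spectrum1D) -> float:
    """Robust noise sigma from point-to-point first differences.

    Differencing removes slowly varying signal, so the estimate is driven by
    the noise floor even when peaks are present; the median absolute
    deviation makes the sparse steep peak flanks irrelevant.  For white
    noise the first difference has variance 2*sigma^2, hence the sqrt(2).
    """
    if spectrum.points < 64:
        raise ValueError("noise estimation needs at least 64 points")
    diffs = np.diff(spectrum.intensity)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _refine_position(axis: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float, bool]:
    """Sub-grid peak position via a three-point quadratic through i-1,i,i+1."""
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(axis[i]), float(y1), False
    delta = 0.5 * (y0 - y2) / denom
    if abs(delta) > 1.0:
        return float(axis[i]), float(y1), False
    step = axis[i + 1] - axis[i]  # negative on a descending axis
    pos = float(axis[i] + delta * step)
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return pos, height, True


def pick_peaks(
    spectrum: Spectrum1D, snr_threshold: float = DEFAULT_SNR_THRESHOLD
) -> PeakList:
    """Every interior local maximum with height above threshold x noise.

    Positions are refined by three-point quadratic interpolation; spectrum
    edge points are never reported.  An empty list is a valid result.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    sigma = estimate_noise(spectrum)
    y = spectrum.intensity
    (idx,) = argrelextrema(y, np.greater, order=1)
    floor = snr_threshold * sigma
    peaks = []
    for i in idx:
        if y[i] <= floor:
            continue
        pos, height, refined = _refine_position(spectrum.axis, y, int(i))
        peaks.append(Peak(position=pos, height=height, interpolated=refined))
    peaks.sort(key=lambda p: -p.position)
    return PeakList(
        peaks=tuple(peaks),
        nucleus=spectrum.nucleus,
        sw=spectrum.sw,
        offset=spectrum.offset,
        noise_sigma=sigma,
    )


def find_solvent_offset(peaks: PeakList) -> float:
    """Position of the tallest picked peak, taken to be the solvent line.

    Used to center the transmitter on a dominant solvent resonance (e.g.
    water) so one general parameter set serves samples with different
    solvent positions.  Ties on height break toward higher ppm (downfield).
    """
    if not peaks.peaks:
        raise NoSolventPeakError("no peaks to identify a solvent line from")
    best = max(peaks, key=lambda p: (p.height, p.position))
    return best.position


def default_margin(span: float) -> float:
    """Margin added on each side of the observed range: 5% of it, >= 1 ppm."""
    return max(1.0, 0.05 * span)


def adapt_sw(
    peaks: PeakList,
    margin: float | None = None,
    sw_floor: float = DEFAULT_SW_FLOOR,
) -> tuple[float, float]:
    """Spectral width spanning all picked peaks, offset at the range center.

    SW = (max - min) + 2*margin, floored at ``sw_floor``; offset =
    (max + min)/2.  With margin >= 0, every input peak lies inside the
    returned window.  ``margin=None`` uses :func:`default_margin`.
    """
    if not peaks.peaks:
        raise NoSolventPeakError("cannot adapt spectral width from an empty peak list")
    positions = peaks.positions
    lo, hi = float(positions.min()), float(positions.max())
    if margin is None:
        margin = default_margin(hi - lo)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    sw = max((hi - lo) + 2.0 * margin, sw_floor)
    offset = (hi + lo) / 2.0
    return sw, offset


def apply_adaptation(
    rule: AdaptationRule,
    result: tuple[float, float],
    experiment_queue: list[ExperimentParams],
) -> tuple[list[ExperimentParams], list[str]]:
    """Substitute the adapted (SW, offset) into the rule's target experiments.

    Returns the updated queue (same order; non-targets untouched) and the
    names of targets that were actually present.  A target missing from the
    queue is skipped — callers audit a warning and the rest still update.
    """
    sw, offset = result
    updated: list[ExperimentParams] = []
    touched: list[str] = []
    for params in experiment_queue:
        if (
            params.parameter_set_name in rule.target_experiments
            and rule.target_dimension <= params.dimensionality
        ):
            updated.append(
                params.with_dim(rule.target_dimension, sw=sw, offset=offset)
            )
            touched.append(params.parameter_set_name)
        else:
            updated.append(params)
    return updated, touched
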
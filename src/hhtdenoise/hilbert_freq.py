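"""Analytic signal, instantaneous frequency, and per-component summaries.

The discrete Hilbert transform pairs a real signal x(t) with its
quadrature component H(t) (principal-value convolution with 1/πt,
computed here by the standard frequency-domain method: zero the negative
frequencies, double the positive ones).  Together they form the analytic
signal Z(t) = x + iH = a·e^{iθ}, whose unwrapped phase derivative is the
instantaneous frequency.  Frequencies are expressed in cycles per
sample, which keeps them axis-unit-agnostic.

Edge samples of a finite record carry known transform artifacts, so the
first and last two samples of each frequency track are masked out of the
mean/SD summaries used downstream by the F-test cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _scipy_hilbert

from .emd import Decomposition

__all__ = [
    "AnalyticSignal",
    "InstFreqTrack",
    "FrequencySummary",
    "analytic_signal",
    "instantaneous_frequency",
    "freq_summary",
]

_EDGE_MARGIN = 2  # samples masked at each end of a frequency track
_MIN_COMPONENT_LEN = 8


@dataclass(frozen=True)
class AnalyticSignal:
    """Real signal, its Hilbert quadrature, amplitude and unwrapped phase."""

    real_part: np.ndarray
    imag_part: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray


@dataclass(frozen=True)
class InstFreqTrack:
    """Instantaneous frequency in cycles/sample with an edge-validity mask."""

    frequency: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class FrequencySummary:
    """Per-component mean and SD of instantaneous frequency.

    Index 0 corresponds to IMF_1 (highest frequency); the last entry is
    the residual.  SDs use the ``n_valid − 1`` denominator.
    """

    means: np.ndarray
    sds: np.ndarray
    component_order: str = "imf_order"

    @property
    def n_components(self) -> int:
        return int(self.means.size)


def analytic_signal(values: np.ndarray) -> AnalyticSignal:
    """Analytic signal of a real record via the FFT Hilbert transform.

    A constant record is a documented degenerate case: its quadrature is
    identically zero and the phase is defined as 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("analytic signal needs >= 8 samples")
    if np.ptp(v) == 0.0:
        zeros = np.zeros_like(v)
        return AnalyticSignal(v.copy(), zeros, np.abs(v), zeros.copy())
    z = _scipy_hilbert(v)
    phase = np.unwrap(np.angle(z))
    return AnalyticSignal(v.copy(), z.imag, np.abs(z), phase)


def instantaneous_frequency(analytic: AnalyticSignal) -> InstFreqTrack:
    """Phase derivative in cycles per sample.

    Central differences on the unwrapped phase in the interior,
    one-sided at the record ends; the first and last two samples are
    flagged invalid for statistics.
    """
    freq = np.gradient(analytic.phase) / (2.0 * np.pi)
    mask = np.ones(freq.size, dtype=bool)
    m = min(_EDGE_MARGIN, freq.size // 2)
    mask[:m] = False
    mask[freq.size - m:] = False
    return InstFreqTrack(freq, mask)


def _component_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean/SD of a component's instantaneous frequency.

    Components for which instantaneous frequency carries no meaning use
    the degenerate convention (mean 0, SD 0): records too short or too
    flat for a Hilbert transform, and sub-cycle components — trends and
    single humps whose unwrapped analytic phase advances by less than
    one full turn, for which a phase derivative is numerical noise
    rather than an oscillation rate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < _MIN_COMPONENT_LEN or np.ptp(v) == 0.0:
        return 0.0, 0.0
    analytic = analytic_signal(v)
    if abs(analytic.phase[-1] - analytic.phase[0]) < 2.0 * np.pi:
        return 0.0, 0.0
    track = instantaneous_frequency(analytic)
    f = track.frequency[track.valid_mask]
    if f.size < 2:
        return 0.0, 0.0
    return float(np.mean(f)), float(np.std(f, ddof=1))


def freq_summary(decomposition: Decomposition) -> FrequencySummary:
    """Mean and SD of instantaneous frequency for each IMF and the residual."""
    if not decomposition.imfs and decomposition.residual.size == 0:
        raise ValueError("empty decomposition")
    components = list(decomposition.imfs) + [decomposition.residual]
    stats = [_component_stats(c) for c in components]
    means = np.array([m for m, _ in stats])
    sds = np.array([s for _, s in stats])
    return FrequencySummary(means, sds)
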
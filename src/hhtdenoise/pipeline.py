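"""End-to-end denoising pipeline, Savitzky–Golay baseline and SNR metric.

``hht_denoise`` chains the stages: empirical mode decomposition →
instantaneous-frequency summaries → F-test cut-off → partial
reconstruction from the retained components.  The intermediate artifacts
(decomposition, frequency summary, cut-off decision) are kept on the
result for inspection.

``sg_smooth`` provides the classical comparator: local least-squares
polynomial smoothing over a symmetric window, exact on polynomials up
to the fit order.  ``snr_db`` is the reference-based power ratio
``10·log10(Σ ref² / Σ (est − ref)²)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .cutoff import CutoffDecision, FTestConfig, select_cutoff
from .emd import Decomposition, SiftConfig, emd
from .hilbert_freq import FrequencySummary, freq_summary
from .spectra_io import Spectrum

__all__ = [
    "SGConfig",
    "DenoiseResult",
    "reconstruct",
    "hht_denoise",
    "sg_coefficients",
    "sg_smooth",
    "snr_db",
]


@dataclass(frozen=True)
class SGConfig:
    """Savitzky–Golay window (odd, = 2·half_width + 1) and fit order."""

    window: int = 13
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not 0 <= self.poly_order < self.window:
            raise ValueError("poly_order must satisfy 0 <= order < window")

    @property
    def half_width(self) -> int:
        return self.window // 2


@dataclass
class DenoiseResult:
    """Denoised spectrum plus every intermediate pipeline artifact."""

    denoised: Spectrum
    removed_orders: list[int]
    decision: CutoffDecision
    decomposition: Decomposition
    summary: FrequencySummary


def reconstruct(decomposition: Decomposition, k: int,
                axis: np.ndarray | None = None,
                axis_label: str = "axis") -> Spectrum:
    """Sum IMF_{k+1}..IMF_n and the residual into a spectrum.

    ``k = 0`` reproduces the input (completeness); ``k = n_imfs`` keeps
    only the residual.
    """
    if not 0 <= k <= decomposition.n_imfs:
        raise ValueError(f"cut-off k={k} outside 0..{decomposition.n_imfs}")
    out = decomposition.residual.copy()
    for imf in decomposition.imfs[k:]:
        out += imf
    if axis is None:
        axis = np.arange(1, out.size + 1, dtype=float)
    return Spectrum(axis, out, axis_label)


def hht_denoise(spectrum: Spectrum,
                sift_config: SiftConfig = SiftConfig(),
                f_config: FTestConfig = FTestConfig()) -> DenoiseResult:
    """Full HHT + F-test denoising of a spectrum.

    Deterministic for a given input and configuration.  When the F-test
    finds no significant dispersion jump the cut-off is 0 and the output
    equals the input.
    """
    decomposition = emd(spectrum, sift_config)
    if decomposition.n_imfs == 0:
        decision = CutoffDecision(0, np.empty(0), float("nan"),
                                  np.empty(0, dtype=bool))
        summary = FrequencySummary(np.zeros(1), np.zeros(1))
        denoised = spectrum.with_intensity(spectrum.intensity.copy())
        return DenoiseResult(denoised, [], decision, decomposition, summary)
    summary = freq_summary(decomposition)
    decision = select_cutoff(summary, f_config)
    denoised = reconstruct(decomposition, decision.k, spectrum.axis,
                           spectrum.axis_label)
    return DenoiseResult(denoised, list(range(1, decision.k + 1)),
                         decision, decomposition, summary)


def sg_coefficients(config: SGConfig) -> np.ndarray:
    """Central-point Savitzky–Golay weights, normalised to sum to 1.

    Convolving these weights with a window reproduces the least-squares
    polynomial fit of degree ``poly_order`` evaluated at the window
    center.
    """
    return savgol_coeffs(config.window, config.poly_order)


def sg_smooth(spectrum: Spectrum, config: SGConfig = SGConfig()) -> Spectrum:
    """Savitzky–Golay smoothing of a spectrum.

    Record ends are handled by one-sided polynomial fits over the last
    full window, so the output keeps the input length.
    """
    if config.window > spectrum.n:
        raise ValueError(
            f"window {config.window} exceeds record length {spectrum.n}")
    smoothed = savgol_filter(spectrum.intensity, config.window,
                             config.poly_order, mode="interp")
    return spectrum.with_intensity(smoothed)


def snr_db(reference: Spectrum | np.ndarray, estimate: Spectrum | np.ndarray) -> float:
    """Signal-to-noise ratio in dB of an estimate against a clean reference.

    ``10·log10(Σ ref² / Σ (est − ref)²)``; a perfect estimate returns
    ``math.inf``.  A zero-energy reference is an error.
    """
    ref = reference.intensity if isinstance(reference, Spectrum) else np.asarray(reference, float)
    est = estimate.intensity if isinstance(estimate, Spectrum) else np.asarray(estimate, float)
    if ref.size != est.size:
        raise ValueError("reference and estimate lengths differ")
    p_ref = float(np.sum(ref * ref))
    if p_ref == 0.0:
        raise ValueError("reference has zero energy")
    p_err = float(np.sum((est - ref) ** 2))
    if p_err == 0.0:
        return math.inf
    return 10.0 * math.log10(p_ref / p_err)
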
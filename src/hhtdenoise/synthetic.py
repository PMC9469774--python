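"""Synthetic chemical-like spectra: a smooth multi-peak pure signal plus
seeded Gaussian noise.

The default pure form is a Gaussian bell modulated by ``|cos u − 1.2|``
evaluated on a scaled coordinate ``u = angular_scale · x`` over the
sample axis ``x = 1..n`` — a strictly positive envelope carrying a few
smooth peaks, emulating overlapping bands on a curved baseline.  The
published description of this test signal is typographically ambiguous
about the cosine's argument scaling and the bell placement; the defaults
here were fixed once by requiring the decomposition and denoising
behaviour of the generated family to match the published outcomes for
the 501-point artificial signal (see docs/methods.md), and are part of
the package's study conditions, not free dials.

Noise is ``noise_scale · (standard normal + noise_mean)``.  The default
``noise_mean = 1`` follows the published generator description
literally, which biases the noisy record by ``+noise_scale``; set
``noise_mean = 0`` for conventional zero-mean noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .spectra_io import Spectrum

__all__ = ["SynthParams", "generate_pure", "generate_noised"]

_DEFAULT_FORM_PARAMS: dict[str, dict[str, Any]] = {
    "modulated_gaussian": {
        # u = angular_scale * x; pure = amplitude * exp(-(u-u_c)^2/width) * |cos u - 1.2|
        "amplitude": 2.0,
        "angular_scale": 0.15,
        "width": 26.0,
        "center": None,  # None → bell centered mid-record
    },
    "gaussian_mixture": {
        # centers/widths in sample units, one Gaussian band per entry
        "amplitudes": (1.0, 2.0, 1.5),
        "centers": (0.25, 0.5, 0.75),  # fractions of the record
        "widths": (0.02, 0.04, 0.03),  # SDs as fractions of the record
        "baseline": 0.1,
    },
}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic noised-spectrum generator.

    ``pure_form`` selects the clean-signal family (``"modulated_gaussian"``
    — the default 501-point artificial chemical signal — or
    ``"gaussian_mixture"`` for richer band spectra); ``form_params``
    overrides individual constants of that form.
    """

    n: int = 501
    noise_scale: float = 0.05
    noise_mean: float = 1.0
    seed: int = 0
    pure_form: str = "modulated_gaussian"
    form_params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.pure_form not in _DEFAULT_FORM_PARAMS:
            raise ValueError(
                f"unknown pure_form {self.pure_form!r}; "
                f"choose from {sorted(_DEFAULT_FORM_PARAMS)}")
        unknown = set(self.form_params) - set(_DEFAULT_FORM_PARAMS[self.pure_form])
        if unknown:
            raise ValueError(f"unknown form_params for {self.pure_form}: {sorted(unknown)}")

    def resolved_form_params(self) -> dict[str, Any]:
        merged = dict(_DEFAULT_FORM_PARAMS[self.pure_form])
        merged.update(self.form_params)
        return merged


def generate_pure(params: SynthParams) -> Spectrum:
    """Clean synthetic spectrum on the integer axis 1..n."""
    axis = np.arange(1, params.n + 1, dtype=float)
    p = params.resolved_form_params()
    if params.pure_form == "modulated_gaussian":
        u = p["angular_scale"] * axis
        center = p["center"]
        u_c = p["angular_scale"] * 0.5 * (params.n + 1) if center is None else center
        bell = np.exp(-((u - u_c) ** 2) / p["width"])
        intensity = p["amplitude"] * bell * np.abs(np.cos(u) - 1.2)
    else:  # gaussian_mixture
        intensity = np.full(params.n, float(p["baseline"]))
        for a, c, w in zip(p["amplitudes"], p["centers"], p["widths"]):
            mu = c * params.n
            sd = w * params.n
            intensity = intensity + a * np.exp(-0.5 * ((axis - mu) / sd) ** 2)
    return Spectrum(axis, intensity, "index")


def generate_noised(params: SynthParams) -> tuple[Spectrum, Spectrum, np.ndarray]:
    """Noisy spectrum, its pure counterpart, and the exact noise vector.

    ``noisy = pure + noise`` holds bitwise, so reference-based SNR can
    be computed without re-deriving the noise.
    """
    pure = generate_pure(params)
    rng = np.random.default_rng(params.seed)
    noise = params.noise_scale * (rng.standard_normal(params.n) + params.noise_mean)
    noisy = pure.with_intensity(pure.intensity + noise)
    # return the realised difference so noisy - pure == noise holds bitwise
    return noisy, pure, noisy.intensity - pure.intensity
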
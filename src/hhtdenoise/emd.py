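"""Empirical mode decomposition by envelope sifting.

EMD adaptively splits a signal into intrinsic mode functions (IMFs) —
components whose extrema and zero-crossing counts differ by at most one
and whose upper/lower envelope mean is near zero — plus a slowly varying
residual.  The sifting loop repeatedly subtracts the mean of the natural
cubic-spline envelopes through the local maxima and minima until the
candidate qualifies as an IMF or a Cauchy-type convergence criterion
fires.  IMF_1 carries the highest-frequency content; successive IMFs
oscillate more slowly; decomposition stops when the residual is monotone
(at most one interior extremum) or too featureless to envelope.

Conventions chosen here (the classical formulation leaves them open):
mirror extension of the two nearest extrema about each endpoint before
splining, natural boundary conditions, Huang's pointwise Cauchy
criterion with threshold 0.2 as the sift stopping rule, and a
5 %-of-range tolerance on the envelope-mean test of :func:`is_imf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .spectra_io import Spectrum

__all__ = [
    "SiftConfig",
    "Decomposition",
    "find_extrema",
    "spline_envelopes",
    "count_zero_crossings",
    "is_imf",
    "sift_one_imf",
    "emd",
]


@dataclass(frozen=True)
class SiftConfig:
    """Parameters of the sifting loop.

    sd_threshold
        Bound on Huang's pointwise Cauchy criterion: sifting stops when
        ``sum((h_prev - h)**2 / h_prev**2)`` falls below it (a small
        fraction of the squared peak regularises near-zero samples).
    max_sift_iterations
        Hard cap on sift iterations per IMF.
    max_imfs
        Safety cap on the number of extracted IMFs.
    boundary_policy
        ``"mirror"`` reflects the two nearest extrema about each endpoint
        before splining; ``"clamp"`` pins both envelopes to the endpoint
        samples instead.
    imf_tolerance
        Envelope-mean test: the candidate passes when the largest
        absolute mean-envelope value is below this fraction of its range.
    """

    sd_threshold: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 12
    boundary_policy: str = "mirror"
    spline_kind: str = "natural_cubic"
    imf_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.max_sift_iterations < 1 or self.max_imfs < 1:
            raise ValueError("iteration/IMF caps must be >= 1")
        if self.boundary_policy not in ("mirror", "clamp"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")
        if self.spline_kind != "natural_cubic":
            raise ValueError("only natural cubic envelopes are supported")


@dataclass
class Decomposition:
    """Ordered IMFs plus residual, with per-IMF sift metadata.

    ``accepted_by[i]`` records how IMF ``i`` left the sifting loop:
    ``"cauchy"``, ``"max_iterations"`` or ``"lost_extrema"``; IMFs
    accepted only through the iteration cap are thereby flagged.  ``stop_reason`` is one of ``"monotone_residual"``,
    ``"too_few_extrema"`` or ``"max_imfs"``.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_iterations: list[int] = field(default_factory=list)
    accepted_by: list[str] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct_full(self) -> np.ndarray:
        """Sum of all IMFs and the residual (should equal the input)."""
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A flat plateau bounded by a rise on one side and a fall on the other
    is reported once, at the plateau midpoint.  Endpoints are never
    reported.  Returns ``(maxima, minima)`` as int arrays.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    dv = np.diff(v)
    nz = np.nonzero(dv)[0]
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    signs = np.sign(dv[nz])
    change = np.nonzero(signs[:-1] != signs[1:])[0]
    # the constant run between steps nz[i] and nz[i+1] spans
    # samples nz[i]+1 .. nz[i+1]; its midpoint represents the extremum
    mid = (nz[change] + 1 + nz[change + 1]) // 2
    is_max = signs[change] > 0
    return mid[is_max].astype(int), mid[~is_max].astype(int)


def count_zero_crossings(values: np.ndarray) -> int:
    """Sign changes between consecutive samples.

    Exact zeros adopt the sign of the next nonzero sample (trailing
    zeros the previous one), so each crossing counts exactly once.
    """
    s = np.sign(np.asarray(values, dtype=float))
    nz = s != 0
    if not nz.any():
        return 0
    idx = np.nonzero(nz)[0]
    # backward-fill from the next nonzero; leading segment forward-filled after
    filled = s[idx[np.searchsorted(idx, np.arange(s.size), side="left").clip(max=idx.size - 1)]]
    filled[idx[-1]:] = s[idx[-1]]
    return int(np.count_nonzero(filled[:-1] != filled[1:]))


def _extend_knots(idx: np.ndarray, vals: np.ndarray, n: int,
                  policy: str, endpoints: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Add boundary knots so the spline is anchored beyond both ends."""
    x = idx.astype(float)
    y = vals.copy()
    if policy == "mirror":
        k = min(2, x.size)
        left_x, left_y = -x[:k][::-1], y[:k][::-1]
        right_x, right_y = 2.0 * (n - 1) - x[-k:][::-1], y[-k:][::-1]
        x = np.concatenate([left_x, x, right_x])
        y = np.concatenate([left_y, y, right_y])
    else:  # clamp: pin envelopes to the record's endpoint samples
        x = np.concatenate([[0.0], x, [float(n - 1)]])
        y = np.concatenate([[endpoints[0]], y, [endpoints[1]]])
    keep = np.concatenate([[True], np.diff(x) > 0])
    return x[keep], y[keep]


def spline_envelopes(values: np.ndarray, maxima: np.ndarray, minima: np.ndarray,
                     policy: str = "mirror") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural cubic-spline envelopes and their pointwise mean.

    The upper envelope interpolates the maxima, the lower the minima,
    both extended past the record ends per ``policy``; the mean envelope
    is their simple average.  Requires at least one maximum and one
    minimum (mirror extension supplies the outer knots).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if maxima.size < 1 or minima.size < 1:
        raise ValueError("need >= 1 maximum and >= 1 minimum to form envelopes")
    grid = np.arange(n, dtype=float)
    ends = (v[0], v[-1])
    ux, uy = _extend_knots(np.sort(maxima), v[np.sort(maxima)], n, policy, ends)
    lx, ly = _extend_knots(np.sort(minima), v[np.sort(minima)], n, policy, ends)
    upper = CubicSpline(ux, uy, bc_type="natural")(grid)
    lower = CubicSpline(lx, ly, bc_type="natural")(grid)
    return upper, lower, 0.5 * (upper + lower)


def is_imf(candidate: np.ndarray, tol: float = 0.05,
           boundary_policy: str = "mirror") -> bool:
    """Intrinsic-mode test: counts criterion plus near-zero envelope mean.

    True iff the numbers of extrema and zero crossings differ by at most
    one AND the mean envelope stays within ``tol`` times the candidate's
    range everywhere.  Candidates with fewer than two maxima or two
    minima fail outright.
    """
    v = np.asarray(candidate, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    maxima, minima = find_extrema(v)
    if maxima.size < 2 or minima.size < 2:
        return False
    n_extrema = maxima.size + minima.size
    n_zc = count_zero_crossings(v)
    if abs(n_extrema - n_zc) > 1:
        return False
    _, _, mean_env = spline_envelopes(v, maxima, minima, boundary_policy)
    vrange = float(np.ptp(v))
    if vrange == 0.0:
        return False
    return bool(np.max(np.abs(mean_env)) <= tol * vrange)


def sift_one_imf(signal: np.ndarray, config: SiftConfig = SiftConfig()
                 ) -> tuple[np.ndarray, int, str]:
    """Extract one IMF from ``signal`` by iterative envelope-mean removal.

    Returns ``(imf, iterations, accepted_by)``.  Each iteration replaces
    the candidate ``h`` by ``h − mean_envelope(h)``; the loop ends when
    Huang's pointwise Cauchy criterion
    ``Σ (h_prev−h)² / h_prev² < sd_threshold`` fires, when the iteration
    cap is reached, or when the candidate runs out of extrema.
    """
    h = np.asarray(signal, dtype=float).copy()
    accepted = "max_iterations"
    iterations = 0
    for iterations in range(1, config.max_sift_iterations + 1):
        maxima, minima = find_extrema(h)
        if maxima.size < 1 or minima.size < 1:
            accepted = "lost_extrema"
            break
        _, _, mean_env = spline_envelopes(h, maxima, minima, config.boundary_policy)
        h_new = h - mean_env
        # Huang's pointwise Cauchy criterion; the peak-scaled epsilon keeps
        # near-zero samples of h from dominating the sum
        scale = float(np.max(h * h))
        sd = float(np.sum((h - h_new) ** 2 / (h * h + 1e-12 * scale))) if scale > 0 else 0.0
        h = h_new
        if sd < config.sd_threshold:
            accepted = "cauchy"
            break
    return h, iterations, accepted


def _n_interior_extrema(values: np.ndarray) -> int:
    maxima, minima = find_extrema(values)
    return int(maxima.size + minima.size)


def emd(spectrum: Spectrum | np.ndarray, config: SiftConfig = SiftConfig()
        ) -> Decomposition:
    """Full empirical mode decomposition of a spectrum.

    Successively sifts IMFs out of the running residual until the
    residual is monotone (at most one interior extremum), can no longer
    support envelopes, or the IMF cap is hit.  The returned components
    satisfy ``sum(imfs) + residual == input`` to machine precision by
    construction.
    """
    values = spectrum.intensity if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if values.size < 5:
        raise ValueError("EMD needs at least 5 samples to form envelopes")
    residual = values.astype(float).copy()
    out = Decomposition(imfs=[], residual=residual)
    while True:
        maxima, minima = find_extrema(out.residual)
        if _n_interior_extrema(out.residual) <= 1:
            out.stop_reason = "monotone_residual"
            break
        if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 3:
            out.stop_reason = "too_few_extrema"
            break
        if out.n_imfs >= config.max_imfs:
            out.stop_reason = "max_imfs"
            break
        imf, iters, accepted = sift_one_imf(out.residual, config)
        out.imfs.append(imf)
        out.sift_iterations.append(iters)
        out.accepted_by.append(accepted)
        out.residual = out.residual - imf
    return out
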
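"""F-test selection of the noise/signal cut-off among IMFs.

Noise-dominated (low-order) IMFs show widely dispersed instantaneous
frequencies, signal IMFs narrow ones, so the squared ratio of the
frequency SDs of consecutive components jumps sharply at the boundary.
Scanning from the residual (lowest frequency) toward IMF_1, each
consecutive pair contributes a variance ratio F; the first ratio
exceeding the upper-tail critical value of the F distribution — by
default at 99.95 % confidence with 2 and 4 degrees of freedom — marks
the cut-off: IMF_1..IMF_k are classed as noise.

Each ratio is oriented with the higher-frequency member's variance in
the numerator (F ≥ 1 convention) so the one-sided upper-tail test is
meaningful; a literal low-over-high ratio would shrink below 1 exactly
where the dispersion jumps and could never be significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hilbert_freq import FrequencySummary

__all__ = ["FTestConfig", "CutoffDecision", "f_statistics", "f_critical", "select_cutoff"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FTestConfig:
    """Confidence level and degrees of freedom of the variance-ratio test.

    The defaults (confidence 0.9995, dof (2, 4)) follow the method's
    published parameterisation and are used regardless of record length.
    """

    confidence: float = 0.9995
    dof1: int = 2
    dof2: int = 4
    scan_order: str = "low_to_high_frequency"

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.dof1 < 1 or self.dof2 < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if self.scan_order != "low_to_high_frequency":
            raise ValueError("only low_to_high_frequency scanning is supported")


@dataclass(frozen=True)
class CutoffDecision:
    """Outcome of the cut-off scan.

    ``k`` is in original IMF indexing: IMF_1..IMF_k are noise and
    ``k == 0`` means nothing is removed.  ``f_values[j]`` is the
    oriented variance ratio of the pair at scan position ``j``, where
    ``j == 0`` compares the residual with the last IMF.
    """

    k: int
    f_values: np.ndarray
    f_critical: float
    significant: np.ndarray


def f_statistics(sds: np.ndarray) -> np.ndarray:
    """Oriented variance ratios of consecutive components.

    ``sds`` is ordered from the lowest-frequency component (residual)
    to the highest (IMF_1).  Entry ``j`` of the result is
    ``sds[j+1]**2 / sds[j]**2`` — higher-frequency variance over
    lower-frequency variance.  Zero SDs are replaced by the smallest
    positive SD in the list so ratios stay finite (logged); an all-zero
    list is an error.
    """
    s = np.asarray(sds, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two components")
    if np.any(s < 0):
        raise ValueError("SDs must be non-negative")
    if not np.any(s > 0):
        raise ValueError("all SDs are zero: no frequency structure to test")
    if np.any(s == 0):
        floor = float(np.min(s[s > 0]))
        logger.info("replacing %d zero SD(s) by the smallest positive SD %.3g",
                    int(np.sum(s == 0)), floor)
        s = np.where(s == 0, floor, s)
    return (s[1:] / s[:-1]) ** 2


def f_critical(config: FTestConfig = FTestConfig()) -> float:
    """Upper-tail critical value of F(dof1, dof2) at 1 − confidence."""
    return float(stats.f.ppf(config.confidence, config.dof1, config.dof2))


def select_cutoff(summary: FrequencySummary, config: FTestConfig = FTestConfig()
                  ) -> CutoffDecision:
    """Scan variance ratios from the residual end and pick the cut-off.

    The summary lists components in IMF order with the residual last;
    the scan runs over the reversed (residual-first) sequence.  The
    first significant ratio, between scan positions ``j`` and ``j+1``,
    declares the component at ``j+1`` and everything at higher frequency
    to be noise, i.e. ``k = n_imfs − j``.  With no significant ratio,
    ``k = 0`` and the spectrum is left untouched.
    """
    n_imfs = summary.n_components - 1
    if summary.n_components < 2:
        logger.warning("fewer than two components; cut-off defaults to 0")
        return CutoffDecision(0, np.empty(0), f_critical(config),
                              np.empty(0, dtype=bool))
    reversed_sds = summary.sds[::-1]  # residual first, IMF_1 last
    f_values = f_statistics(reversed_sds)
    crit = f_critical(config)
    significant = f_values > crit
    k = 0
    hits = np.nonzero(significant)[0]
    if hits.size:
        k = n_imfs - int(hits[0])
    return CutoffDecision(k, f_values, crit, significant)
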
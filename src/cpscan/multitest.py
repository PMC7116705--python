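"""Multiple-testing procedures over candidate p-values (final pruning stage).

Two classical rules are provided: the Benjamini-Hochberg step-up procedure
controlling the false discovery rate, and the per-hypothesis Bonferroni
(adjusted p-value) rule.  Both operate once, on the p-values computed over
the stage-1 segmentation; there is no iterative re-merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discrimination import SegmentTestResult
from .scan import CandidateSet

__all__ = ["DetectionResult", "bh_procedure", "bonferroni_procedure",
           "finalize", "METHODS"]

METHODS = ("bh", "bonferroni")


@dataclass(frozen=True)
class DetectionResult:
    """Validated change point set with per-candidate decisions."""

    candidates: CandidateSet
    p_values: np.ndarray
    method: str
    alpha: float
    rejected: np.ndarray
    final_change_points: np.ndarray
    tests: tuple[SegmentTestResult, ...] = field(default=(), repr=False)

    @property
    def n_change_points(self) -> int:
        return int(self.final_change_points.size)


def _check(p_values, alpha) -> np.ndarray:
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return p


def bh_procedure(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions, in the original order.

    Sort the q p-values, find the largest i with ``P_(i) <= (i/q) alpha`` and
    reject every hypothesis with a p-value at or below that ``P_(i)`` (so
    tied p-values are rejected or retained together).
    """
    p = _check(p_values, alpha)
    q = p.size
    if q == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = alpha * np.arange(1, q + 1) / q
    passing = np.flatnonzero(sorted_p <= thresh)
    if passing.size == 0:
        return np.zeros(q, dtype=bool)
    cutoff = sorted_p[passing[-1]]
    return p <= cutoff


def bonferroni_procedure(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni adjusted-p-value decisions: reject i iff ``q * p_i <= alpha``."""
    p = _check(p_values, alpha)
    q = p.size
    if q == 0:
        return np.zeros(0, dtype=bool)
    return q * p <= alpha


def finalize(candidates: CandidateSet, results: list[SegmentTestResult],
             method: str = "bh", alpha: float = 0.05) -> DetectionResult:
    """Assemble the final change point set from per-candidate test results.

    The chosen procedure is applied in a single pass to the unadjusted
    p-values (one per candidate, order preserved); candidates whose null is
    rejected form the final set.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    cps = candidates.change_points
    if len(results) != cps.size:
        raise ValueError(
            f"{cps.size} candidates but {len(results)} test results")
    p = np.array([r.p_value for r in results], dtype=float)
    reject = bh_procedure(p, alpha) if method == "bh" else \
        bonferroni_procedure(p, alpha)
    return DetectionResult(
        candidates=candidates, p_values=p, method=method, alpha=alpha,
        rejected=reject, final_change_points=cps[reject],
        tests=tuple(results))
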
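"""Parametric spectral discrimination likelihood-ratio test for two segments.

Tests whether two adjacent segments share one autoregressive structure
(equal coefficients and innovation variance, i.e. equal spectral density).
Both segments are fitted by Yule-Walker at a common fixed order
``p = floor(log10(T_min)^2)`` (configurable exponent and base); under the
null the same recursion runs on the pooled autocovariances.  The statistic

    Lambda = T1 log(s0^2 / sx^2) + T2 log(s0^2 / sy^2)

is referred to a chi-square distribution whose degrees of freedom depend on
the variant:

==============  ====================================================  ======
variant         null hypothesis                                       df
==============  ====================================================  ======
zero_mean       equal coefficients and variance (zero-mean series)    p + 1
mean_corrected  additionally equal means (pooled-mean centering)      p + 2
known_order     orders estimated per segment by BIC                   px+py-p+1
==============  ====================================================  ======

``known_order`` is exposed for completeness but is not the pipeline default:
with BIC-estimated orders the test degrades when the segments are not truly
autoregressive, which is exactly the situation the fixed-order rule exists
for.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .ar import (DegenerateSeriesError, as_values, autocovariance,
                 fixed_order, levinson_durbin, levinson_path,
                 pooled_autocovariance)
from .scan import CandidateSet

__all__ = ["SegmentTestResult", "discrimination_test", "validate_candidates",
           "VARIANTS"]

VARIANTS = ("zero_mean", "mean_corrected", "known_order")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentTestResult:
    """Outcome of one two-segment discrimination test."""

    lambda_stat: float
    df: int
    p_value: float
    order_x: int
    order_y: int
    order_common: int
    var_x: float
    var_y: float
    var_pooled: float
    variant: str
    position: int | None = None   # candidate location, when run in a pipeline


def _bic_order(gamma: np.ndarray, n: int) -> int:
    """Smallest-BIC AR order for one autocovariance sequence."""
    sigma2, _, valid = levinson_path(gamma)
    orders = np.arange(gamma.size)
    with np.errstate(divide="ignore"):
        bic = np.where(valid[:, 0], n * np.log(np.where(valid[:, 0], sigma2[:, 0], 1.0)),
                       np.inf) + orders * math.log(n)
    if not np.isfinite(bic).any():
        raise DegenerateSeriesError("degenerate segment in order selection")
    return int(np.argmin(bic))


def discrimination_test(x, y, variant: str = "zero_mean",
                        upsilon: float = 2.0, log_base: float = 10.0,
                        max_order: int | None = None) -> SegmentTestResult:
    """Likelihood-ratio test that segments ``x`` and ``y`` share one AR model.

    ``zero_mean`` treats the data as already centred (the pipeline centres
    each segment by its own mean before calling); ``mean_corrected`` centres
    internally (per-segment means under the alternative, the pooled mean
    under the null) and also tests equality of means.  Lambda is clipped at
    zero if round-off makes it marginally negative.

    Raises
    ------
    ValueError
        If a segment is too short to support the fixed order (the candidate
        should be rejected upstream).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    vx, vy = as_values(x), as_values(y)
    t1, t2 = vx.size, vy.size
    tmin = min(t1, t2)

    if variant == "known_order":
        pmax = min(10, tmin - 2) if max_order is None else max_order
        gx_full = autocovariance(vx, pmax)
        gy_full = autocovariance(vy, pmax)
        px = _bic_order(gx_full, t1)
        py = _bic_order(gy_full, t2)
        pooled_full = pooled_autocovariance(vx, vy, pmax)
        p = _bic_order(pooled_full.values, t1 + t2)
        df = max(px + py - p + 1, 1)
        fx = levinson_durbin(gx_full, px)
        fy = levinson_durbin(gy_full, py)
        f0 = levinson_durbin(pooled_full.values, p)
    else:
        p = fixed_order(tmin, upsilon=upsilon, log_base=log_base)
        if p + 1 >= tmin:
            raise ValueError(
                f"segment of length {tmin} too short for fixed order {p}; "
                "reject this candidate upstream")
        mean_correct = variant == "mean_corrected"
        gx = autocovariance(vx, p, mean_correct=mean_correct)
        gy = autocovariance(vy, p, mean_correct=mean_correct)
        pooled = pooled_autocovariance(vx, vy, p, mean_correct=mean_correct)
        fx = levinson_durbin(gx, p)
        fy = levinson_durbin(gy, p)
        f0 = levinson_durbin(pooled.values, p)
        px = py = p
        df = p + 2 if mean_correct else p + 1

    s_x, s_y, s_0 = fx.innovation_var, fy.innovation_var, f0.innovation_var
    lam = t1 * math.log(s_0 / s_x) + t2 * math.log(s_0 / s_y)
    lam = max(lam, 0.0)
    return SegmentTestResult(
        lambda_stat=lam, df=int(df), p_value=float(chi2.sf(lam, df)),
        order_x=int(px), order_y=int(py), order_common=int(p),
        var_x=float(s_x), var_y=float(s_y), var_pooled=float(s_0),
        variant=variant)


def validate_candidates(x, candidates: CandidateSet,
                        variant: str = "zero_mean", upsilon: float = 2.0,
                        log_base: float = 10.0) -> list[SegmentTestResult]:
    """Test every candidate against its two flanking segments.

    Candidate ``k_i`` is tested on the segments delimited by the
    *neighboring candidates* ``(k_{i-1}, k_i]`` and ``(k_i, k_{i+1}]`` (with
    ``k_0 = 0`` and ``k_{q+1} = T``), the bottom-up convention.  For the
    ``zero_mean`` variant each segment is centred by its own mean first.

    A candidate whose flanking segment is too short (or degenerate) cannot
    support a change and is assigned ``p_value = 1`` with a logged warning.
    """
    v = as_values(x)
    T = v.size
    cps = candidates.change_points
    bounds = np.concatenate(([0], cps, [T]))
    results: list[SegmentTestResult] = []
    for idx in range(1, bounds.size - 1):
        k = int(bounds[idx])
        seg1 = v[bounds[idx - 1]: bounds[idx]]
        seg2 = v[bounds[idx]: bounds[idx + 1]]
        tmin = min(seg1.size, seg2.size)
        try:
            p = fixed_order(max(tmin, 2), upsilon=upsilon, log_base=log_base)
            if tmin < p + 2:
                raise ValueError(f"flanking segment of length {tmin} too short")
            if variant == "zero_mean":
                seg1 = seg1 - seg1.mean()
                seg2 = seg2 - seg2.mean()
            res = discrimination_test(seg1, seg2, variant=variant,
                                      upsilon=upsilon, log_base=log_base)
            res = SegmentTestResult(**{**res.__dict__, "position": k})
        except (ValueError, DegenerateSeriesError) as exc:
            logger.warning("candidate %d cannot support a change (%s); "
                           "p-value set to 1", k, exc)
            p = fixed_order(max(tmin, 2), upsilon=upsilon, log_base=log_base)
            res = SegmentTestResult(
                lambda_stat=0.0, df=p + (2 if variant == "mean_corrected" else 1),
                p_value=1.0, order_x=p, order_y=p, order_common=p,
                var_x=float("nan"), var_y=float("nan"),
                var_pooled=float("nan"), variant=variant, position=k)
        results.append(res)
    return results
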
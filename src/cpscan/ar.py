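"""Autocovariance, Levinson-Durbin recursion and Gaussian AR conditional likelihood.

This is the shared numerical engine of the package.  All autoregressive fits
use the Yule-Walker moment equations solved by the Levinson-Durbin recursion.

Sign convention
---------------
Fitted coefficients ``beta`` follow the *estimation* convention

    x_t + beta_1 x_{t-1} + ... + beta_p x_{t-p} = eps_t,

so a generative AR(1) ``x_t = phi x_{t-1} + eps_t`` is recovered as
``beta_1 = -phi``.  The simulator (:mod:`cpscan.simulate`) uses the generative
convention; conversion between the two is a sign flip and is always explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ARFit",
    "PooledCov",
    "DegenerateSeriesError",
    "autocovariance",
    "pooled_autocovariance",
    "levinson_durbin",
    "levinson_path",
    "ar_conditional_loglik",
    "fixed_order",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateSeriesError(ValueError):
    """Raised when an autocovariance sequence is not positive definite.

    Typically the underlying window is constant (zero variance) or the sample
    autocovariances fail positive-definiteness at the requested order.
    """


def as_values(x) -> np.ndarray:
    """Return the observation vector of ``x`` as a 1-d float array.

    Accepts a plain array-like or any object exposing a ``values`` attribute
    (e.g. :class:`cpscan.simulate.TimeSeries`).
    """
    v = getattr(x, "values", x)
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


@dataclass(frozen=True)
class ARFit:
    """A fitted autoregression in the +sign convention.

    Attributes
    ----------
    order
        AR order ``p``.
    coeffs
        ``beta_1 .. beta_p`` with ``x_t + beta_1 x_{t-1} + ... = eps_t``.
    innovation_var
        Residual (innovation) variance ``sigma^2_p``.
    autocovariances
        The autocovariances ``gamma(0) .. gamma(p)`` the fit was computed from.
    """

    order: int
    coeffs: np.ndarray
    innovation_var: float
    autocovariances: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PooledCov:
    """Pooled autocovariances ``c(0) .. c(p)`` of two adjacent segments."""

    values: np.ndarray
    n1: int
    n2: int


def autocovariance(x, max_lag: int, mean_correct: bool = False,
                   mean_value: float | None = None) -> np.ndarray:
    """Sample autocovariances ``gamma(0) .. gamma(max_lag)`` with divisor T.

    ``gamma(j) = (1/T) * sum_{t=j}^{T-1} x_t x_{t-j}`` (0-based), the biased
    moment estimator.  With ``mean_correct=True`` every observation is first
    centred by ``mean_value`` (the sample mean when not given), yielding the
    mean-corrected variant ``gamma*(j)``.
    """
    v = as_values(x)
    T = v.size
    if max_lag >= T:
        raise ValueError(f"max_lag ({max_lag}) must be < series length ({T})")
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    if mean_correct:
        mu = v.mean() if mean_value is None else float(mean_value)
        v = v - mu
    out = np.empty(max_lag + 1)
    for j in range(max_lag + 1):
        out[j] = np.dot(v[j:], v[: T - j]) / T
    return out


def pooled_autocovariance(x, y, max_lag: int,
                          mean_correct: bool = False) -> PooledCov:
    """Pooled autocovariances of two segments, divisor ``T1 + T2``.

    ``c(j) = (sum_x + sum_y) / (T1 + T2)`` where each sum runs over the lag-j
    cross products within its own segment (no products across the boundary).
    In the mean-corrected variant *both* segments are centred by the single
    pooled mean ``mu = (T1 mu_X + T2 mu_Y) / (T1 + T2)``, matching the
    mean-corrected null of the discrimination test.
    """
    vx, vy = as_values(x), as_values(y)
    n1, n2 = vx.size, vy.size
    if max_lag >= min(n1, n2):
        raise ValueError(
            f"max_lag ({max_lag}) must be < min segment length ({min(n1, n2)})")
    if mean_correct:
        mu = (vx.sum() + vy.sum()) / (n1 + n2)
        vx = vx - mu
        vy = vy - mu
    out = np.empty(max_lag + 1)
    for j in range(max_lag + 1):
        sx = np.dot(vx[j:], vx[: n1 - j])
        sy = np.dot(vy[j:], vy[: n2 - j])
        out[j] = (sx + sy) / (n1 + n2)
    return PooledCov(values=out, n1=n1, n2=n2)


def levinson_path(gamma: np.ndarray, rtol: float = 1e-12):
    """Batched Levinson-Durbin recursion over all orders ``0 .. m``.

    Parameters
    ----------
    gamma
        Array of shape ``(n, m+1)`` (or ``(m+1,)``) of autocovariance
        sequences, one row per problem.
    rtol
        Relative floor on the innovation variance below which the recursion
        is flagged invalid (non-positive-definite input).

    Returns
    -------
    sigma2 : ``(m+1, n)``
        Innovation variance path; ``sigma2[k]`` is the order-k residual
        variance.
    beta : ``(m+1, n, m)``
        Coefficients in the +sign convention; row ``beta[k, i, :k]`` holds the
        order-k fit of problem ``i``.
    valid : ``(m+1, n)`` bool
        Whether the recursion is numerically valid up to each order.
    """
    g = np.atleast_2d(np.asarray(gamma, dtype=float))
    n, m1 = g.shape
    m = m1 - 1
    g0 = g[:, 0]
    sigma2 = np.zeros((m + 1, n))
    phi = np.zeros((m + 1, n, m))
    valid = np.zeros((m + 1, n), dtype=bool)
    sigma2[0] = g0
    valid[0] = g0 > 0
    floor = rtol * np.abs(g0)
    for k in range(1, m + 1):
        prev = phi[k - 1, :, : k - 1]
        # sum_{j=1}^{k-1} phi_{k-1,j} gamma(k-j)
        acc = g[:, k] - np.einsum("nj,nj->n", prev, g[:, k - 1:0:-1])
        s_prev = np.where(sigma2[k - 1] > 0, sigma2[k - 1], 1.0)
        kappa = np.where(valid[k - 1], acc / s_prev, 0.0)
        phi[k, :, : k - 1] = prev - kappa[:, None] * prev[:, ::-1]
        phi[k, :, k - 1] = kappa
        sigma2[k] = sigma2[k - 1] * (1.0 - kappa ** 2)
        valid[k] = valid[k - 1] & (np.abs(kappa) < 1.0) & (sigma2[k] > floor)
    return sigma2, -phi, valid


def levinson_durbin(gamma, p: int) -> ARFit:
    """Solve the order-``p`` Yule-Walker equations by Levinson-Durbin.

    Equivalent (to ~1e-10 relative) to the direct Toeplitz solution
    ``beta = -Gamma_p^{-1} gamma_p`` with ``sigma^2_p = gamma(0) +
    gamma_p' beta_p``, but in O(p^2).

    Raises
    ------
    DegenerateSeriesError
        If the autocovariance sequence is not positive definite up to order
        ``p`` (e.g. a constant segment).
    """
    g = np.asarray(gamma, dtype=float).ravel()
    if g.size < p + 1:
        raise ValueError(f"need gamma(0..{p}), got length {g.size}")
    if not g[0] > 0:
        raise DegenerateSeriesError(
            f"gamma(0) = {g[0]!r} is not positive (degenerate segment)")
    sigma2, beta, valid = levinson_path(g[: p + 1])
    if not valid[p, 0]:
        k_bad = int(np.argmin(valid[:, 0]))
        raise DegenerateSeriesError(
            f"autocovariance sequence not positive definite at order {k_bad} "
            "(degenerate segment)")
    return ARFit(order=p, coeffs=beta[p, 0, :p].copy(),
                 innovation_var=float(sigma2[p, 0]),
                 autocovariances=g[: p + 1].copy())


def ar_conditional_loglik(x, fit: ARFit, start: int | None = None,
                          end: int | None = None) -> float:
    """Gaussian conditional log-likelihood of ``x[start..end]`` under ``fit``.

    Each term ``t`` in the inclusive 0-based range contributes

        -0.5 log(2 pi sigma^2) - (x_t + beta_1 x_{t-1} + ... )^2 / (2 sigma^2)

    conditioning on the ``p`` observations preceding ``start``, which must
    exist (``start >= p``).  The sum is additive over a partition of the
    range at fixed parameters, which is what makes the scan statistic a
    genuine likelihood ratio.
    """
    v = as_values(x)
    p = fit.order
    if start is None:
        start = p
    if end is None:
        end = v.size - 1
    if start < p:
        raise ValueError(
            f"start ({start}) must be >= order ({p}): lagged values needed")
    if end >= v.size or end < start:
        raise ValueError(f"invalid evaluation range [{start}, {end}]")
    s2 = fit.innovation_var
    if not s2 > 0:
        raise DegenerateSeriesError("non-positive innovation variance")
    idx = np.arange(start, end + 1)
    resid = v[idx].copy()
    for j in range(1, p + 1):
        resid += fit.coeffs[j - 1] * v[idx - j]
    n = idx.size
    return float(-0.5 * n * (_LOG_2PI + math.log(s2))
                 - np.dot(resid, resid) / (2.0 * s2))


def fixed_order(t_min: int, upsilon: float = 2.0, log_base: float = 10.0) -> int:
    """Fixed AR order ``p = floor(log(t_min)^upsilon)`` for the two-segment test.

    The autoregressive-approximation order rule: both segments are fitted at
    the same order driven by the shorter segment length ``t_min``, keeping the
    test valid when the data are not truly autoregressive.  Defaults are the
    base-10 logarithm with ``upsilon = 2``; both are configurable (any
    ``upsilon > 1`` is admissible, and the rule is not tied to a particular
    base on theoretical grounds).
    """
    if t_min < 2:
        raise ValueError("t_min must be >= 2")
    if log_base == 10.0:
        lg = math.log10(t_min)
    elif log_base == math.e:
        lg = math.log(t_min)
    else:
        lg = math.log(t_min) / math.log(log_base)
    return int(math.floor(lg ** upsilon))
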
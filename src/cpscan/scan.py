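"""Likelihood-ratio scan statistics and candidate change point extraction.

For every position ``t`` a window of radius ``h`` is split into halves; AR
models are fitted (Yule-Walker) to each half and to the full window at a
single common order, and the normalized likelihood-ratio

    LS_h(t) = (1/h) [ L_left(theta_1) + L_right(theta_2) - L_full(theta) ]

is recorded.  The three conditional log-likelihoods are evaluated over the
same observation set (the right half conditions on lagged values from the
left half), so the full-window likelihood is the sum of the two half
contributions at common parameters and the statistic is non-negative up to
the Yule-Walker/exact-MLE discrepancy; residual round-off negatives are
floored at zero.

Positions where LS_h is a neighborhood maximum become candidate change
points.  No threshold is applied: the candidate set is deliberately
over-inclusive, and the validation stage prunes it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .ar import as_values, levinson_path

__all__ = [
    "ScanProfile",
    "CandidateSet",
    "window_radius",
    "rule_of_thumb_radius",
    "scan_profile",
    "select_candidates",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ScanProfile:
    """LS_h(t) over all scanning positions ``t = h .. T-h`` (1-based)."""

    h: int
    positions: np.ndarray
    values: np.ndarray
    orders: np.ndarray

    def __post_init__(self):
        if len(self.values) != len(self.positions):
            raise ValueError("positions/values length mismatch")


@dataclass(frozen=True)
class CandidateSet:
    """Candidate change points (1-based; each k is the last index of its
    segment) extracted from one scan profile of radius ``source_h``."""

    change_points: np.ndarray
    source_h: int

    def __post_init__(self):
        cp = np.asarray(self.change_points, dtype=int)
        if cp.size and np.any(np.diff(cp) <= 0):
            raise ValueError("candidates must be strictly increasing")
        object.__setattr__(self, "change_points", cp)

    def __len__(self) -> int:
        return self.change_points.size


def window_radius(T: int, r: float = 1.0) -> int:
    """Scan radius ``h = floor(r * floor(ln(T)^2))``.

    ``r`` is the user multiplier; typical choices are 1 to 2.5.  Raises when
    the resulting radius leaves no scanning positions (``2h >= T``).
    """
    if T < 4:
        raise ValueError("series too short to scan (T < 4)")
    h = int(math.floor(r * math.floor(math.log(T) ** 2)))
    if h < 1 or 2 * h >= T:
        raise ValueError(
            f"radius h={h} leaves no scanning positions for T={T}")
    return h


def rule_of_thumb_radius(T: int) -> int:
    """The default radius ``h = max(50, 2 floor(ln(T)^2))``."""
    if T < 4:
        raise ValueError("series too short to scan (T < 4)")
    h = max(50, 2 * int(math.floor(math.log(T) ** 2)))
    if 2 * h >= T:
        raise ValueError(
            f"rule-of-thumb radius h={h} leaves no scanning positions for T={T}")
    return h


def _sliding_gammas(x: np.ndarray, h: int, pmax: int):
    """Autocovariances (divisor = window length) of the left half, right half
    and full window at every scan position, via per-lag cumulative sums."""
    T = x.size
    i = np.arange(h - 1, T - h)          # 0-based last index of the left half
    a = i - h + 1                        # window start
    b = i + h                            # window end (inclusive)
    nwin = i.size
    gl = np.empty((nwin, pmax + 1))
    gr = np.empty((nwin, pmax + 1))
    gf = np.empty((nwin, pmax + 1))
    for j in range(pmax + 1):
        prod = np.zeros(T)
        prod[j:] = x[j:] * x[: T - j]
        C = np.concatenate(([0.0], np.cumsum(prod)))
        gl[:, j] = (C[i + 1] - C[a + j]) / h
        gr[:, j] = (C[b + 1] - C[i + 1 + j]) / h
        gf[:, j] = (C[b + 1] - C[a + j]) / (2 * h)
    return a, i, b, gl, gr, gf


def scan_profile(x, h: int, max_order: int | None = None,
                 center: bool = True) -> ScanProfile:
    """Compute LS_h(t) for every scanning position.

    The series is mean-corrected first (``center=True``; the pipeline's
    convention, so that level shifts are not flagged).  The common AR order
    for each window is chosen by BIC on the full window over orders
    ``0 .. min(10, floor(sqrt(h)))`` and imposed on both halves, making the
    three fits nested.

    Degenerate (constant) windows get LS = 0 with a warning.
    """
    v = as_values(x)
    T = v.size
    if 2 * h >= T:
        raise ValueError(f"need 2h < T (h={h}, T={T})")
    if h < 4:
        raise ValueError("radius too small to fit AR models (h < 4)")
    if center:
        v = v - v.mean()
    pmax = min(10, int(math.isqrt(h))) if max_order is None else int(max_order)
    pmax = max(pmax, 0)

    a, i, b, gl, gr, gf = _sliding_gammas(v, h, pmax)
    nwin = i.size
    s2f, bf, vf = levinson_path(gf)
    s2l, bl, vl = levinson_path(gl)
    s2r, br, vr = levinson_path(gr)

    n_full = 2 * h
    orders_grid = np.arange(pmax + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bic = np.where(vf, n_full * np.log(np.where(vf, s2f, 1.0)), np.inf)
    bic = bic + orders_grid[:, None] * math.log(n_full)
    p_bic = np.argmin(bic, axis=0)

    # largest order each of the three recursions supports, per window
    def _max_valid(valid):
        ok = np.cumprod(valid, axis=0).astype(bool)
        return ok.sum(axis=0) - 1  # -1 when even order 0 is invalid

    cap = np.minimum(np.minimum(_max_valid(vl), _max_valid(vr)), _max_valid(vf))
    degenerate = cap < 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} degenerate (constant) scan window(s); "
            "LS set to 0", RuntimeWarning, stacklevel=2)
    orders = np.minimum(p_bic, np.maximum(cap, 0)).astype(int)

    values = np.zeros(nwin)
    usable = ~degenerate
    lag_grid = np.arange(pmax + 1)
    for p in np.unique(orders[usable]):
        w = np.flatnonzero(usable & (orders == p))
        if w.size == 0:
            continue
        npts = 2 * h - p                       # evaluated observations
        offs = np.arange(npts)
        S = (a[w] + p)[:, None] + offs[None, :]
        lag = S[:, :, None] - lag_grid[None, None, : p + 1]
        X = v[lag]                             # (m, npts, p+1)
        ones = np.ones((w.size, 1))
        cF = np.hstack([ones, bf[p][w, :p]])
        cL = np.hstack([ones, bl[p][w, :p]])
        cR = np.hstack([ones, br[p][w, :p]])
        eF = np.einsum("mnk,mk->mn", X, cF)
        eL = np.einsum("mnk,mk->mn", X[:, : h - p, :], cL)
        eR = np.einsum("mnk,mk->mn", X[:, h - p:, :], cR)
        sF, sL, sR = s2f[p, w], s2l[p, w], s2r[p, w]
        LF = -0.5 * npts * (_LOG_2PI + np.log(sF)) - (eF ** 2).sum(1) / (2 * sF)
        LL = -0.5 * (h - p) * (_LOG_2PI + np.log(sL)) - (eL ** 2).sum(1) / (2 * sL)
        LR = -0.5 * h * (_LOG_2PI + np.log(sR)) - (eR ** 2).sum(1) / (2 * sR)
        values[w] = (LL + LR - LF) / h

    values = np.maximum(values, 0.0)
    positions = i + 1                          # 1-based t in [h, T-h]
    return ScanProfile(h=h, positions=positions, values=values, orders=orders)


def select_candidates(profile: ScanProfile) -> CandidateSet:
    """Extract candidate change points as neighborhood maxima of LS_h.

    A position ``t`` is a candidate iff ``LS_h(t) >= LS_h(s)`` for every
    profile position ``s`` with ``|s - t| < h``, with ties broken to the
    smallest ``t`` (i.e. ``t`` must strictly exceed every *earlier* position
    in its neighborhood).  Candidates are therefore at least ``h`` apart.
    No height threshold is applied; pruning is left to the validation stage.
    """
    v = profile.values
    h = profile.h
    if v.size == 0:
        return CandidateSet(change_points=np.empty(0, dtype=int), source_h=h)
    size = 2 * h - 1
    fmax = maximum_filter1d(v, size=size, mode="constant", cval=-np.inf)
    keep = []
    for t in np.flatnonzero(v >= fmax):
        lo = max(0, t - (h - 1))
        if t > lo and v[lo:t].max() >= v[t]:
            continue  # an earlier neighbor ties or beats it
        keep.append(t)
    cps = profile.positions[np.asarray(keep, dtype=int)] if keep else \
        np.empty(0, dtype=int)
    return CandidateSet(change_points=cps, source_h=h)
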
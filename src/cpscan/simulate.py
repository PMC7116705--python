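"""Piecewise stationary AR/ARMA simulation with known change points.

Segments are mutually independent stationary ARMA processes with Gaussian
innovations, concatenated at the change points.  Coefficients here use the
*generative* convention ``x_t = phi_1 x_{t-1} + ... + theta_1 eps_{t-1} +
eps_t`` (note the sign flip relative to the fitted ``beta`` of
:mod:`cpscan.ar`).

A built-in library provides the nine benchmark generating models (A-I)
used throughout the package's simulation study: piecewise AR(1)/AR(2)
processes, near-unit-root segments with a variance change, and piecewise
MA/ARMA processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.arima_process import arma_generate_sample

__all__ = [
    "SegmentSpec",
    "PiecewiseSpec",
    "TimeSeries",
    "simulate_segment",
    "simulate_piecewise",
    "model_library",
    "MODEL_NAMES",
]

MODEL_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I")

#: Extra samples generated and discarded before each retained segment so the
#: kept values are (approximately) draws from the stationary distribution.
BURN_IN_BASE = 500


def _ar_root_check(phi: tuple[float, ...]) -> None:
    """Raise if the AR polynomial 1 - phi_1 z - ... - phi_p z^p has a root
    on or inside the unit circle (non-causal / non-stationary segment)."""
    if not phi:
        return
    poly = np.polynomial.Polynomial([1.0] + [-c for c in phi])
    roots = poly.roots()
    if roots.size:
        moduli = np.abs(roots)
        worst = moduli.min()
        if worst <= 1.0:
            raise ValueError(
                "non-stationary AR polynomial: root modulus "
                f"{worst:.6f} <= 1 (coefficients {list(phi)})")


@dataclass(frozen=True)
class SegmentSpec:
    """One stationary segment of a piecewise process (generative convention).

    ``ar_coeffs`` are ``phi_1 .. phi_p``, ``ma_coeffs`` are ``theta_1 ..
    theta_q`` (empty for a pure AR), ``noise_sd`` the innovation standard
    deviation and ``length`` the number of retained observations.
    """

    ar_coeffs: tuple[float, ...] = ()
    ma_coeffs: tuple[float, ...] = ()
    noise_sd: float = 1.0
    length: int = 1

    def __post_init__(self):
        object.__setattr__(self, "ar_coeffs", tuple(float(c) for c in self.ar_coeffs))
        object.__setattr__(self, "ma_coeffs", tuple(float(c) for c in self.ma_coeffs))
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        _ar_root_check(self.ar_coeffs)


@dataclass(frozen=True)
class PiecewiseSpec:
    """An ordered list of independent segments defining a piecewise process."""

    segments: tuple[SegmentSpec, ...]
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("need at least one segment")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def change_points(self) -> np.ndarray:
        """1-based indices of the last observation of each non-final segment."""
        ends = np.cumsum([s.length for s in self.segments])
        return ends[:-1].astype(int)


@dataclass(frozen=True)
class TimeSeries:
    """A univariate series of ordered real observations."""

    values: np.ndarray
    origin: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("a time series needs at least 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _resolve_seed(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_segment(spec: SegmentSpec, seed) -> TimeSeries:
    """Simulate one stationary ARMA segment with Gaussian innovations.

    A burn-in of ``500 + 10 (p + q)`` samples is generated first and
    discarded, so the retained ``spec.length`` values are approximately
    stationary.  The same ``(spec, seed)`` always yields identical output.
    """
    rng = np.random.default_rng(_resolve_seed(seed))
    p, q = len(spec.ar_coeffs), len(spec.ma_coeffs)
    burn = BURN_IN_BASE + 10 * (p + q)
    ar = np.r_[1.0, [-c for c in spec.ar_coeffs]]
    ma = np.r_[1.0, list(spec.ma_coeffs)]
    x = arma_generate_sample(ar, ma, nsample=spec.length, scale=spec.noise_sd,
                             distrvs=rng.standard_normal, burnin=burn)
    return TimeSeries(values=x, origin="simulated segment")


def simulate_piecewise(spec: PiecewiseSpec, seed):
    """Simulate a piecewise stationary series with known change points.

    Segments are simulated independently, each with its own burn-in; segment
    ``i`` uses the deterministic sub-seed ``SeedSequence([seed, i])`` so that
    editing a later segment never perturbs earlier ones.

    Returns
    -------
    (TimeSeries, numpy.ndarray)
        The concatenated series and the 1-based change point locations (the
        last observation of each non-final segment); empty for a
        single-segment spec.
    """
    if isinstance(seed, np.random.SeedSequence):
        raise TypeError("simulate_piecewise needs an integer seed to derive "
                        "per-segment sub-seeds")
    parts = []
    for i, seg in enumerate(spec.segments):
        sub = np.random.SeedSequence([int(seed), i])
        parts.append(simulate_segment(seg, sub).values)
    name = spec.name or "piecewise"
    ts = TimeSeries(values=np.concatenate(parts), origin=f"simulated {name}")
    return ts, spec.change_points


def _pw(name, *segs):
    return PiecewiseSpec(segments=tuple(SegmentSpec(*s) for s in segs), name=name)


def model_library(name: str, beta: float | None = None) -> PiecewiseSpec:
    """The nine benchmark generating models A-I.

    Segment entries are ``(ar, ma, sd, length)`` in the generative
    convention.  Model A is a single stationary AR(1) segment whose
    coefficient ``beta`` must be supplied (the null, no-change model); all
    other models ignore ``beta`` and supplying it raises.

    =====  ==========================================================
    A      AR(1), coefficient ``beta``, T = 1024, no change point
    B      AR(1) -> AR(2) -> AR(2), changes at 512, 768
    C      AR(1) 0.4 / -0.6 / 0.5, changes at 400, 612
    D      AR(1) 0.75 -> -0.5, one change at 50 (short first segment)
    E      near-unit-root 0.999 with innovation SD 1 / 1.5 / 1,
           changes at 400, 750 (variance-only changes)
    F      AR(2) / near-unit-root AR(1) (SD 1.5) / AR(2), changes at
           400, 750
    G      AR(1) 0.7 / 0.3 / 0.9 / 0.1, changes at 125, 532, 704
    H      ARMA(1,1) segments, changes at 125, 532, 704
    I      MA(1) -> MA(2), one change at 128, T = 256
    =====  ==========================================================
    """
    key = str(name).strip().upper()
    if key not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose one of {MODEL_NAMES}")
    if key == "A":
        if beta is None:
            raise ValueError("Model A needs its AR(1) coefficient `beta`")
        return _pw("A", ((beta,), (), 1.0, 1024))
    if beta is not None:
        raise ValueError(f"`beta` only applies to Model A, not Model {key}")
    if key == "B":
        return _pw("B", ((0.9,), (), 1.0, 512),
                   ((1.69, -0.81), (), 1.0, 256),
                   ((1.32, -0.81), (), 1.0, 256))
    if key == "C":
        return _pw("C", ((0.4,), (), 1.0, 400),
                   ((-0.6,), (), 1.0, 212),
                   ((0.5,), (), 1.0, 412))
    if key == "D":
        return _pw("D", ((0.75,), (), 1.0, 50),
                   ((-0.5,), (), 1.0, 974))
    if key == "E":
        return _pw("E", ((0.999,), (), 1.0, 400),
                   ((0.999,), (), 1.5, 350),
                   ((0.999,), (), 1.0, 274))
    if key == "F":
        return _pw("F", ((1.399, -0.4), (), 1.0, 400),
                   ((0.999,), (), 1.5, 350),
                   ((0.699, 0.3), (), 1.0, 274))
    if key == "G":
        return _pw("G", ((0.7,), (), 1.0, 125),
                   ((0.3,), (), 1.0, 407),
                   ((0.9,), (), 1.0, 172),
                   ((0.1,), (), 1.0, 320))
    if key == "H":
        return _pw("H", ((0.7,), (0.6,), 1.0, 125),
                   ((0.3,), (0.3,), 1.0, 407),
                   ((0.9,), (), 1.0, 172),
                   ((0.1,), (-0.5,), 1.0, 320))
    # key == "I"
    return _pw("I", ((), (0.8,), 1.0, 128),
               ((), (1.68, -0.81), 1.0, 128))
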
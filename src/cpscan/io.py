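"""Reading and writing single-column series files and piecewise model configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import PiecewiseSpec, SegmentSpec, TimeSeries

__all__ = ["read_series", "write_series", "read_piecewise_config"]


def read_series(path) -> TimeSeries:
    """Read a univariate series from a single-column delimited text file.

    A header line is auto-detected (first token not parseable as a number).
    Missing or non-finite values are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    token = first.split(",")[0].split()[0] if first else ""
    try:
        float(token)
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, header=header, skip_blank_lines=False)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column, got {df.shape[1]}")
    values = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite values are not allowed")
    return TimeSeries(values=values, origin=str(path))


def write_series(path, values, header: str = "x") -> None:
    """Write a series as single-column text with a one-line header."""
    arr = np.asarray(getattr(values, "values", values), dtype=float).ravel()
    pd.DataFrame({header: arr}).to_csv(path, index=False)


def read_piecewise_config(path) -> PiecewiseSpec:
    """Read a piecewise model spec from a YAML file.

    Expected layout::

        name: my-model        # optional
        segments:
          - ar: [0.9]         # generative AR coefficients (optional)
            ma: []            # MA coefficients (optional)
            sd: 1.0           # innovation SD (default 1)
            length: 512
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "segments" not in cfg:
        raise ValueError(f"{path}: config must contain a 'segments' list")
    segments = []
    for i, seg in enumerate(cfg["segments"]):
        if "length" not in seg:
            raise ValueError(f"{path}: segment {i} is missing 'length'")
        segments.append(SegmentSpec(
            ar_coeffs=tuple(seg.get("ar", ())),
            ma_coeffs=tuple(seg.get("ma", ())),
            noise_sd=float(seg.get("sd", 1.0)),
            length=int(seg["length"])))
    return PiecewiseSpec(segments=tuple(segments), name=cfg.get("name"))
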
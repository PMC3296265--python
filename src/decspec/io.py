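"""Plain-text I/O: CSV time series, TSV results, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TimeSeries
from .estimators import EstimationResult

__all__ = ["read_timeseries", "write_timeseries", "write_result", "read_result"]


def read_timeseries(path, fs: float) -> TimeSeries:
    """Read a complex series from a CSV with header ``n,re,im``.

    Rows are ordered by index; duplicate or missing indices are rejected with
    an error naming the offending index.
    """
    if fs is None or fs <= 0:
        raise ValueError("a positive sampling frequency fs is required")
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["n", "re", "im"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df[["n", "re", "im"]].isna().any().any():
        bad = int(df.index[df[["n", "re", "im"]].isna().any(axis=1)][0]) + 2
        raise ValueError(f"{path}: malformed row at line {bad}")
    df = df.sort_values("n", kind="stable")
    idx = df["n"].to_numpy()
    dup = idx[:-1][np.diff(idx) == 0]
    if dup.size:
        raise ValueError(f"{path}: duplicate sample index {int(dup[0])}")
    if not np.array_equal(idx, np.arange(len(df))):
        missing = int(np.setdiff1d(np.arange(idx.max() + 1), idx)[0])
        raise ValueError(f"{path}: gap in sample indices (missing index {missing})")
    samples = df["re"].to_numpy(float) + 1j * df["im"].to_numpy(float)
    return TimeSeries(samples=samples, fs=fs)


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a complex series as CSV ``n,re,im`` at full double precision."""
    with open(path, "w") as fh:
        fh.write("n,re,im\n")
        for n, s in enumerate(ts.samples):
            fh.write(f"{n},{float(s.real)!r},{float(s.imag)!r}\n")


def write_result(result: EstimationResult, path) -> None:
    """Write estimated peaks as TSV plus a JSON sidecar with run metadata.

    Numbers are written with ``repr`` so a parse round-trip is exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("peak\tf_hz\td_rad_s\tamplitude\tphase_deg\n")
        for i, pk in enumerate(result.peaks, start=1):
            fh.write(f"{i}\t{pk.f!r}\t{pk.d!r}\t{pk.b!r}\t{pk.psi!r}\n")
    meta = {
        "method": result.method,
        "D": result.D,
        "p": result.p,
        "dims": {
            "L": result.dims.L,
            "M": result.dims.M,
            "D": result.dims.D,
            "N": result.dims.N,
        },
        "diagnostics": result.diagnostics,
        "poles": [[z.real, z.imag] for z in result.poles.poles],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_result(path) -> pd.DataFrame:
    """Parse a result TSV back into a DataFrame (exact round-trip)."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
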
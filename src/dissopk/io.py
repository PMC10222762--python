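"""CSV readers/writers for dissolution and plasma profiles.

Dialect: comma-separated, dot decimal, mandatory header.  Time is in hours
everywhere; units are asserted from header suffixes (``time_h``,
``conc_ng_ml``, dissolution columns ``unit_1..unit_n`` in percent).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dissolution import DissolutionProfile
from .pk import PlasmaProfile

__all__ = [
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_profile_csv",
]


class ProfileIOError(ValueError):
    """Malformed profile file (bad header, units or time ordering)."""


def _check_times(times: np.ndarray, path, require_zero_start: bool) -> None:
    start = 0 if require_zero_start else 1
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            raise ProfileIOError(
                f"{path}: time not increasing at data row {i + 1} "
                f"({times[i]} after {times[i - 1]})"
            )
    if require_zero_start and times[0] != 0:
        raise ProfileIOError(f"{path}: plasma profile must start at time 0")


def read_dissolution_csv(path, product_id: str = "", method_id: str = "") -> DissolutionProfile:
    """Read ``time_h,unit_1..unit_n`` (percent dissolved per replicate)."""
    df = pd.read_csv(path, comment="#")
    if "time_h" not in df.columns:
        raise ProfileIOError(f"{path}: missing 'time_h' column (hours)")
    unit_cols = [c for c in df.columns if c.startswith("unit_")]
    if not unit_cols:
        raise ProfileIOError(f"{path}: no 'unit_*' columns (percent dissolved)")
    times = df["time_h"].to_numpy(dtype=float)
    _check_times(times, path, require_zero_start=False)
    return DissolutionProfile(
        times=times,
        q=df[unit_cols].to_numpy(dtype=float).T,
        product_id=product_id,
        method_id=method_id,
    )


def write_dissolution_csv(profile: DissolutionProfile, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame({"time_h": profile.times})
    for i in range(profile.n_units):
        df[f"unit_{i + 1}"] = profile.q[i]
    _write_with_comment(df, path, header_comment)


def read_plasma_csv(path) -> PlasmaProfile:
    """Read ``time_h,conc_ng_ml``; times must increase strictly from 0."""
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "conc_ng_ml"):
        if col not in df.columns:
            raise ProfileIOError(f"{path}: missing '{col}' column")
    times = df["time_h"].to_numpy(dtype=float)
    _check_times(times, path, require_zero_start=True)
    return PlasmaProfile(times_h=times, conc_ng_ml=df["conc_ng_ml"].to_numpy(dtype=float))


def write_plasma_csv(profile: PlasmaProfile, path, header_comment: str | None = None) -> None:
    df = pd.DataFrame({"time_h": profile.times_h, "conc_ng_ml": profile.conc_ng_ml})
    _write_with_comment(df, path, header_comment)


def _write_with_comment(df: pd.DataFrame, path, comment: str | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def read_profile_csv(path, kind: str):
    """Dispatch on ``kind`` in {'dissolution', 'plasma'}."""
    if kind == "dissolution":
        return read_dissolution_csv(path)
    if kind == "plasma":
        return read_plasma_csv(path)
    raise ValueError(f"kind must be 'dissolution' or 'plasma', got {kind!r}")
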
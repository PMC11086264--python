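"""CSV readers and writers for split times and velocity traces.

Dialect: comma-separated, UTF-8, dot decimal, mandatory header row.
Split files carry columns ``distance,time`` plus optional ``athlete``
and ``trial``; trace files carry ``t,v_raw`` plus optional ``v_smooth``
(and optional ``athlete,trial``).  Values are stored at full precision —
clock rounding is a property of the simulator, not of the file format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fitting import SplitTimes, VelocityTrace

__all__ = ["read_splits", "write_splits", "read_trace", "write_trace"]


class ParseError(ValueError):
    """Malformed input file; message carries location detail."""


def _require_columns(df: pd.DataFrame, required: tuple, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_splits(path) -> dict[tuple[str, int], SplitTimes]:
    """Read split times, one SplitTimes per (athlete, trial) group.

    Files without athlete/trial columns yield the single key
    ``("", 1)``.  An empty file returns an empty dict.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return {}
    _require_columns(df, ("distance", "time"), path)
    if "athlete" not in df.columns:
        df["athlete"] = ""
    if "trial" not in df.columns:
        df["trial"] = 1
    out: dict[tuple[str, int], SplitTimes] = {}
    for (athlete, trial), g in df.groupby(["athlete", "trial"], sort=False):
        g = g.sort_values("distance")
        if g["distance"].duplicated().any():
            dup = g.loc[g["distance"].duplicated(), "distance"].iloc[0]
            raise ParseError(
                f"{path}: duplicate distance {dup} for athlete={athlete!r} "
                f"trial={trial}"
            )
        try:
            out[(str(athlete), int(trial))] = SplitTimes(
                distances=g["distance"].to_numpy(float),
                times=g["time"].to_numpy(float),
                provenance="observed",
            )
        except ValueError as e:
            first_line = int(g.index.min()) + 2  # header + 1-based
            raise ParseError(
                f"{path} (rows from line {first_line}, athlete={athlete!r} "
                f"trial={trial}): {e}"
            ) from e
    return out


def write_splits(
    splits: SplitTimes | dict[tuple[str, int], SplitTimes], path
) -> None:
    """Write one SplitTimes, or a dict keyed by (athlete, trial)."""
    if isinstance(splits, SplitTimes):
        splits = {("", 1): splits}
    rows = []
    for (athlete, trial), s in splits.items():
        for d, t in zip(s.distances, s.times):
            rows.append(
                {"athlete": athlete, "trial": trial, "distance": d, "time": t}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace(path) -> VelocityTrace:
    """Read one velocity trace (columns t, v_raw, optional v_smooth)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("t", "v_raw"), path)
    v_smooth = (
        df["v_smooth"].to_numpy(float) if "v_smooth" in df.columns else None
    )
    try:
        return VelocityTrace(
            t=df["t"].to_numpy(float),
            v_raw=df["v_raw"].to_numpy(float),
            v_smooth=v_smooth,
        )
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_trace(trace: VelocityTrace, path) -> None:
    data = {"t": trace.t, "v_raw": trace.v_raw}
    if trace.v_smooth is not None:
        data["v_smooth"] = trace.v_smooth
    pd.DataFrame(data).to_csv(path, index=False)
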
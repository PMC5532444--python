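"""CSV format contracts between pipeline stages.

All on-disk formats are plain CSV:

* raw movement: ``t_s,x,y,z`` per participant-conversation;
* study metadata: ``dyad,conversation,conv_type,conv_order,task,file_a,file_b``;
* processed movement: ``t_s,a``;
* cutoffs: ``dyad,conversation,cutoff_a,cutoff_b,cutoff_dyad``;
* CRQA parameters: ``dyad,conversation,delay,dimension,radius``;
* DRPs (long): ``dyad,conversation,conv_type,task,source,surrogate_id,lag,rr``;
* model coefficients: ``model,term,estimate,se,t,p``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import AccelTrace, MovementSeries

__all__ = [
    "read_movement_csv",
    "write_movement_csv",
    "write_series_csv",
    "read_series_csv",
    "read_metadata_csv",
    "write_metadata_csv",
]

PathLike = Union[str, Path]

_RAW_COLS = ["t_s", "x", "y", "z"]


def read_movement_csv(
    path: PathLike, participant: str = "", conversation: str = ""
) -> AccelTrace:
    """Read a raw ``t_s,x,y,z`` trace with strict validation.

    Extra columns are tolerated (with a warning) and ignored; missing
    required columns or non-monotone timestamps raise, naming the
    offending column/row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _RAW_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _RAW_COLS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: timestamps not strictly increasing at row {row + 1}")
        rate = 1.0 / float(np.median(dt))
    else:
        rate = 250.0
    return AccelTrace(
        t, df["x"].to_numpy(float), df["y"].to_numpy(float), df["z"].to_numpy(float),
        participant=participant or Path(path).stem, conversation=conversation,
        sample_rate_hz=rate,
    )


def write_movement_csv(trace: AccelTrace, path: PathLike) -> None:
    pd.DataFrame(
        {"t_s": trace.t, "x": trace.x, "y": trace.y, "z": trace.z}
    ).to_csv(path, index=False, float_format="%.6f")


def write_series_csv(series: MovementSeries, path: PathLike) -> None:
    pd.DataFrame({"t_s": series.t, "a": series.a}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_series_csv(path: PathLike, rate_hz: float = 10.0) -> MovementSeries:
    df = pd.read_csv(path)
    if not {"t_s", "a"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t_s,a")
    return MovementSeries(
        df["t_s"].to_numpy(float), df["a"].to_numpy(float), rate_hz=rate_hz,
        filtered=True, smoothed=True, trimmed=True,
    )


_META_COLS = ["dyad", "conversation", "conv_type", "conv_order", "task", "file_a", "file_b"]


def read_metadata_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return df


def write_metadata_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, columns=_META_COLS)
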
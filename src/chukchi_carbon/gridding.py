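"""Daily quarter-degree reduction of underway surface tracks.

Shipboard underway systems log every few minutes, so a slow transit through
a small area would otherwise dominate any regional statistic.  Records are
therefore averaged into daily 0.25 deg latitude x 0.25 deg longitude cells
before any flux or decomposition work.  Bins are half-open ``[k*0.25,
(k+1)*0.25)`` anchored at 0 deg, and the day boundary is UTC midnight
(integer day-of-year).

Missing values are dropped per variable: a record with no salinity still
contributes to the cell's pCO2 mean.  ``n_obs`` counts member records (with
finite time and position), so the total over cells equals the number of
usable input records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["BIN_DEG", "grid_daily"]

BIN_DEG = 0.25

#: Variables averaged within each cell (input column -> output column).
_MEAN_VARS = {"sst": "mean_sst", "sss": "mean_sss", "pco2": "mean_pco2"}


def grid_daily(records: pd.DataFrame) -> pd.DataFrame:
    """Average underway records into daily quarter-degree cells.

    Parameters
    ----------
    records : DataFrame
        Columns ``time`` (decimal day of year), ``lat``, ``lon`` (degE,
        west negative), ``sst``, ``sss``, ``pco2``.

    Returns
    -------
    DataFrame with one row per (day, lat_bin, lon_bin): bin indices, bin
    center coordinates, per-variable means, and ``n_obs``.
    """
    required = {"time", "lat", "lon"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if len(records) == 0:
        return pd.DataFrame(columns=["day", "lat_bin", "lon_bin", "lat", "lon",
                                     *_MEAN_VARS.values(), "n_obs"])

    df = records.copy()
    usable = np.isfinite(df["time"]) & np.isfinite(df["lat"]) & np.isfinite(df["lon"])
    df = df[usable]

    df["day"] = np.floor(df["time"]).astype(int)
    df["lat_bin"] = np.floor(df["lat"] / BIN_DEG).astype(int)
    df["lon_bin"] = np.floor(df["lon"] / BIN_DEG).astype(int)

    agg = {out: (src, "mean") for src, out in _MEAN_VARS.items() if src in df.columns}
    grouped = (df.groupby(["day", "lat_bin", "lon_bin"])
                 .agg(n_obs=("time", "size"), **agg)
                 .reset_index())
    grouped["lat"] = (grouped["lat_bin"] + 0.5) * BIN_DEG
    grouped["lon"] = (grouped["lon_bin"] + 0.5) * BIN_DEG
    cols = ["day", "lat_bin", "lon_bin", "lat", "lon",
            *[c for c in _MEAN_VARS.values() if c in grouped.columns], "n_obs"]
    return grouped[cols]
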
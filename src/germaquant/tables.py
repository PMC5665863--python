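"""The per-cell table: one row per detected nucleus.

This is the record behind every plotted dot: position, core radius, per-
channel raw / background-subtracted / normalized intensities, AP position,
region, clone label, QC flags, depth band and sample id.  Stored as a
plain pandas DataFrame in a fixed, documented column order; CSV (UTF-8,
comma separator, '.' decimal) is the single on-disk dialect, chosen for
bit-stable round trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGIONS = ["R1", "R2a", "R2b_A", "R2b_P", "R3_S1", "S2plus", "unassigned"]
CLONE_LABELS = ["control", "mutant", "unassigned"]
DEPTH_BANDS = ["top", "middle", "bottom", "unassigned"]

# fixed leading columns; per-channel intensity columns follow in channel
# order as <ch>_raw, <ch>_bgsub, <ch>_norm; trailing metadata last
LEADING = ["cell_id", "z_um", "y_um", "x_um", "core_radius_um"]
TRAILING = ["ap_um", "region", "clone", "qc", "depth_band", "sample_id"]


class TableIntegrityError(ValueError):
    pass


def new_cell_table(channels: list[str]) -> pd.DataFrame:
    cols = list(LEADING)
    for ch in channels:
        cols += [f"{ch}_raw", f"{ch}_bgsub", f"{ch}_norm"]
    cols += TRAILING
    return pd.DataFrame({c: pd.Series(dtype=_dtype(c)) for c in cols})


def _dtype(col: str):
    if col in ("cell_id",):
        return np.int64
    if col in ("region", "clone", "qc", "depth_band", "sample_id"):
        return object
    return float


def column_order(table: pd.DataFrame) -> list[str]:
    chans = channels_of(table)
    cols = list(LEADING)
    for ch in chans:
        cols += [f"{ch}_raw", f"{ch}_bgsub", f"{ch}_norm"]
    return cols + TRAILING


def channels_of(table: pd.DataFrame) -> list[str]:
    return [c[:-4] for c in table.columns if c.endswith("_raw")]


def validate_cell_table(table: pd.DataFrame) -> None:
    for sample, sub in table.groupby("sample_id", dropna=False):
        if sub["cell_id"].duplicated().any():
            raise TableIntegrityError(f"duplicate cell_id in sample {sample!r}")
    for ch in channels_of(table):
        bad = table[f"{ch}_bgsub"] < -1e-12
        if bad.any():
            raise TableIntegrityError(f"negative background-subtracted values in {ch}")


def write_cell_table(path, table: pd.DataFrame) -> None:
    validate_cell_table(table)
    table[column_order(table)].to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"qc": object, "sample_id": object})
    if "qc" in table.columns:
        table["qc"] = table["qc"].fillna("")
    validate_cell_table(table)
    return table
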
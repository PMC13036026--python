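"""File formats: spot tables (CSV), volumes (multi-page TIFF + spacing sidecar).

Spot tables are plain pandas DataFrames with world-micrometre coordinates.
Columns: x_um, y_um, z_um, intensity, source, score, is_cell, region_id,
region_acronym.  Unknown fields are left empty (NaN / empty string);
region_id 0 means unassigned.  Arrays are ordered (z, y, x) throughout, with
z the anterior-posterior axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SPOT_COLUMNS",
    "empty_spots",
    "make_spots",
    "read_spots",
    "write_spots",
    "read_volume",
    "write_volume",
    "spot_coords",
]

SPOT_COLUMNS = [
    "x_um",
    "y_um",
    "z_um",
    "intensity",
    "source",
    "score",
    "is_cell",
    "region_id",
    "region_acronym",
]


def empty_spots() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "intensity": pd.Series(dtype=float),
            "source": pd.Series(dtype=object),
            "score": pd.Series(dtype=float),
            "is_cell": pd.Series(dtype=object),
            "region_id": pd.Series(dtype=int),
            "region_acronym": pd.Series(dtype=object),
        }
    )


def make_spots(
    coords_um: np.ndarray,
    intensity: np.ndarray | float = np.nan,
    source: str = "truth",
    region_id: np.ndarray | int = 0,
) -> pd.DataFrame:
    """Build a spot table from an (n, 3) array of (z, y, x) µm coordinates."""
    coords_um = np.atleast_2d(np.asarray(coords_um, dtype=float))
    if coords_um.size == 0:
        return empty_spots()
    if coords_um.shape[1] != 3:
        raise ValueError("coords_um must be (n, 3) ordered (z, y, x)")
    n = len(coords_um)
    out = pd.DataFrame(
        {
            "x_um": coords_um[:, 2],
            "y_um": coords_um[:, 1],
            "z_um": coords_um[:, 0],
            "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), n).copy(),
            "source": source,
            "score": np.nan,
            "is_cell": None,
            "region_id": np.broadcast_to(np.asarray(region_id, dtype=int), n).copy(),
            "region_acronym": "",
        }
    )
    return out


def spot_coords(spots: pd.DataFrame) -> np.ndarray:
    """(n, 3) array of (z, y, x) world-µm coordinates."""
    if len(spots) == 0:
        return np.empty((0, 3), dtype=float)
    return spots[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)


def write_spots(spots: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SPOT_COLUMNS if c in spots.columns]
    extra = [c for c in spots.columns if c not in SPOT_COLUMNS]
    spots[cols + extra].to_csv(path, index=False, float_format="%.6g")


def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "z_um", "intensity", "score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "region_id" in df.columns:
        df["region_id"] = df["region_id"].fillna(0).astype(int)
    if "region_acronym" in df.columns:
        df["region_acronym"] = df["region_acronym"].fillna("")
    return df


def write_volume(volume: np.ndarray, path: str | Path, spacing_um) -> None:
    """Multi-page 32-bit float TIFF with a ``<stem>.spacing.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
    sidecar = path.with_suffix(path.suffix + ".spacing.json")
    with open(sidecar, "w") as fh:
        json.dump({"spacing_um": [float(s) for s in spacing_um], "axis_order": "zyx"}, fh)
        fh.write("\n")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    volume = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".spacing.json")
    with open(sidecar) as fh:
        spacing = tuple(json.load(fh)["spacing_um"])
    return volume, spacing  # type: ignore[return-value]
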
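"""Spot-to-atlas mapping, regional aggregation and cohort heatmaps.

A deformation field (the output of nonlinear registration) maps sample world
coordinates into atlas world coordinates by adding a trilinearly interpolated
displacement.  Mapped cells are assigned the atlas parcellation at their
nearest voxel, aggregated into per-structure counts and densities
(cells/mm^3, count over structure volume), and arranged into the wide-format
density matrix used for cohort statistics.  All arrays are (z, y, x) with z
the anterior-posterior axis; all distances are world micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter, map_coordinates

from .atlas import AtlasBundle, Ontology

__all__ = [
    "DeformationField",
    "transform_spots",
    "assign_regions",
    "aggregate",
    "build_density_matrix",
    "coronal_heatmaps",
]

META_COLUMNS = ["animal_id", "treatment", "time", "sex"]


@dataclass
class DeformationField:
    """Gridded displacements (µm) from sample space to atlas space.

    ``displacements`` has shape (nz, ny, nx, 3) ordered (dz, dy, dx); grid
    node ``(i, j, k)`` sits at world position ``(i, j, k) * grid_spacing_um``.
    The mapped position of a point is point + displacement(point).
    The inverse direction (atlas to sample) is not supported.
    """

    displacements: np.ndarray
    grid_spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (nz, ny, nx, 3)")
        if any(n < 2 for n in self.displacements.shape[:3]):
            raise ValueError(
                f"degenerate grid {self.displacements.shape[:3]}: every axis needs >= 2 nodes"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements contain non-finite values")
        self.grid_spacing_um = tuple(float(g) for g in self.grid_spacing_um)  # type: ignore[assignment]
        if any(g <= 0 for g in self.grid_spacing_um):
            raise ValueError("grid_spacing_um must be positive")

    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            (n - 1) * g
            for n, g in zip(self.displacements.shape[:3], self.grid_spacing_um)
        )  # type: ignore[return-value]

    def displacement_at(self, points_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear displacement at (n, 3) world points; also out-of-grid flags.

        Points beyond the grid are clamped to the nearest border node rather
        than dropped (registration edges are imperfect; silent dropping would
        bias border regions), and flagged.
        """
        points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
        grid = np.asarray(self.grid_spacing_um)
        idx = points_um / grid  # fractional grid coordinates
        n = np.asarray(self.displacements.shape[:3])
        out_of_grid = np.any((idx < 0) | (idx > (n - 1)), axis=1)
        idx = np.clip(idx, 0, (n - 1))
        disp = np.empty_like(points_um)
        for c in range(3):
            disp[:, c] = map_coordinates(
                self.displacements[..., c], idx.T, order=1, mode="nearest"
            )
        return disp, out_of_grid

    # -- persistence: multi-page float TIFF + sidecar JSON -----------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.displacements.astype(np.float32))
        with open(path.with_suffix(path.suffix + ".grid.json"), "w") as fh:
            json.dump(
                {
                    "grid_spacing_um": list(self.grid_spacing_um),
                    "axis_order": "zyx",
                    "channel_order": "dz,dy,dx",
                },
                fh,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        path = Path(path)
        disp = tifffile.imread(path)
        with open(path.with_suffix(path.suffix + ".grid.json")) as fh:
            grid = tuple(json.load(fh)["grid_spacing_um"])
        return cls(displacements=disp, grid_spacing_um=grid)  # type: ignore[arg-type]


def transform_spots(spots: pd.DataFrame, field: DeformationField) -> pd.DataFrame:
    """Push sample-space spots into atlas space through the deformation field."""
    out = spots.copy()
    if len(spots) == 0:
        out["out_of_grid"] = pd.Series(dtype=bool)
        return out
    pts = out[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    disp, oog = field.displacement_at(pts)
    mapped = pts + disp
    out["z_um"] = mapped[:, 0]
    out["y_um"] = mapped[:, 1]
    out["x_um"] = mapped[:, 2]
    out["out_of_grid"] = oog
    return out


def assign_regions(spots: pd.DataFrame, atlas: AtlasBundle) -> pd.DataFrame:
    """Label each atlas-space spot with the parcellation at its nearest voxel.

    Background (label 0) or out-of-volume positions stay unassigned
    (region_id 0): they count in whole-brain totals but are excluded from
    region statistics.  Hemispheres share labels by atlas construction, so
    left/right counterparts combine automatically.
    """
    out = spots.copy()
    if len(spots) == 0:
        out["region_id"] = pd.Series(dtype=int)
        out["region_acronym"] = pd.Series(dtype=object)
        return out
    spacing = np.asarray(atlas.spacing_um)
    vox = np.rint(
        out[["z_um", "y_um", "x_um"]].to_numpy(dtype=float) / spacing
    ).astype(int)
    shape = np.asarray(atlas.label_volume.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    region = np.zeros(len(out), dtype=int)
    iv = vox[inside]
    region[inside] = atlas.label_volume[iv[:, 0], iv[:, 1], iv[:, 2]]
    out["region_id"] = region
    acronyms = {sid: atlas.ontology[sid].acronym for sid in set(region) if sid != 0}
    out["region_acronym"] = [acronyms.get(r, "") for r in region]
    return out


def aggregate(
    spots: pd.DataFrame,
    ontology: Ontology,
    gray_only: bool = False,
) -> pd.DataFrame:
    """Per-structure counts and densities for one brain.

    ``direct_count`` counts spots whose voxel label is exactly the structure;
    ``cumulative_count`` adds all descendants (a parent's count contains its
    children's).  ``density`` is cumulative count over the structure's
    annotated volume (cells/mm^3).  Unassigned spots (region_id 0) are
    excluded.  Indexed by structure id in depth-first ontology order.
    """
    assigned = spots[spots["region_id"] != 0] if len(spots) else spots
    if len(assigned):
        unknown = sorted(set(assigned["region_id"]) - set(ontology.ids()))
        if unknown:
            raise KeyError(f"spots labeled with unknown structure ids: {unknown}")
        direct = assigned["region_id"].value_counts().to_dict()
    else:
        direct = {}

    order = ontology.depth_first_ids()
    rows = []
    for sid in order:
        s = ontology[sid]
        if gray_only and not s.is_gray_matter:
            continue
        cum = direct.get(sid, 0) + sum(
            direct.get(d, 0) for d in ontology.descendants(sid)
        )
        density = cum / s.volume_mm3 if s.volume_mm3 > 0 else 0.0
        rows.append(
            {
                "region_id": sid,
                "acronym": s.acronym,
                "direct_count": int(direct.get(sid, 0)),
                "cumulative_count": int(cum),
                "volume_mm3": s.volume_mm3,
                "density": density,
            }
        )
    return pd.DataFrame(rows).set_index("region_id")


def build_density_matrix(
    counts: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    ontology: Ontology,
) -> pd.DataFrame:
    """Arrange per-animal region counts into the wide cohort table.

    ``counts`` maps animal_id -> the output of :func:`aggregate`;
    ``metadata`` carries one row per animal with treatment/time/sex labels.
    Columns follow depth-first ontology order; a region absent from an
    animal's table means no detected spots there and becomes density 0,
    never a missing value.
    """
    meta = metadata.copy()
    if meta["animal_id"].duplicated().any():
        dup = sorted(meta.loc[meta["animal_id"].duplicated(), "animal_id"])
        raise ValueError(f"duplicate animal_id in metadata: {dup}")
    missing = set(counts) - set(meta["animal_id"])
    if missing:
        raise ValueError(f"animals without metadata: {sorted(missing)}")

    order = ontology.depth_first_ids()
    acr = [ontology[sid].acronym for sid in order]
    rows = []
    for _, m in meta.iterrows():
        aid = m["animal_id"]
        table = counts.get(aid)
        dens = (
            table["density"].reindex(order).fillna(0.0).to_numpy()
            if table is not None
            else np.zeros(len(order))
        )
        row = {c: m[c] for c in META_COLUMNS}
        row.update(dict(zip(acr, dens)))
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + acr)


def coronal_heatmaps(
    spots: pd.DataFrame,
    atlas: AtlasBundle,
    n_animals: int,
    slab_um: float = 1000.0,
    sigma_um: float = 100.0,
) -> list[np.ndarray]:
    """Group-average coronal density maps.

    The anterior-posterior axis is partitioned into slabs of ``slab_um``;
    each slab is a 2-D histogram of spot (dorsoventral, mediolateral)
    positions at atlas voxel resolution, divided by the number of animals in
    the group, then Gaussian-smoothed with ``sigma_um`` (0 disables
    smoothing).  Before smoothing, each map sums exactly to
    (spots in slab) / n_animals.
    """
    if slab_um <= 0:
        raise ValueError("slab_um must be positive")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    nz, ny, nx = atlas.label_volume.shape
    sz, sy, sx = atlas.spacing_um
    extent_z = nz * sz
    n_slabs = max(1, int(np.ceil(extent_z / slab_um)))

    maps = [np.zeros((ny, nx), dtype=float) for _ in range(n_slabs)]
    if len(spots):
        z = spots["z_um"].to_numpy(dtype=float)
        y = spots["y_um"].to_numpy(dtype=float)
        x = spots["x_um"].to_numpy(dtype=float)
        slab = np.clip((z // slab_um).astype(int), 0, n_slabs - 1)
        iy = np.clip(np.rint(y / sy).astype(int), 0, ny - 1)
        ix = np.clip(np.rint(x / sx).astype(int), 0, nx - 1)
        for s, j, k in zip(slab, iy, ix):
            maps[s][j, k] += 1.0
    maps = [m / n_animals for m in maps]
    if sigma_um > 0:
        sig = (sigma_um / sy, sigma_um / sx)
        maps = [gaussian_filter(m, sigma=sig, mode="constant") for m in maps]
    return maps
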
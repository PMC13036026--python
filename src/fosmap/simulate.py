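"""Synthetic phantoms: toy atlases, fluorescence volumes and cohorts.

The generators emulate the substrate of a cleared-brain c-Fos experiment at
desk scale: a hemisphere-symmetric hierarchical atlas, 3-D volumes carrying
PSF-blurred Gaussian puncta of varying size and intensity over a tissue
background (plus the three artifact classes seen in cleared-tissue data —
bright edge planes, autofluorescent vessel tubes and single-voxel noise
spikes), and multi-animal cohorts with a treatment x time x sex factorial
design and region-specific standardized effects injected on the density
scale.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasBundle, Ontology, Structure
from .io import make_spots
from .mapping import DeformationField

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "DEFAULT_GROUPS",
    "make_toy_atlas",
    "simulate_volume",
    "simulate_cohort",
    "simulate_deformation",
    "true_contrasts",
]

#: factorial cohort: (treatment, time, sex, n_animals); total N = 27
#: (15 males, 12 females) split over the 8 treatment x time x sex cells
DEFAULT_GROUPS: tuple[tuple[str, str, str, int], ...] = (
    ("morphine", "1h", "male", 5),
    ("morphine", "1h", "female", 3),
    ("morphine", "4h", "male", 4),
    ("morphine", "4h", "female", 3),
    ("saline", "1h", "male", 3),
    ("saline", "1h", "female", 2),
    ("saline", "4h", "male", 3),
    ("saline", "4h", "female", 4),
)

#: metadata columns of a wide-format density matrix
META_COLUMNS = ["animal_id", "treatment", "time", "sex"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic fluorescence volume.

    Spacing defaults to the anisotropic confocal voxel pitch
    (5.33, 0.361, 0.361) µm in (z, y, x).  ``puncta_sigma_um`` is the
    PSF-convolved Gaussian width of a punctum; amplitudes and widths are
    jittered per punctum to mimic cells of different sizes and intensities.
    ``region_rates`` maps atlas region id -> homogeneous Poisson intensity in
    cells/mm^3.
    """

    shape_vox: tuple[int, int, int] = (100, 512, 512)
    spacing_um: tuple[float, float, float] = (5.33, 0.361, 0.361)
    puncta_sigma_um: tuple[float, float, float] = (3.0, 1.5, 1.5)
    puncta_amplitude: float = 100.0
    background_level: float = 20.0
    noise_sd: float = 10.0
    artifact_spec: Mapping[str, int] = field(
        default_factory=lambda: {"edge_plane": 0, "vessel_tube": 0, "noise_spike": 0}
    )
    region_rates: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape_vox):
            raise ValueError(f"shape_vox must be >= 16 per axis, got {self.shape_vox}")
        if any(s <= 0 for s in self.puncta_sigma_um):
            raise ValueError("puncta_sigma_um must be positive")
        if any(r < 0 for r in self.region_rates.values()):
            raise ValueError("region rates must be non-negative")


@dataclass
class CohortSpec:
    """Generative counterpart of the factorial mixed model.

    Per animal a mouse intercept u ~ N(0, sigma_mouse^2) is shared across
    regions; per region the density is

        baseline + total_sd * (d_treat * I[morphine]
                               + d_treat_time * I[morphine & 4h]
                               + d_treat_sex  * I[morphine & female])
                 + u + N(0, sigma_resid^2)

    with total_sd = sqrt(sigma_mouse^2 + sigma_resid^2), so the injected d's
    ARE the standardized effects (Cohen's d) the analysis should recover.
    """

    groups: Sequence[tuple[str, str, str, int]] = DEFAULT_GROUPS
    baseline_density: Mapping[str, float] = field(default_factory=dict)
    effect_map: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    sigma_mouse: float = 40.0
    sigma_resid: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort has no groups")
        for g in self.groups:
            if g[3] < 1:
                raise ValueError(f"group {g[:3]} has n_animals < 1")
        if self.sigma_mouse < 0 or self.sigma_resid < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.sigma_mouse, self.sigma_resid))


# -- toy atlas -------------------------------------------------------------

def make_toy_atlas(
    n_regions: int,
    shape_vox: tuple[int, int, int] = (64, 64, 64),
    spacing_um: tuple[float, float, float] = (10.0, 10.0, 10.0),
    seed: int = 0,
) -> AtlasBundle:
    """Build a mirror-symmetric 3-level toy atlas.

    A tissue block (leaving a small background margin on every face) is split
    along the anterior-posterior axis into ``n_regions`` leaf slabs with
    seeded random boundaries; leaves are grouped into lobes under a single
    root.  Left and right hemispheres share the same labels (slabs span the
    full medio-lateral axis), and all ontology volumes are computed exactly
    from voxel counts times the voxel volume.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    shape = tuple(int(n) for n in shape_vox)
    nz, ny, nx = shape
    margin = tuple(max(2, n // 12) for n in shape)
    z0, z1 = margin[0], nz - margin[0]
    y0, y1 = margin[1], ny - margin[1]
    x0, x1 = margin[2], nx - margin[2]
    span = z1 - z0
    if span < 2 * n_regions:
        raise ValueError(
            f"shape {shape} too small to host {n_regions} regions "
            f"(needs >= 2 voxels per region along z after margins)"
        )

    rng = np.random.default_rng(seed)
    # random slab boundaries with at least 2 voxels per slab
    slack = span - 2 * n_regions
    cuts = np.sort(rng.choice(slack + 1, size=n_regions - 1, replace=True))
    bounds = [z0]
    for i, c in enumerate(cuts):
        bounds.append(z0 + 2 * (i + 1) + int(c))
    bounds.append(z1)

    labels = np.zeros(shape, dtype=np.uint32)
    leaf_ids = [100 + j for j in range(n_regions)]
    for j, lid in enumerate(leaf_ids):
        labels[bounds[j] : bounds[j + 1], y0:y1, x0:x1] = lid

    voxel_mm3 = float(np.prod(spacing_um)) * 1e-9
    n_lobes = max(2, int(np.round(np.sqrt(n_regions))))
    n_lobes = min(n_lobes, n_regions)
    lobe_of = [min(j * n_lobes // n_regions, n_lobes - 1) for j in range(n_regions)]

    # volumes derived from integer voxel counts, multiplied by the voxel
    # volume once per structure so parent volumes equal child sums exactly
    structures = []
    leaf_counts = []
    for j, lid in enumerate(leaf_ids):
        count = (bounds[j + 1] - bounds[j]) * (y1 - y0) * (x1 - x0)
        leaf_counts.append(count)
        structures.append(
            Structure(
                id=lid,
                acronym=f"R{j:02d}",
                name=f"toy region {j}",
                parent_id=10 + lobe_of[j],
                volume_mm3=count * voxel_mm3,
            )
        )
    lobe_counts = [0] * n_lobes
    for j, count in enumerate(leaf_counts):
        lobe_counts[lobe_of[j]] += count
    for i in range(n_lobes):
        structures.append(
            Structure(
                id=10 + i,
                acronym=f"LB{i}",
                name=f"toy lobe {i}",
                parent_id=1,
                volume_mm3=lobe_counts[i] * voxel_mm3,
            )
        )
    structures.append(
        Structure(
            id=1,
            acronym="BR",
            name="toy brain root",
            parent_id=None,
            volume_mm3=sum(leaf_counts) * voxel_mm3,
        )
    )
    return AtlasBundle(
        ontology=Ontology(structures),
        label_volume=labels,
        spacing_um=tuple(float(s) for s in spacing_um),
    )


# -- volume phantom --------------------------------------------------------

def _render_blob(volume, center_vox, sigma_vox, amplitude) -> None:
    """Add an anisotropic Gaussian blob in place (4-sigma support box)."""
    shape = volume.shape
    lo = [max(0, int(np.floor(c - 4 * s)) ) for c, s in zip(center_vox, sigma_vox)]
    hi = [min(n, int(np.ceil(c + 4 * s)) + 1) for n, c, s in zip(shape, center_vox, sigma_vox)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = (np.arange(lo[0], hi[0]) - center_vox[0]) / sigma_vox[0]
    yy = (np.arange(lo[1], hi[1]) - center_vox[1]) / sigma_vox[1]
    xx = (np.arange(lo[2], hi[2]) - center_vox[2]) / sigma_vox[2]
    g = np.exp(
        -0.5
        * (
            zz[:, None, None] ** 2
            + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2
        )
    )
    volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (amplitude * g).astype(
        volume.dtype
    )


def simulate_volume(
    atlas: AtlasBundle, spec: PhantomSpec, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a phantom volume and its ground-truth spot table.

    Puncta counts per region are Poisson(rate x region volume in mm^3);
    centers are uniform over the region's voxels with sub-voxel jitter.
    World coordinates are voxel index x spacing (origin at the first voxel
    center).  Artifacts are rendered per ``spec.artifact_spec`` and are NOT
    listed in the truth table.
    """
    unknown = [rid for rid in spec.region_rates if rid not in atlas.ontology]
    if unknown:
        raise KeyError(f"region_rates ids not in atlas ontology: {unknown}")
    if tuple(atlas.label_volume.shape) != tuple(spec.shape_vox):
        raise ValueError(
            f"atlas labels {atlas.label_volume.shape} != spec shape {tuple(spec.shape_vox)}"
        )

    rng = np.random.default_rng(seed)
    spacing = np.asarray(spec.spacing_um, dtype=float)
    labels = atlas.label_volume
    volume = np.zeros(labels.shape, dtype=np.float32)

    # tissue autofluorescence background: bright inside the annotated block,
    # dim outside (mounting medium)
    tissue = labels > 0
    volume += np.where(tissue, spec.background_level, 0.1 * spec.background_level).astype(
        np.float32
    )

    voxel_mm3 = float(np.prod(spacing)) * 1e-9
    sigma_vox = np.asarray(spec.puncta_sigma_um) / spacing

    centers = []
    regions = []
    amps = []
    flat_labels = labels.ravel()
    for rid in sorted(spec.region_rates):
        rate = spec.region_rates[rid]
        idx = np.flatnonzero(flat_labels == rid)
        if idx.size == 0 or rate == 0:
            continue
        vol_mm3 = idx.size * voxel_mm3
        count = rng.poisson(rate * vol_mm3)
        if count == 0:
            continue
        chosen = rng.choice(idx, size=count, replace=True)
        vox = np.stack(np.unravel_index(chosen, labels.shape), axis=1).astype(float)
        vox += rng.uniform(-0.5, 0.5, size=vox.shape)
        for v in vox:
            amp = spec.puncta_amplitude * rng.uniform(0.6, 1.5)
            size = rng.uniform(0.8, 1.25)
            _render_blob(volume, v, sigma_vox * size, amp)
            centers.append(v * spacing)
            regions.append(rid)
            amps.append(amp)

    # artifacts -----------------------------------------------------------
    art = dict(spec.artifact_spec)
    bright = np.float32(1.5 * spec.puncta_amplitude)
    # tissue bounding box (cheap axis projections) for placing interior artifacts
    bbox = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        proj = np.flatnonzero(tissue.any(axis=other))
        bbox.append((int(proj[0]), int(proj[-1])) if proj.size else (0, labels.shape[axis] - 1))

    def _tissue_point() -> tuple[int, int, int]:
        return tuple(int(rng.integers(lo, hi + 1)) for lo, hi in bbox)  # type: ignore[return-value]

    for _ in range(int(art.get("edge_plane", 0))):
        axis = int(rng.integers(3))
        side = int(rng.integers(2))
        sl: list[object] = [slice(None)] * 3
        sl[axis] = -1 if side else 0
        volume[tuple(sl)] += bright
    for _ in range(int(art.get("vessel_tube", 0))):
        # bright cylinder, radius 2 um in world units, running along one axis
        # through the tissue block
        axis = int(rng.integers(3))
        other = [a for a in range(3) if a != axis]
        p = _tissue_point()
        coords = [
            (np.arange(labels.shape[a]) - p[a]) * spacing[a] for a in other
        ]
        d2 = coords[0][:, None] ** 2 + coords[1][None, :] ** 2
        disk = (d2 <= 2.0**2).astype(np.float32)
        if not disk.any():  # radius below the voxel pitch: keep a 1-voxel core
            disk[p[other[0]], p[other[1]]] = 1.0
        if axis == 0:
            volume += 0.8 * bright * disk[None, :, :]
        elif axis == 1:
            volume += 0.8 * bright * disk[:, None, :]
        else:
            volume += 0.8 * bright * disk[:, :, None]
    for _ in range(int(art.get("noise_spike", 0))):
        volume[_tissue_point()] += np.float32(3.0 * spec.puncta_amplitude)

    if spec.noise_sd > 0:
        volume += rng.standard_normal(volume.shape, dtype=np.float32) * np.float32(
            spec.noise_sd
        )

    if centers:
        truth = make_spots(
            np.asarray(centers), intensity=np.asarray(amps), source="truth",
            region_id=np.asarray(regions, dtype=int),
        )
        acr = {rid: atlas.ontology[rid].acronym for rid in set(regions)}
        truth["region_acronym"] = [acr[r] for r in regions]
    else:
        truth = make_spots(np.empty((0, 3)))
    return volume, truth


# -- cohort ----------------------------------------------------------------

def _default_regions(atlas: AtlasBundle) -> list[str]:
    return [atlas.ontology[i].acronym for i in atlas.ontology.leaves()]


def simulate_cohort(
    atlas: AtlasBundle, cohort: CohortSpec
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Draw a wide-format density matrix plus the true standardized effects.

    Returns ``(dm, truth)`` where ``dm`` has one row per animal (columns:
    animal_id, treatment, time, sex, then one density column per region
    acronym) and ``truth`` maps region -> contrast -> true Cohen's d.
    Negative densities are clipped at zero with a warning.
    """
    rng = np.random.default_rng(cohort.seed)
    regions = (
        sorted(cohort.baseline_density)
        if cohort.baseline_density
        else _default_regions(atlas)
    )
    baseline = {r: float(cohort.baseline_density.get(r, 200.0)) for r in regions}
    sd_total = cohort.total_sd

    rows = []
    clipped = 0
    counter = 0
    for treatment, time, sex, n in cohort.groups:
        for k in range(n):
            counter += 1
            animal = f"{treatment[0].upper()}-{time}-{sex[0]}-{k + 1}"
            u = rng.normal(0.0, cohort.sigma_mouse)
            row: dict[str, object] = {
                "animal_id": animal,
                "treatment": treatment,
                "time": time,
                "sex": sex,
            }
            is_m = treatment == "morphine"
            for r in regions:
                d_t, d_tt, d_ts = cohort.effect_map.get(r, (0.0, 0.0, 0.0))
                shift = 0.0
                if is_m:
                    shift += d_t
                    if time == "4h":
                        shift += d_tt
                    if sex == "female":
                        shift += d_ts
                dens = (
                    baseline[r]
                    + sd_total * shift
                    + u
                    + rng.normal(0.0, cohort.sigma_resid)
                )
                if dens < 0:
                    dens = 0.0
                    clipped += 1
                row[r] = dens
            rows.append(row)
    if clipped:
        warnings.warn(
            f"clipped {clipped} negative simulated densities at 0", stacklevel=2
        )
    dm = pd.DataFrame(rows, columns=META_COLUMNS + regions)

    truth = {}
    for r in regions:
        d_t, d_tt, d_ts = cohort.effect_map.get(r, (0.0, 0.0, 0.0))
        truth[r] = true_contrasts(d_t, d_tt, d_ts)
    return dm, truth


def true_contrasts(d_t: float, d_tt: float, d_ts: float) -> dict[str, float]:
    """True standardized effects per contrast implied by the injected d's."""
    return {
        "treat@M1h": d_t,
        "treat@F1h": d_t + d_ts,
        "treat@M4h": d_t + d_tt,
        "treat@F4h": d_t + d_tt + d_ts,
        "treat:time@M": d_tt,
        "treat:time@F": d_tt,
        "treat:sex@1h": d_ts,
        "treat:sex@4h": d_ts,
    }


# -- deformation fixtures --------------------------------------------------

def simulate_deformation(
    atlas: AtlasBundle,
    mode: str = "identity",
    magnitude_um: float = 0.0,
    seed: int = 0,
    grid_spacing_um: tuple[float, float, float] | None = None,
) -> DeformationField:
    """Synthetic registration output covering the atlas extent.

    ``identity`` is all-zero; ``translation`` is a constant (dz, dy, dx) =
    (magnitude, 0, 0); ``smooth_warp`` is a seeded low-frequency random field
    with maximum displacement norm exactly ``magnitude_um``.
    """
    if magnitude_um < 0:
        raise ValueError("magnitude_um must be >= 0")
    extent = atlas.extent_um()
    if grid_spacing_um is None:
        grid_spacing_um = tuple(e / 8 for e in extent)
    shape = tuple(int(np.ceil(e / g)) + 1 for e, g in zip(extent, grid_spacing_um))
    shape = tuple(max(2, n) for n in shape)

    if mode == "identity":
        disp = np.zeros(shape + (3,), dtype=float)
    elif mode == "translation":
        disp = np.zeros(shape + (3,), dtype=float)
        disp[..., 0] = magnitude_um
    elif mode == "smooth_warp":
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        disp = rng.standard_normal(shape + (3,))
        for c in range(3):
            disp[..., c] = gaussian_filter(disp[..., c], sigma=1.5, mode="nearest")
        norms = np.sqrt((disp**2).sum(axis=-1))
        peak = norms.max()
        if peak > 0 and magnitude_um > 0:
            disp *= magnitude_um / peak
        else:
            disp[:] = 0.0
    else:
        raise ValueError(f"unknown deformation mode {mode!r}")
    return DeformationField(
        displacements=disp, grid_spacing_um=tuple(float(g) for g in grid_spacing_um)
    )
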
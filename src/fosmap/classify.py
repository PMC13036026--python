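"""Cell / non-cell discrimination of consolidated detections.

Consolidated spot lists still contain artifacts — bright edge planes,
autofluorescent vessels and single-voxel noise spikes.  Each spot is reduced
to a small vector of patch features designed to separate those classes
(edges concentrate their energy in one plane; vessels are strongly
anisotropic; spikes have anomalous peak-to-local-SD contrast) and scored by
a seeded random-forest binary classifier.  The workflow contract is
train / fine-tune / predict: a base model is trained once, and brains whose
validation F1 falls below the acceptance gate get the model fine-tuned on a
small set of locally annotated examples (new examples up-weighted rather
than retrained from scratch, so the base training is not forgotten).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .detection import match_spots
from .io import spot_coords

__all__ = [
    "FEATURE_NAMES",
    "SpotClassifier",
    "extract_features",
    "extract_feature_matrix",
    "train_classifier",
    "fine_tune",
    "classify_spots",
    "label_spots_by_truth",
]

FEATURE_NAMES = [
    "peak_intensity",
    "local_mean",
    "local_sd",
    "contrast_ratio",
    "anisotropy",
    "border_distance_um",
    "planarity",
    "elongation",
]

#: weight multiplier for fine-tuning examples: strong enough that 50-200
#: local annotations can move the decision boundary, small enough that the
#: base training set is not forgotten
FINE_TUNE_WEIGHT = 5.0


def extract_features(
    volume: np.ndarray,
    spacing_um,
    spot_um,
    patch_radius_um: float = 10.0,
) -> np.ndarray:
    """Deterministic patch features around one spot (z, y, x world µm).

    Features (in :data:`FEATURE_NAMES` order): core peak intensity, patch
    mean and SD, peak-to-annulus contrast ratio, second-moment anisotropy
    (sqrt of largest/smallest eigenvalue in µm^2; 1 for an isotropic blob),
    distance to the volume border (µm), and planarity (largest fraction of
    above-background patch energy concentrated in a single plane).
    Patches clipped by the volume border are allowed; the border distance
    feature carries that information.
    """
    spacing = np.asarray(spacing_um, dtype=float)
    spot_um = np.asarray(spot_um, dtype=float)
    shape = np.asarray(volume.shape)
    extent = shape * spacing
    if np.any(spot_um < -spacing) or np.any(spot_um > extent + spacing):
        raise ValueError(f"spot {spot_um} lies outside the volume (extent {extent} µm)")

    center_vox = spot_um / spacing
    radius_vox = np.maximum(1, np.ceil(patch_radius_um / spacing).astype(int))
    c = np.rint(center_vox).astype(int)
    lo = np.maximum(c - radius_vox, 0)
    hi = np.minimum(c + radius_vox + 1, shape)
    patch = np.asarray(
        volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]], dtype=float
    )

    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    pos_um = np.stack([g * s for g, s in zip(grids, spacing)], axis=-1)
    dist_um = np.sqrt(((pos_um - spot_um) ** 2).sum(axis=-1))

    core = patch[dist_um <= max(2.0, float(spacing.max()))]
    peak = float(core.max()) if core.size else float(patch.max())
    local_mean = float(patch.mean())
    local_sd = float(patch.std())

    annulus = patch[dist_um > 0.6 * patch_radius_um]
    bg = float(annulus.mean()) if annulus.size else local_mean
    eps = 1e-6 + 1e-3 * abs(peak)
    contrast_ratio = (peak - min(0.0, bg) + eps) / (bg - min(0.0, bg) + eps)

    w = np.clip(patch - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        anisotropy = 1.0
        planarity = 0.0
    else:
        mu = (w[..., None] * pos_um).reshape(-1, 3).sum(axis=0) / total
        d = pos_um - mu
        cov = np.einsum("zyx,zyxi,zyxj->ij", w, d, d) / total
        # regularize by the voxel second moment so a single-voxel spike has
        # finite, near-isotropic-in-voxel-units moments
        cov += np.diag(spacing**2 / 12.0)
        evals = np.linalg.eigvalsh(cov)
        anisotropy = float(np.sqrt(evals[-1] / max(evals[0], 1e-12)))
        planarity = 0.0
        for axis in range(3):
            other = tuple(a for a in range(3) if a != axis)
            plane_energy = w.sum(axis=other)
            planarity = max(planarity, float(plane_energy.max() / total))

    # elongation: a punctum decays to background at the patch ends along
    # every axis, while a vessel tube (or edge plane) stays bright in BOTH
    # directions along its own axis — the second-moment features miss this
    # when the annulus background estimate contains the structure itself
    c_local = c - lo
    ends = []
    for axis in range(3):
        probes = []
        for end in (0, patch.shape[axis] - 1):
            idx = list(c_local)
            idx[axis] = end
            idx = [int(np.clip(v, 0, s - 1)) for v, s in zip(idx, patch.shape)]
            probes.append(float(patch[tuple(idx)]))
        ends.append(min(probes))
    base = float(patch.min())
    elongation = (max(ends) - base) / max(peak - base, 1e-6)
    elongation = float(np.clip(elongation, 0.0, 1.0))

    border_distance_um = float(np.minimum(spot_um, extent - spot_um).min())
    return np.array(
        [peak, local_mean, local_sd, contrast_ratio, anisotropy,
         border_distance_um, planarity, elongation]
    )


def extract_feature_matrix(
    volume: np.ndarray,
    spacing_um,
    spots: pd.DataFrame,
    patch_radius_um: float = 10.0,
) -> np.ndarray:
    coords = spot_coords(spots)
    if len(coords) == 0:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.stack(
        [extract_features(volume, spacing_um, c, patch_radius_um) for c in coords]
    )


@dataclass
class SpotClassifier:
    """Fitted cell/non-cell model plus the manifest needed to refit it."""

    model: RandomForestClassifier
    decision_threshold: float = 0.5
    X_train: np.ndarray = field(default_factory=lambda: np.empty((0, len(FEATURE_NAMES))))
    y_train: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    w_train: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    @property
    def training_manifest(self) -> dict:
        y = np.asarray(self.y_train)
        return {
            "n_cell": int((y == 1).sum()),
            "n_non_cell": int((y == 0).sum()),
            "decision_threshold": self.decision_threshold,
            "feature_names": FEATURE_NAMES,
            "seed": self.seed,
        }

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of 'cell' for each feature row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.empty(0)
        proba = self.model.predict_proba(X)
        cell_col = list(self.model.classes_).index(1)
        return proba[:, cell_col]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "manifest": json.dumps(self.training_manifest),
                "model": self.model,
                "X_train": self.X_train,
                "y_train": self.y_train,
                "w_train": self.w_train,
                "decision_threshold": self.decision_threshold,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpotClassifier":
        blob = joblib.load(path)
        return cls(
            model=blob["model"],
            decision_threshold=blob["decision_threshold"],
            X_train=blob["X_train"],
            y_train=blob["y_train"],
            w_train=blob["w_train"],
            seed=blob["seed"],
        )


def _fit(X, y, w, seed) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=200, random_state=seed, n_jobs=1, class_weight=None
    )
    model.fit(X, y, sample_weight=w)
    return model


def train_classifier(
    features: np.ndarray,
    labels,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> SpotClassifier:
    """Fit the base cell/non-cell model (deterministic given the seed).

    ``labels`` may be booleans or the strings 'cell'/'non_cell'.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both cell and non-cell examples")
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    w = np.ones(len(y))
    model = _fit(X, y, w, seed)
    return SpotClassifier(
        model=model, decision_threshold=decision_threshold,
        X_train=X, y_train=y, w_train=w, seed=seed,
    )


def fine_tune(
    clf: SpotClassifier,
    extra_features: np.ndarray,
    extra_labels,
    seed: int | None = None,
) -> SpotClassifier:
    """Adapt a fitted model to a new brain with a few local annotations.

    Refits on the original manifest plus the extra examples, the extra
    examples weighted x5.  Returns a NEW classifier; the input model is
    untouched.  An empty extra set reproduces the original decisions.
    """
    seed = clf.seed if seed is None else seed
    Xe = np.atleast_2d(np.asarray(extra_features, dtype=float))
    if Xe.size == 0:
        model = _fit(clf.X_train, clf.y_train, clf.w_train, seed)
        return SpotClassifier(
            model=model, decision_threshold=clf.decision_threshold,
            X_train=clf.X_train.copy(), y_train=clf.y_train.copy(),
            w_train=clf.w_train.copy(), seed=seed,
        )
    ye = _as_binary(extra_labels)
    X = np.vstack([clf.X_train, Xe])
    y = np.concatenate([clf.y_train, ye])
    w = np.concatenate([clf.w_train, np.full(len(ye), FINE_TUNE_WEIGHT)])
    if len(np.unique(y)) < 2:
        raise ValueError("combined training set must contain both classes")
    model = _fit(X, y, w, seed)
    return SpotClassifier(
        model=model, decision_threshold=clf.decision_threshold,
        X_train=X, y_train=y, w_train=w, seed=seed,
    )


def classify_spots(
    clf: SpotClassifier,
    volume: np.ndarray,
    spacing_um,
    spots: pd.DataFrame,
    patch_radius_um: float = 10.0,
) -> pd.DataFrame:
    """Score consolidated spots; is_cell = score >= decision threshold.

    Only spots flagged ``is_cell`` proceed to atlas mapping and region
    analysis.  Deterministic given a fitted model.
    """
    if not hasattr(clf.model, "classes_"):
        raise RuntimeError("classifier model is not fitted")
    out = spots.copy()
    X = extract_feature_matrix(volume, spacing_um, spots, patch_radius_um)
    scores = clf.predict_proba(X) if len(X) else np.empty(0)
    out["score"] = scores
    out["is_cell"] = scores >= clf.decision_threshold
    return out


def label_spots_by_truth(
    spots: pd.DataFrame, truth: pd.DataFrame, radius_um: float = 5.0
) -> np.ndarray:
    """Binary labels for training: 1 where a detection matches a true cell.

    Uses the same one-to-one radius matching as the validation protocol, so
    labels are consistent with how the model is later scored.
    """
    result = match_spots(spots, truth, radius_um)
    y = np.zeros(len(spots), dtype=int)
    for i, _ in result.pairs:
        y[i] = 1
    return y


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OSU":
        mapping = {"cell": 1, "non_cell": 0, "noncell": 0}
        try:
            return np.array([mapping[str(v)] for v in arr], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown label {exc}") from None
    return arr.astype(int)
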
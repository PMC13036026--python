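"""Analysis constants shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Workflow-wide thresholds and parameters.

    Defaults encode the workflow's operating points: a large standardized
    effect is |d| > 0.8; FDR significance is q < 0.05; the leaf/volume region
    filter keeps leaves above 0.25 mm^3; region pre-selection uses a
    300-tree random forest with 10-fold cross-validation; spot matching and
    duplicate consolidation both use a 5 µm radius; a brain's detection +
    classification is accepted when its validation F1 exceeds 0.80; cohort
    heatmaps use 1 mm coronal slabs smoothed at 100 µm.
    """

    d_threshold: float = 0.8
    q_threshold: float = 0.05
    leaf_min_volume_mm3: float = 0.25
    rf_n_trees: int = 300
    rf_cv_folds: int = 10
    match_radius_um: float = 5.0
    consolidation_eps_um: float = 5.0
    f1_acceptance: float = 0.80
    heatmap_slab_um: float = 1000.0
    heatmap_sigma_um: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "d_threshold": self.d_threshold,
            "q_threshold": self.q_threshold,
            "leaf_min_volume_mm3": self.leaf_min_volume_mm3,
            "rf_n_trees": self.rf_n_trees,
            "rf_cv_folds": self.rf_cv_folds,
            "match_radius_um": self.match_radius_um,
            "consolidation_eps_um": self.consolidation_eps_um,
            "heatmap_slab_um": self.heatmap_slab_um,
            "heatmap_sigma_um": self.heatmap_sigma_um,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not (0 < self.f1_acceptance <= 1):
            raise ValueError(
                f"f1_acceptance must be in (0, 1], got {self.f1_acceptance}"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        return cls(**dict(d))
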
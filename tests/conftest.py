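import numpy as np
import pytest

from fosmap import PhantomSpec, Structure, Ontology, make_toy_atlas, simulate_volume


@pytest.fixture(scope="session")
def toy_ontology() -> Ontology:
    """7-node tree: BR -> {A -> {A1 -> A1a, A2}, B -> B1}."""
    return Ontology(
        [
            Structure(1, "BR", "root", None, 2.0),
            Structure(2, "A", "lobe A", 1, 0.5),
            Structure(3, "B", "lobe B", 1, 0.4),
            Structure(4, "A1", "sub A1", 2, 0.15),
            Structure(5, "A2", "sub A2", 2, 0.25),
            Structure(6, "A1a", "leaf A1a", 4, 0.1),
            Structure(7, "B1", "leaf B1", 3, 0.3),
        ]
    )


@pytest.fixture(scope="session")
def iso_atlas():
    """Isotropic 2-µm toy atlas for mapping/feature geometry tests."""
    return make_toy_atlas(4, (32, 64, 64), (2.0, 2.0, 2.0), seed=0)


@pytest.fixture(scope="session")
def aniso_atlas():
    """Anisotropic confocal-pitch atlas for detection tests."""
    return make_toy_atlas(4, (32, 128, 128), (5.33, 0.361, 0.361), seed=1)


@pytest.fixture(scope="session")
def aniso_phantom(aniso_atlas):
    """Phantom volume + truth at realistic puncta density, no artifacts."""
    tissue = (aniso_atlas.label_volume > 0).sum() * aniso_atlas.voxel_volume_mm3
    rate = 60.0 / tissue
    spec = PhantomSpec(
        shape_vox=(32, 128, 128),
        region_rates={rid: rate for rid in aniso_atlas.ontology.leaves()},
        artifact_spec={},
    )
    volume, truth = simulate_volume(aniso_atlas, spec, seed=3)
    return spec, volume, truth
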
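"""Detectors, foreground masking, DBSCAN consolidation and radius matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fosmap import (
    PhantomSpec,
    consolidate,
    detect_conventional,
    detect_matched,
    foreground_mask,
    match_spots,
    simulate_volume,
)
from fosmap.io import make_spots
from fosmap.simulate import _render_blob

SPACING = (5.33, 0.361, 0.361)


def _blob_volume(centers_vox, amplitude=100.0, noise_sd=10.0, shape=(24, 96, 96),
                 sigma_um=(3.0, 1.5, 1.5), seed=0):
    rng = np.random.default_rng(seed)
    vol = np.full(shape, 20.0, dtype=np.float32)
    sigma_vox = np.asarray(sigma_um) / np.asarray(SPACING)
    for c in centers_vox:
        _render_blob(vol, np.asarray(c, dtype=float), sigma_vox, amplitude)
    if noise_sd:
        vol += rng.standard_normal(shape, dtype=np.float32) * np.float32(noise_sd)
    return vol


class TestForegroundMask:
    def test_constant_volume_warns_all_true(self):
        vol = np.zeros((20, 20, 20), dtype=np.float32)
        with pytest.warns(UserWarning, match="contrast"):
            mask = foreground_mask(vol, (2, 2, 2))
        assert mask.all()

    def test_covers_tissue_block(self, aniso_atlas, aniso_phantom):
        spec, volume, _ = aniso_phantom
        mask = foreground_mask(volume, spec.spacing_um)
        block = aniso_atlas.label_volume > 0
        assert mask[block].mean() >= 0.99

    def test_idempotent_on_masked_volume(self, aniso_phantom):
        spec, volume, _ = aniso_phantom
        mask = foreground_mask(volume, spec.spacing_um)
        remask = foreground_mask(np.where(mask, volume, 0.0), spec.spacing_um)
        assert (mask & remask).sum() / mask.sum() > 0.95


class TestDetectConventional:
    def test_blank_volume_no_detections(self):
        vol = np.full((24, 96, 96), 20.0, dtype=np.float32)
        spots = detect_conventional(vol, SPACING)
        assert len(spots) == 0

    def test_single_punctum_within_one_voxel(self):
        center = (12.0, 48.0, 48.0)
        vol = _blob_volume([center], amplitude=100.0, noise_sd=10.0)
        spots = detect_conventional(vol, SPACING, threshold_sd=5.0)
        spots = spots[~spots["near_border"]]  # border responses are flagged
        assert len(spots) == 1
        got = spots[["z_um", "y_um", "x_um"]].to_numpy()[0]
        want = np.asarray(center) * np.asarray(SPACING)
        assert np.all(np.abs(got - want) <= np.asarray(SPACING))

    def test_two_separated_puncta(self):
        # 20 um apart laterally, both well inside the border flag zone
        c1 = (12.0, 48.0, 50.0)
        c2 = (12.0, 48.0, 50.0 + 20.0 / SPACING[2])
        vol = _blob_volume([c1, c2], shape=(24, 96, 160))
        spots = detect_conventional(vol, SPACING, threshold_sd=5.0)
        assert len(spots[~spots["near_border"]]) == 2

    def test_anisotropic_world_coordinates(self):
        # the same punctum must land at the same world position whatever the
        # grid pitch; accuracy within half a voxel per axis
        center_um = np.array([64.0, 17.3, 17.3])
        vol = _blob_volume([center_um / np.asarray(SPACING)], noise_sd=5.0)
        spots = detect_conventional(vol, SPACING, threshold_sd=5.0)
        spots = spots[~spots["near_border"]].reset_index(drop=True)
        got = spots[["z_um", "y_um", "x_um"]].to_numpy()[0]
        assert np.all(np.abs(got - center_um) <= 0.5 * np.asarray(SPACING) + 1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_conventional(np.zeros((20, 20, 20)), SPACING, sigma_um=(0, 1, 1))


class TestDetectMatched:
    def test_blank_volume_no_detections(self):
        vol = np.full((24, 96, 96), 20.0, dtype=np.float32)
        spots = detect_matched(vol, SPACING)
        assert len(spots) == 0

    def test_dim_punctum_found_where_conventional_fails(self):
        # noise heterogeneity is where the locally-normalized matched filter
        # earns its keep: most of the volume is high-variance autofluorescent
        # tissue that inflates the global LoG threshold, and a dim punctum
        # sits in a quiet region below that threshold but at high local SNR
        center = np.array([12.0, 48.0, 24.0])
        rng = np.random.default_rng(0)
        vol = np.full((24, 96, 192), 20.0, dtype=np.float32)
        noise = rng.standard_normal((24, 96, 192)).astype(np.float32)
        sd = np.where(np.arange(192)[None, None, :] >= 48, 80.0, 8.0).astype(np.float32)
        vol += noise * sd
        sigma_vox = np.asarray((3.0, 1.5, 1.5)) / np.asarray(SPACING)
        _render_blob(vol, center, sigma_vox, 40.0)  # local SNR 5, global SNR < 1
        want = center * np.asarray(SPACING)

        def hits(spots):
            if len(spots) == 0:
                return False
            d = np.linalg.norm(
                spots[["z_um", "y_um", "x_um"]].to_numpy() - want, axis=1
            )
            return bool((d <= 5.33).any())

        assert not hits(detect_conventional(vol, SPACING, threshold_sd=5.0))
        assert hits(detect_matched(vol, SPACING))

    def test_intensity_scale_invariance(self):
        vol = _blob_volume([(12.0, 40.0, 40.0), (12.0, 40.0, 70.0)], noise_sd=8.0)
        n1 = len(detect_matched(vol, SPACING))
        n2 = len(detect_matched(vol * 10.0, SPACING))
        assert n1 == n2 > 0


class TestConsolidate:
    def test_identical_points_merge(self):
        spots = make_spots(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]), intensity=5.0)
        out = consolidate(spots, eps_um=5.0)
        assert len(out) == 1
        assert out.iloc[0][["z_um", "y_um", "x_um"]].tolist() == [1.0, 2.0, 3.0]

    def test_near_pair_merges_to_centroid(self):
        spots = make_spots(
            np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]),
            intensity=np.array([2.0, 7.0]),
        )
        out = consolidate(spots, eps_um=5.0)
        assert len(out) == 1
        assert out.iloc[0]["z_um"] == pytest.approx(2.0)
        assert out.iloc[0]["intensity"] == 7.0  # max member intensity
        assert out.iloc[0]["source"] == "consolidated"

    def test_distant_pair_survives(self):
        spots = make_spots(np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]]))
        out = consolidate(spots, eps_um=5.0)
        assert len(out) == 2
        assert sorted(out["z_um"]) == [0.0, 12.0]

    def test_output_never_larger(self, aniso_phantom):
        spec, volume, _ = aniso_phantom
        union = pd.concat(
            [detect_conventional(volume, SPACING), detect_matched(volume, SPACING)],
            ignore_index=True,
        )
        out = consolidate(union)
        assert len(out) <= len(union)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        ),
        min_size=1,
        max_size=15,
    )
)
def test_consolidate_idempotent(points):
    spots = make_spots(np.asarray(points), intensity=1.0)
    once = consolidate(spots, eps_um=5.0)
    twice = consolidate(once, eps_um=5.0)
    a = np.sort(once[["z_um", "y_um", "x_um"]].to_numpy(), axis=0)
    b = np.sort(twice[["z_um", "y_um", "x_um"]].to_numpy(), axis=0)
    assert np.allclose(a, b)


class TestMatchSpots:
    def test_perfect_prediction(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 20.0, 5.0]])
        r = match_spots(make_spots(pts), make_spots(pts), 5.0)
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_hand_enumerated_half_match(self):
        truth = make_spots(np.array([[0.0, 0, 0], [0, 0, 10.0]]))
        pred = make_spots(np.array([[0.0, 0, 2.0], [0, 0, 30.0]]))
        r = match_spots(pred, truth, 5.0)
        assert r.n_matched == 1
        assert r.precision == 0.5
        assert r.recall == 0.5
        assert r.f1 == 0.5

    def test_empty_sides(self):
        empty = make_spots(np.empty((0, 3)))
        some = make_spots(np.array([[0.0, 0, 0]]))
        assert match_spots(empty, some, 5.0).recall == 0.0
        assert match_spots(some, empty, 5.0).precision == 0.0
        assert match_spots(empty, empty, 5.0).f1 == 0.0

    def test_assignment_beats_greedy(self):
        # greedy nearest-first would match pred0 to truth0 and strand pred1;
        # optimal assignment matches both
        truth = make_spots(np.array([[0.0, 0, 0], [0, 0, 4.0]]))
        pred = make_spots(np.array([[0.0, 0, 3.0], [0, 0, 2.9]]))
        r = match_spots(pred, truth, 5.0)
        assert r.n_matched == 2

    def test_over_detection_union_recall(self, aniso_atlas):
        # the union of both detectors must dominate either alone and reach
        # high recall at SNR >= 5
        tissue = (aniso_atlas.label_volume > 0).sum() * aniso_atlas.voxel_volume_mm3
        spec = PhantomSpec(
            shape_vox=(32, 128, 128),
            region_rates={r: 40.0 / tissue for r in aniso_atlas.ontology.leaves()},
            artifact_spec={},
        )
        union_rec, conv_rec, matched_rec = [], [], []
        for seed in range(20):
            volume, truth = simulate_volume(aniso_atlas, spec, seed=100 + seed)
            if len(truth) == 0:
                continue
            a = detect_conventional(volume, spec.spacing_um)
            b = detect_matched(volume, spec.spacing_um)
            union = pd.concat([a, b], ignore_index=True)
            conv_rec.append(match_spots(a, truth, 5.0).recall)
            matched_rec.append(match_spots(b, truth, 5.0).recall)
            union_rec.append(match_spots(union, truth, 5.0).recall)
        assert np.mean(union_rec) >= np.mean(conv_rec) - 1e-9
        assert np.mean(union_rec) >= np.mean(matched_rec) - 1e-9
        assert np.mean(union_rec) >= 0.95
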
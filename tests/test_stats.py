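"""FDR, region selection, mixed-model fits and effect-size classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from fosmap import (
    AnalysisConfig,
    CohortSpec,
    RegionResponseModel,
    bh_fdr,
    classify_responses,
    effect_sizes,
    fit_region_lmm,
    make_toy_atlas,
    select_regions,
    simulate_cohort,
)
from fosmap.stats import (
    CONTRASTS,
    TERMS,
    DegenerateVarianceError,
    LmmFit,
    design_matrix,
)


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.2]
        q = bh_fdr(p)
        assert q[1] < q[2] < q[0]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), expected, atol=1e-12)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50
    )
)
def test_bh_fdr_brute_force_and_monotone(p):
    p = np.asarray(p)
    q = bh_fdr(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    # oracle: q_i = min over j with p_j >= p_i of p_j * n / rank_j
    for i in range(n):
        candidates = [
            p[j] * n / rank[j] for j in range(n) if p[j] >= p[i]
        ]
        assert q[i] == pytest.approx(min(min(candidates), 1.0), abs=1e-12)
    # monotone in p
    for i in range(n):
        for j in range(n):
            if p[i] <= p[j]:
                assert q[i] <= q[j] + 1e-12


@pytest.fixture(scope="module")
def flat_atlas():
    return make_toy_atlas(10, (48, 32, 32), (10, 10, 10), seed=0)


@pytest.fixture(scope="module")
def regions(flat_atlas):
    return [flat_atlas.ontology[i].acronym for i in flat_atlas.ontology.leaves()]


class TestSelectRegions:
    def test_strong_region_ranked_first(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 500.0 for r in regions},
            effect_map={regions[0]: (3.0, 0.0, 0.0)},
            seed=5,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        sel = select_regions(dm, flat_atlas.ontology, n_trees=300, cv_folds=10, seed=0)
        top = max(sel.importances, key=sel.importances.get)
        assert top == regions[0]
        assert regions[0] in sel.pruned
        assert 0 <= sel.cv_f1 <= 1

    def test_constant_column_zero_importance(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 500.0 for r in regions},
            effect_map={regions[0]: (3.0, 0.0, 0.0)},
            seed=5,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        dm[regions[-1]] = 77.0  # constant across animals
        sel = select_regions(dm, flat_atlas.ontology, seed=0)
        assert sel.importances[regions[-1]] == 0.0
        assert regions[-1] not in sel.selected

    def test_parent_pruning_delegated(self, flat_atlas, regions):
        # inject signal into a lobe column too: parent must drop if a child
        # is selected
        spec = CohortSpec(
            baseline_density={r: 500.0 for r in regions},
            effect_map={regions[0]: (3.0, 0.0, 0.0)},
            seed=5,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        ont = flat_atlas.ontology
        parent_acr = ont[ont[regions[0]].parent_id].acronym
        dm[parent_acr] = dm[regions[0]] * 0.9
        sel = select_regions(dm, ont, seed=0)
        if parent_acr in sel.selected and regions[0] in sel.selected:
            assert parent_acr not in sel.pruned

    def test_single_class_rejected(self, flat_atlas, regions):
        spec = CohortSpec(
            groups=[("morphine", "1h", "male", 6)],
            baseline_density={r: 500.0 for r in regions},
            seed=0,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        with pytest.raises(ValueError, match="class"):
            select_regions(dm, flat_atlas.ontology)


class TestFitRegionLmm:
    def test_zero_noise_betas_vanish(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 200.0 for r in regions},
            sigma_mouse=0.0,
            sigma_resid=0.0,
            seed=0,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        fit = fit_region_lmm(dm, regions[0])
        for term in TERMS[1:]:
            assert abs(fit.beta[term]) < 1e-8
        assert fit.beta["Intercept"] == pytest.approx(200.0)

    def test_beta_recovery_within_3se(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 500.0 for r in regions},
            effect_map={regions[0]: (1.5, -0.8, 0.6)},
            seed=21,
        )
        dm, truth = simulate_cohort(flat_atlas, spec)
        fit = fit_region_lmm(dm, regions[0])
        eff = effect_sizes(fit)
        sd = np.sqrt(spec.sigma_mouse**2 + spec.sigma_resid**2)
        for _, row in eff.iterrows():
            true_beta = truth[regions[0]][row["contrast"]] * sd
            assert abs(row["beta"] - true_beta) < 3 * row["se"]

    def test_total_variance_matches_lstsq_oracle(self, flat_atlas, regions):
        spec = CohortSpec(baseline_density={r: 500.0 for r in regions}, seed=8)
        dm, _ = simulate_cohort(flat_atlas, spec)
        fit = fit_region_lmm(dm, regions[0])
        X = design_matrix(dm)
        y = dm[regions[0]].to_numpy()
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_hat
        mse = resid @ resid / (len(y) - X.shape[1])
        assert fit.sigma2_total == pytest.approx(mse, rel=0.1)

    def test_empty_cell_named_in_error(self, flat_atlas, regions):
        spec = CohortSpec(
            groups=[g for g in CohortSpec().groups if g[:3] != ("saline", "1h", "female")],
            baseline_density={r: 500.0 for r in regions},
            seed=0,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        with pytest.raises(ValueError, match="saline, 1h, female"):
            fit_region_lmm(dm, regions[0])

    def test_repeated_measures_uses_mixedlm(self, flat_atlas, regions):
        spec = CohortSpec(baseline_density={r: 500.0 for r in regions}, seed=4)
        dm, _ = simulate_cohort(flat_atlas, spec)
        dm2 = pd.concat([dm, dm], ignore_index=True)
        rng = np.random.default_rng(0)
        dm2[regions[0]] += rng.normal(0, 10, len(dm2))
        fit = fit_region_lmm(dm2, regions[0])
        assert fit.method == "mixedlm-reml"
        assert fit.sigma2_total > 0

    def test_d_invariant_to_variance_split(self):
        # d depends only on the sum sigma2_resid + sigma2_intercept
        beta = {t: 0.0 for t in TERMS}
        beta["treat"] = 2.0
        cov = np.eye(len(TERMS)) * 0.25
        a = LmmFit("r", beta, cov, 0.64, 0.36, True, 27, "x")
        b = LmmFit("r", beta, cov, 0.36, 0.64, True, 27, "x")
        da = effect_sizes(a).set_index("contrast")["d"]
        db = effect_sizes(b).set_index("contrast")["d"]
        assert np.allclose(da, db)
        assert da["treat@M1h"] == pytest.approx(2.0)


class TestEffectSizes:
    def _fit(self, beta_treat=0.0, s2e=0.64, s2u=0.36):
        beta = {t: 0.0 for t in TERMS}
        beta["treat"] = beta_treat
        cov = np.eye(len(TERMS)) * 0.25
        return LmmFit("r", beta, cov, s2e, s2u, True, 27, "x")

    def test_null_contrast_symmetric_ci(self):
        eff = effect_sizes(self._fit(0.0)).set_index("contrast")
        row = eff.loc["treat@M1h"]
        assert row["d"] == 0.0
        assert row["d_lower"] == pytest.approx(-row["d_upper"])

    def test_hand_arithmetic(self):
        eff = effect_sizes(self._fit(2.0)).set_index("contrast")
        assert eff.loc["treat@M1h", "d"] == pytest.approx(2.0)  # 2 / sqrt(1.0)

    def test_zero_variance_zero_beta_reports_zero(self):
        eff = effect_sizes(self._fit(0.0, 0.0, 0.0)).set_index("contrast")
        assert (eff["d"] == 0.0).all()
        assert (eff["p"] == 1.0).all()

    def test_zero_variance_nonzero_beta_raises(self):
        with pytest.raises(DegenerateVarianceError):
            effect_sizes(self._fit(2.0, 0.0, 0.0))

    def test_unconverged_fit_rejected(self):
        fit = self._fit(1.0)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            effect_sizes(fit)


def _effects_frame(rows):
    base = []
    for region, contrast, d, lo, hi, p in rows:
        base.append(
            {"region": region, "contrast": contrast, "beta": d, "se": 1.0,
             "d": d, "d_lower": lo, "d_upper": hi, "p": p, "large_effect": abs(d) > 0.8}
        )
    df = pd.DataFrame(base)
    # fill every remaining contrast with nulls so families are complete
    filled = []
    for region in df["region"].unique():
        have = set(df.loc[df["region"] == region, "contrast"])
        for name in CONTRASTS:
            if name not in have:
                filled.append(
                    {"region": region, "contrast": name, "beta": 0.0, "se": 1.0,
                     "d": 0.0, "d_lower": -0.5, "d_upper": 0.5, "p": 0.9,
                     "large_effect": False}
                )
    return pd.concat([df, pd.DataFrame(filled)], ignore_index=True)


class TestClassifyResponses:
    def test_small_effect_never_responsive(self):
        eff = _effects_frame([("r1", "treat@M1h", 0.5, 0.2, 0.8, 0.01)])
        _, report = classify_responses(eff)
        assert report["responsive"] == []

    def test_ci_rule(self):
        eff = _effects_frame(
            [
                ("r1", "treat@M1h", 1.0, 0.1, 1.9, 0.02),
                ("r2", "treat@M1h", 1.0, -0.1, 2.1, 0.06),
            ]
        )
        _, report = classify_responses(eff)
        assert report["responsive"] == ["r1"]

    def test_star_thresholds(self):
        rows = [
            ("r1", "treat@M1h", 2.0, 1.0, 3.0, 0.00001),
            ("r2", "treat@M1h", 1.5, 0.5, 2.5, 0.004),
            ("r3", "treat@M1h", 1.2, 0.2, 2.2, 0.015),
            ("r4", "treat@M1h", 1.1, 0.1, 2.1, 0.4),
        ]
        out, _ = classify_responses(_effects_frame(rows))
        stars = out.set_index(["region", "contrast"])["stars"]
        # q re-ranks within the family: q = [4e-5, 8e-3, 2e-2, 4e-1]
        assert stars[("r1", "treat@M1h")] == "***"
        assert stars[("r2", "treat@M1h")] == "**"
        assert stars[("r3", "treat@M1h")] == "*"
        assert stars[("r4", "treat@M1h")] == ""

    def test_interaction_sets(self):
        eff = _effects_frame(
            [
                ("r1", "treat:time@M", -1.2, -2.0, -0.4, 0.01),
                ("r2", "treat:sex@1h", -1.0, -1.9, -0.1, 0.03),
            ]
        )
        _, report = classify_responses(eff)
        assert report["time_difference"] == ["r1"]
        assert report["sex_difference"] == ["r2"]

    def test_missing_contrast_rejected(self):
        eff = _effects_frame([("r1", "treat@M1h", 1.0, 0.1, 1.9, 0.02)])
        eff = eff[eff["contrast"] != "treat@F4h"]
        with pytest.raises(ValueError, match="missing"):
            classify_responses(eff)


class TestRegionResponseModel:
    def test_zero_noise_null_cohort_reports_d_zero(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 200.0 for r in regions},
            sigma_mouse=0.0,
            sigma_resid=0.0,
            seed=0,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        model = RegionResponseModel(dm, flat_atlas.ontology)
        res = model.fit(select=False, regions=regions)
        assert (res.effects["d"] == 0.0).all()
        assert res.report["n_responsive"] == 0

    def test_summary_mentions_counts(self, flat_atlas, regions):
        spec = CohortSpec(
            baseline_density={r: 500.0 for r in regions},
            effect_map={regions[0]: (2.5, 0.0, 0.0)},
            seed=3,
        )
        dm, _ = simulate_cohort(flat_atlas, spec)
        res = RegionResponseModel(dm, flat_atlas.ontology).fit(regions=regions)
        text = res.summary()
        assert "27 animals" in text
        assert "responsive" in text.lower()
        table = res.effect_table()
        assert set(
            ["region_id", "acronym", "contrast", "beta", "d", "d_lower",
             "d_upper", "p", "q", "stars", "large_effect", "responsive"]
        ) == set(table.columns)
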
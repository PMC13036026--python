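"""Cohort inference: region pre-selection, factorial mixed models,
variance-standardized effect sizes, FDR and response classification.

The density matrix (one row per animal, one cells/mm^3 column per region)
is first screened with a random-forest classifier of treatment; regions
with nonzero impurity importance are kept and ancestors of selected regions
pruned (parents and children carry correlated signal).  Each surviving
region then gets a factorial linear mixed model

    density ~ treatment * time * sex,   random intercept per mouse,

with reference cell (saline, 1h, male), so the treatment main effect is the
morphine effect in 1h males.  Standardized effects (Cohen's d) divide a
fixed-effect contrast by sqrt(sigma2_resid + sigma2_intercept) — the total
variance, which stays identifiable even when the random-intercept split is
not.  A structure "responds" when some treatment contrast has |d| > 0.8
with a 95% CI excluding 0; time and sex differences use the same rule on
the treatment:time and treatment:sex interaction contrasts.  p-values are
Wald (normal) tests, Benjamini-Hochberg-adjusted within each contrast
family across regions; stars mark q < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .atlas import Ontology, exclude_parents
from .config import AnalysisConfig

__all__ = [
    "TERMS",
    "CONTRASTS",
    "GROUP_CONTRASTS",
    "LmmFit",
    "SelectionResult",
    "bh_fdr",
    "select_regions",
    "fit_region_lmm",
    "effect_sizes",
    "classify_responses",
    "RegionResponseModel",
    "RegionResponseResults",
]

META_COLUMNS = ["animal_id", "treatment", "time", "sex"]

#: fixed-effect terms of the full-factorial design, reference (saline, 1h, male)
TERMS = [
    "Intercept",
    "treat",
    "time4h",
    "female",
    "treat:time4h",
    "treat:female",
    "time4h:female",
    "treat:time4h:female",
]

#: contrast vectors over TERMS; e.g. the morphine effect in 4h females is
#: beta_treat + beta_treat:time + beta_treat:sex + beta_treat:time:sex
CONTRASTS: dict[str, np.ndarray] = {
    "treat@M1h": np.array([0, 1, 0, 0, 0, 0, 0, 0], dtype=float),
    "treat@F1h": np.array([0, 1, 0, 0, 0, 1, 0, 0], dtype=float),
    "treat@M4h": np.array([0, 1, 0, 0, 1, 0, 0, 0], dtype=float),
    "treat@F4h": np.array([0, 1, 0, 0, 1, 1, 0, 1], dtype=float),
    "treat:time@M": np.array([0, 0, 0, 0, 1, 0, 0, 0], dtype=float),
    "treat:time@F": np.array([0, 0, 0, 0, 1, 0, 0, 1], dtype=float),
    "treat:sex@1h": np.array([0, 0, 0, 0, 0, 1, 0, 0], dtype=float),
    "treat:sex@4h": np.array([0, 0, 0, 0, 0, 1, 0, 1], dtype=float),
}

GROUP_CONTRASTS = ["treat@M1h", "treat@F1h", "treat@M4h", "treat@F4h"]
TIME_CONTRASTS = ["treat:time@M", "treat:time@F"]
SEX_CONTRASTS = ["treat:sex@1h", "treat:sex@4h"]


class DegenerateVarianceError(ValueError):
    """Total variance is zero but a contrast is nonzero: d undefined."""


# -- multiple testing ------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, compute p_(i) * n / i, take the running minimum from the
    largest rank down, cap at 1, and return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    raw = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# -- region pre-selection --------------------------------------------------

@dataclass
class SelectionResult:
    """Random-forest screening outcome on the density matrix."""

    importances: dict[str, float]
    selected: set[str]
    cv_f1: float
    pruned: set[str]
    n_folds: int


def _region_columns(dm: pd.DataFrame) -> list[str]:
    return [c for c in dm.columns if c not in META_COLUMNS]


def select_regions(
    dm: pd.DataFrame,
    ontology: Ontology,
    n_trees: int = 300,
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Screen regions by random-forest importance for the treatment label.

    Stratified K-fold cross-validated F1 is reported (folds capped at the
    smaller class size — a small factorial cohort cannot always fill 10
    stratified folds), then a final forest is fit on all animals.  Regions
    with nonzero impurity importance are selected; ancestors of selected
    regions are pruned so the survivors form an antichain in the ontology.
    """
    regions = _region_columns(dm)
    y = (dm["treatment"] == "morphine").to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("treatment label is single-class; cannot select regions")
    if counts.min() < 2:
        raise ValueError("need >= 2 animals per treatment class")
    X = dm[regions].to_numpy(dtype=float)

    folds = int(min(cv_folds, counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    scores = cross_val_score(forest, X, y, cv=cv, scoring="f1")
    cv_f1 = float(scores.mean())

    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(X, y)
    importances = dict(zip(regions, (float(v) for v in final.feature_importances_)))
    selected = {r for r, v in importances.items() if v > 0}

    sel_ids = {ontology[r].id for r in selected}
    pruned_ids = exclude_parents(sel_ids, ontology)
    pruned = {ontology[i].acronym for i in pruned_ids}
    return SelectionResult(
        importances=importances,
        selected=selected,
        cv_f1=cv_f1,
        pruned=pruned,
        n_folds=folds,
    )


# -- per-region mixed model ------------------------------------------------

@dataclass
class LmmFit:
    """Fitted factorial model for one region.

    ``sigma2_resid`` + ``sigma2_intercept`` is the identifiable total
    variance used to standardize effects; with one observation per mouse the
    split between the two is arbitrary and only the sum is meaningful.
    """

    region: str
    beta: dict[str, float]
    cov_beta: np.ndarray
    sigma2_resid: float
    sigma2_intercept: float
    converged: bool
    n_obs: int
    method: str

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_resid + self.sigma2_intercept


def design_matrix(dm: pd.DataFrame) -> np.ndarray:
    """Full-factorial (2x2x2) design matrix in TERMS order."""
    t = (dm["treatment"] == "morphine").to_numpy(dtype=float)
    h4 = (dm["time"] == "4h").to_numpy(dtype=float)
    f = (dm["sex"] == "female").to_numpy(dtype=float)
    return np.column_stack(
        [np.ones(len(dm)), t, h4, f, t * h4, t * f, h4 * f, t * h4 * f]
    )


def _check_cells(dm: pd.DataFrame) -> None:
    for treat in ("saline", "morphine"):
        for time in ("1h", "4h"):
            for sex in ("male", "female"):
                n = (
                    (dm["treatment"] == treat)
                    & (dm["time"] == time)
                    & (dm["sex"] == sex)
                ).sum()
                if n == 0:
                    raise ValueError(
                        f"design cell ({treat}, {time}, {sex}) is empty; "
                        "the full factorial model is rank-deficient"
                    )


def fit_region_lmm(dm: pd.DataFrame, region: str) -> LmmFit:
    """Fit density ~ treatment*time*sex with a per-mouse random intercept.

    With repeated measures per mouse the model is fit by REML
    (statsmodels MixedLM).  The wide density matrix has exactly one row per
    mouse, making the intercept variance unidentifiable; the fit then runs
    through OLS, which estimates the same fixed effects and the same
    identifiable total variance (MSE on n - p df, the REML estimate), with
    the intercept share reported as 0.
    """
    if region not in dm.columns:
        raise KeyError(f"region column {region!r} not in density matrix")
    _check_cells(dm)
    y = dm[region].to_numpy(dtype=float)
    X = design_matrix(dm)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} animals to fit the factorial model")

    singleton = dm["animal_id"].nunique() == n
    if singleton:
        res = sm.OLS(y, X).fit()
        beta = dict(zip(TERMS, (float(b) for b in res.params)))
        return LmmFit(
            region=region,
            beta=beta,
            cov_beta=np.asarray(res.cov_params()),
            sigma2_resid=float(res.mse_resid),
            sigma2_intercept=0.0,
            converged=True,
            n_obs=n,
            method="ols-identifiable-sum",
        )

    groups = dm["animal_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    beta = dict(zip(TERMS, (float(b) for b in res.fe_params)))
    return LmmFit(
        region=region,
        beta=beta,
        cov_beta=np.asarray(res.cov_params())[:p, :p],
        sigma2_resid=float(res.scale),
        sigma2_intercept=float(np.asarray(res.cov_re)[0, 0]),
        converged=bool(res.converged),
        n_obs=n,
        method="mixedlm-reml",
    )


# -- standardized effects --------------------------------------------------

def effect_sizes(
    fit: LmmFit,
    contrasts: Mapping[str, np.ndarray] | None = None,
    d_threshold: float = 0.8,
) -> pd.DataFrame:
    """Cohen's d with 95% CI and Wald p per contrast for one region fit.

    d = c'beta / sqrt(sigma2_resid + sigma2_intercept); the CI scales the
    Wald CI of c'beta by the same total SD (the SD is treated as known — no
    small-sample correction is applied).  Zero total variance with a zero
    contrast reports d = 0; with a nonzero contrast it raises, as d is then
    undefined.
    """
    if not fit.converged:
        raise ValueError(f"region {fit.region!r}: fit did not converge")
    contrasts = dict(CONTRASTS) if contrasts is None else dict(contrasts)
    beta = np.array([fit.beta[t] for t in TERMS])
    var_total = fit.sigma2_total
    tol = 1e-12 * max(1.0, float(np.abs(beta).max()) ** 2)

    rows = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        bc = float(c @ beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        if var_total <= tol:
            if abs(bc) <= np.sqrt(tol):
                d = d_lo = d_hi = 0.0
                pval = 1.0
            else:
                raise DegenerateVarianceError(
                    f"region {fit.region!r}, contrast {name!r}: zero total "
                    "variance with nonzero contrast; d undefined"
                )
        else:
            sd = float(np.sqrt(var_total))
            d = bc / sd
            d_lo = (bc - 1.96 * se) / sd
            d_hi = (bc + 1.96 * se) / sd
            z = bc / se if se > 0 else (0.0 if bc == 0 else np.inf)
            pval = float(2 * norm.sf(abs(z)))
        rows.append(
            {
                "region": fit.region,
                "contrast": name,
                "beta": bc,
                "se": se,
                "d": d,
                "d_lower": d_lo,
                "d_upper": d_hi,
                "p": pval,
                "large_effect": abs(d) > d_threshold,
            }
        )
    return pd.DataFrame(rows)


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def classify_responses(
    effects: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """FDR-adjust, star and classify regions from their effect records.

    FDR is applied within each contrast family (one contrast name, across
    regions).  A region is morphine-responsive when any of the four
    treatment group contrasts has |d| above the threshold AND a CI excluding
    zero; time- and sex-difference sets apply the same rule to the
    interaction contrasts.  Returns the augmented effect table and a report
    with the responsive / time-difference / sex-difference sets.
    """
    config = config or AnalysisConfig()
    required = set(CONTRASTS)
    for region, grp in effects.groupby("region"):
        missing = required - set(grp["contrast"])
        if missing:
            raise ValueError(f"region {region!r} missing contrasts: {sorted(missing)}")

    out = effects.copy()
    out["q"] = np.nan
    for name in required:
        fam = out["contrast"] == name
        out.loc[fam, "q"] = bh_fdr(out.loc[fam, "p"].to_numpy())
    out["stars"] = [_stars(q) for q in out["q"]]
    out["large_effect"] = out["d"].abs() > config.d_threshold
    out["ci_excludes_zero"] = (out["d_lower"] > 0) | (out["d_upper"] < 0)
    out["responsive"] = (
        out["contrast"].isin(GROUP_CONTRASTS)
        & out["large_effect"]
        & out["ci_excludes_zero"]
    )

    flagged = out["large_effect"] & out["ci_excludes_zero"]
    responsive_by_group = {
        name: sorted(out.loc[(out["contrast"] == name) & flagged, "region"])
        for name in GROUP_CONTRASTS
    }
    responsive = sorted(
        set().union(*(set(v) for v in responsive_by_group.values()))
    )
    time_diff = sorted(
        set(out.loc[out["contrast"].isin(TIME_CONTRASTS) & flagged, "region"])
    )
    sex_diff = sorted(
        set(out.loc[out["contrast"].isin(SEX_CONTRASTS) & flagged, "region"])
    )
    significant = sorted(
        set(out.loc[(out["q"] < config.q_threshold), "region"])
    )
    report = {
        "responsive": responsive,
        "responsive_by_group": responsive_by_group,
        "time_difference": time_diff,
        "sex_difference": sex_diff,
        "significant_any_contrast": significant,
        "n_responsive": len(responsive),
    }
    return out, report


# -- model / results facade ------------------------------------------------

class RegionResponseModel:
    """Treatment-response analysis of a cohort density matrix.

    Bundles the full inference stack — random-forest region selection,
    per-region factorial mixed models, standardized effects, FDR and
    response classification — behind a fit() that returns a results object.

    Parameters
    ----------
    dm : wide-format density matrix (animal_id/treatment/time/sex + one
        column per region acronym).
    ontology : the structure tree the region columns come from.
    config : analysis thresholds; defaults to the workflow operating points.
    """

    def __init__(
        self,
        dm: pd.DataFrame,
        ontology: Ontology,
        config: AnalysisConfig | None = None,
    ):
        missing = [c for c in META_COLUMNS if c not in dm.columns]
        if missing:
            raise ValueError(f"density matrix missing metadata columns {missing}")
        self.dm = dm
        self.ontology = ontology
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(
        cls, dm: pd.DataFrame, ontology: Ontology, **kwargs
    ) -> "RegionResponseModel":
        return cls(dm, ontology, **kwargs)

    def fit(self, select: bool = True, regions: Sequence[str] | None = None):
        """Run selection (unless given explicit regions) and per-region fits."""
        cfg = self.config
        selection = None
        if regions is None:
            if select:
                selection = select_regions(
                    self.dm,
                    self.ontology,
                    n_trees=cfg.rf_n_trees,
                    cv_folds=cfg.rf_cv_folds,
                    seed=cfg.rng_seed,
                )
                regions = sorted(selection.pruned)
            else:
                regions = _region_columns(self.dm)
        fits = {r: fit_region_lmm(self.dm, r) for r in regions}
        tables = [
            effect_sizes(fit, d_threshold=cfg.d_threshold) for fit in fits.values()
        ]
        effects = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(
                columns=["region", "contrast", "beta", "se", "d", "d_lower",
                         "d_upper", "p", "large_effect"]
            )
        )
        if len(effects):
            effects, report = classify_responses(effects, cfg)
        else:
            report = {
                "responsive": [], "responsive_by_group": {},
                "time_difference": [], "sex_difference": [],
                "significant_any_contrast": [], "n_responsive": 0,
            }
        return RegionResponseResults(self, selection, fits, effects, report)


class RegionResponseResults:
    """Estimates, uncertainties and classification from a fitted model."""

    def __init__(self, model, selection, fits, effects, report):
        self.model = model
        self.selection = selection
        self.fits = fits
        self.effects = effects
        self.report = report

    @property
    def responsive_regions(self) -> list[str]:
        return self.report["responsive"]

    def effect_table(self) -> pd.DataFrame:
        """Effect records with ontology ids, CSV-ready column order."""
        eff = self.effects.copy()
        ont = self.model.ontology
        eff.insert(0, "region_id", [ont[r].id for r in eff["region"]])
        eff = eff.rename(columns={"region": "acronym"})
        cols = ["region_id", "acronym", "contrast", "beta", "d", "d_lower",
                "d_upper", "p", "q", "stars", "large_effect", "responsive"]
        return eff[cols]

    def summary(self) -> str:
        lines = []
        if self.selection is not None:
            lines.append(
                f"Region selection: {len(self.selection.selected)} regions with "
                f"nonzero importance, {len(self.selection.pruned)} after parent "
                f"exclusion (CV F1 = {self.selection.cv_f1:.3f}, "
                f"{self.selection.n_folds} folds)"
            )
        lines.append(
            f"Fitted {len(self.fits)} region models on "
            f"{self.model.dm.shape[0]} animals"
        )
        rep = self.report
        lines.append(f"Morphine-responsive structures: {rep['n_responsive']}")
        for name, regions in rep["responsive_by_group"].items():
            lines.append(f"  {name}: {len(regions)}")
        lines.append(f"Time differences: {len(rep['time_difference'])}")
        lines.append(f"Sex differences: {len(rep['sex_difference'])}")
        if len(self.effects):
            flagged = self.effects[self.effects["responsive"]]
            if len(flagged):
                lines.append("Top responsive effects (|d| desc):")
                top = flagged.reindex(
                    flagged["d"].abs().sort_values(ascending=False).index
                ).head(10)
                for _, r in top.iterrows():
                    lines.append(
                        f"  {r['region']:>10s} {r['contrast']:<12s} "
                        f"d={r['d']:+.2f} ({r['d_lower']:+.2f}, {r['d_upper']:+.2f}) "
                        f"q={r['q']:.4f}{r['stars']}"
                    )
        return "\n".join(lines)
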
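"""Multi-site group inference on network-metric AUC outcomes.

Each outcome (a global metric's AUC, or one node's AUC for a nodal
metric) is fit with a linear mixed-effects model

    y ~ 1 + group + age + sex + education + head motion
        + (1 | site) + (group | site)

so both the intercept and the case-control effect carry site-specific
random components. Estimation is by REML (statsmodels ``MixedLM``); the
group effect is tested with a Wald statistic. When the random-slope fit
fails to converge or is singular, the model is refit with a random
intercept only, and as a last resort with ordinary least squares plus
site fixed effects — the structure actually used is always recorded in
the result.

Nodal metrics are corrected with Benjamini-Hochberg FDR across their
nodes (one family per nodal metric); global metrics are reported with
raw p-values (q set equal to p), matching the reporting convention of
large consortium analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "ContrastResult",
    "filter_sites",
    "fit_lme",
    "contrast_all_outcomes",
    "subgroup_contrast",
    "symptom_association",
    "map_significant_nodes",
    "benjamini_hochberg",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of the per-outcome mixed model."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    #: extra fixed covariates, e.g. ("overall_fc",) or ("on_medication",)
    extra_covariates: tuple[str, ...] = ()
    group_col: str = "group"
    reference_level: str = "NC"
    #: "slope" = (1|site) + (group|site); "intercept" = (1|site); "ols" = site fixed effects
    random_structure: str = "slope"
    #: interaction terms with the group indicator, e.g. ("sex",)
    interactions: tuple[str, ...] = ()
    reml: bool = True

    def all_covariates(self) -> tuple[str, ...]:
        return tuple(self.covariates) + tuple(self.extra_covariates)


@dataclass
class ContrastResult:
    """Wald test of the effect of interest for one outcome."""

    metric: str
    node_id: str  # "GLOBAL" for global metrics
    beta: float
    t: float
    df: float
    p: float
    q: float | None = None
    significant: bool | None = None
    n_used: int = 0
    converged: bool = True
    random_structure_used: str = "slope"

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.t != 0 and np.sign(self.t) != np.sign(self.beta):
            raise ValueError("sign(t) must equal sign(beta)")


def filter_sites(
    covariates: pd.DataFrame,
    min_per_group: int = 10,
    group_col: str = "group",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop sites with fewer than ``min_per_group`` subjects in either group.

    A site with exactly ``min_per_group`` in both groups is retained.
    Returns the filtered table and the list of removed site ids.
    """
    if min_per_group < 1:
        raise ValueError("min_per_group must be >= 1")
    groups = covariates[group_col].unique()
    dropped: list[str] = []
    for site, sub in covariates.groupby("site_id"):
        counts = sub[group_col].value_counts()
        if any(counts.get(g, 0) < min_per_group for g in groups):
            dropped.append(str(site))
    kept = covariates[~covariates["site_id"].astype(str).isin(dropped)].copy()
    if kept.empty:
        raise ValueError(
            f"no sites survive the >= {min_per_group}-per-group filter"
        )
    return kept, sorted(dropped)


def _encode_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col = df[name]
    if name == "sex":
        return (col.astype(str) == "male").to_numpy(float)
    if col.dtype == bool or col.dtype == object:
        try:
            return col.astype(float).to_numpy()
        except (TypeError, ValueError):
            raise ValueError(f"cannot encode covariate {name!r} numerically")
    return col.to_numpy(float)


def _design(
    covariates: pd.DataFrame, spec: ModelSpec, effect: str
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Build (X, names, effect_column, site_codes); effect is column 1."""
    if effect == spec.group_col:
        levels = set(covariates[spec.group_col].astype(str))
        if len(levels) < 2:
            raise ValueError("cohort contains a single group; contrast undefined")
        if len(levels) > 2:
            raise ValueError(f"group column must be binary, found {sorted(levels)}")
        eff = (covariates[spec.group_col].astype(str)
               != spec.reference_level).to_numpy(float)
    else:
        eff = covariates[effect].to_numpy(float)
    cols = [np.ones(len(covariates)), eff]
    names = ["intercept", effect]
    for cov in spec.all_covariates():
        if cov == effect:  # the effect of interest is never its own nuisance
            continue
        cols.append(_encode_column(covariates, cov))
        names.append(cov)
    for term in spec.interactions:
        cols.append(eff * _encode_column(covariates, term))
        names.append(f"{effect}:{term}")
    X = np.column_stack(cols)
    sites = covariates["site_id"].astype(str).to_numpy()
    return X, names, eff, sites


def _fit_mixed(y, X, sites, exog_re, reml):
    """One MixedLM fit; returns (result, converged, singular)."""
    # boundary-of-parameter-space warnings are routine when a variance
    # component is near zero; the eigenvalue check below handles that case,
    # so warnings are silenced rather than treated as failure
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=sites, exog_re=exog_re)
        try:
            res = model.fit(reml=reml, method=["lbfgs"])
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            return None, False, True
        converged = bool(getattr(res, "converged", False))
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        eig = np.linalg.eigvalsh((cov_re + cov_re.T) / 2)
        scale = max(float(res.scale), 1e-12)
        singular = bool(eig[0] < 1e-6 * scale)
        if not np.isfinite(res.bse_fe[1]) or res.bse_fe[1] <= 0:
            return res, False, True
    return res, converged, singular


def fit_lme(
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    effect: str | None = None,
    metric: str = "outcome",
    node_id: str = "GLOBAL",
) -> ContrastResult:
    """Fit the mixed model for one outcome and test the effect of interest.

    ``outcome`` must be aligned with ``covariates`` row-for-row; rows
    with missing values in the outcome or any model column are dropped
    (listwise), and the count actually used is recorded. The fallback
    chain random slope -> random intercept -> OLS with site fixed
    effects is deterministic and the structure used is recorded.
    """
    effect = effect or spec.group_col
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != len(covariates):
        raise ValueError("outcome and covariates are misaligned")
    needed = [c for c in spec.all_covariates() if c != "sex"]
    if effect != spec.group_col:
        needed.append(effect)
    num = covariates[needed].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(y) & num.notna().all(axis=1).to_numpy()
    cov = covariates.loc[keep].reset_index(drop=True)
    y = y[keep]
    if y.size == 0:
        raise ValueError("no complete cases")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to model")
    X, names, eff, sites = _design(cov, spec, effect)
    if len(set(sites)) < 2:
        raise ValueError("need at least 2 sites for site random effects")
    # standardize the outcome for optimizer health (AUC outcomes can live
    # at 1e-2 scales); beta and its SE are mapped back, t and p unchanged
    y_sd = float(np.std(y))
    y = y / y_sd

    order = ["slope", "intercept", "ols"]
    start = order.index(spec.random_structure)
    res = None
    used = "ols"
    converged = True
    for structure in order[start:]:
        if structure == "ols":
            break
        exog_re = np.column_stack([np.ones_like(eff), eff]) \
            if structure == "slope" else np.ones((len(eff), 1))
        res, conv, singular = _fit_mixed(y, X, sites, exog_re, spec.reml)
        if res is not None and conv and not singular:
            used = structure
            converged = True
            break
        res = None
    if res is not None:
        beta = float(res.fe_params[1])
        se = float(res.bse_fe[1])
        t = beta / se
        p = float(2 * stats.norm.sf(abs(t)))
        df = float("inf")
    else:
        # site fixed effects
        dummies = pd.get_dummies(pd.Series(sites), drop_first=True, dtype=float)
        Xf = np.column_stack([X, dummies.to_numpy()])
        ols = np.linalg.lstsq(Xf, y, rcond=None)
        resid = y - Xf @ ols[0]
        dof = len(y) - np.linalg.matrix_rank(Xf)
        if dof <= 0:
            raise ValueError("insufficient residual degrees of freedom")
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(Xf.T @ Xf)
        beta = float(ols[0][1])
        se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
        t = beta / se
        p = float(2 * stats.t.sf(abs(t), dof))
        df = float(dof)
        used = "ols"
        converged = True
    beta *= y_sd  # back to the outcome's original units
    return ContrastResult(
        metric=metric, node_id=node_id, beta=beta, t=t, df=df, p=p,
        n_used=int(y.size), converged=converged, random_structure_used=used,
    )


def benjamini_hochberg(pvalues, level: float = 0.05):
    """BH step-up FDR: returns (reject, q-values)."""
    p = np.asarray(pvalues, dtype=float)
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, q


def _results_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [r.metric for r in results],
            "node_id": [r.node_id for r in results],
            "beta": [r.beta for r in results],
            "t": [r.t for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
            "n_used": [r.n_used for r in results],
            "converged": [r.converged for r in results],
            "random_structure_used": [r.random_structure_used for r in results],
        }
    )


def contrast_all_outcomes(
    auc_table: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    fdr_level: float = 0.05,
    effect: str | None = None,
) -> pd.DataFrame:
    """Fit every outcome in a tidy AUC table and apply per-metric FDR.

    ``auc_table`` has columns subject_id, metric, node_id, value, with
    node_id == "GLOBAL" for global metrics. Global metrics form no
    correction family (q = p); each nodal metric is corrected across its
    nodes as one BH family at ``fdr_level``.
    """
    effect = effect or spec.group_col
    cov = covariates.reset_index(drop=True)
    wide = auc_table.pivot_table(
        index="subject_id", columns=["metric", "node_id"], values="value",
        sort=False,
    )
    wide = wide.reindex(cov["subject_id"])
    results: list[ContrastResult] = []
    for metric in auc_table["metric"].unique():
        node_ids = [n for (m, n) in wide.columns if m == metric]
        fam: list[ContrastResult] = []
        for nid in node_ids:
            y = wide[(metric, nid)].to_numpy(float)
            fam.append(
                fit_lme(y, cov, spec, effect=effect, metric=metric, node_id=nid)
            )
        if node_ids == ["GLOBAL"]:
            for r in fam:
                r.q = r.p
                r.significant = bool(r.p < fdr_level)
        else:
            reject, q = benjamini_hochberg([r.p for r in fam], fdr_level)
            for r, rj, qv in zip(fam, reject, q):
                r.q = float(qv)
                r.significant = bool(rj)
        results.extend(fam)
    return _results_frame(results)


_SUBGROUPS = ("FEDN", "recurrent", "unknown", "NC", "MDD")


def _select_subgroup(covariates: pd.DataFrame, label: str) -> pd.DataFrame:
    if label == "NC":
        return covariates[covariates["group"] == "NC"]
    if label == "MDD":
        return covariates[covariates["group"] == "MDD"]
    return covariates[
        (covariates["group"] == "MDD") & (covariates["subtype"] == label)
    ]


def subgroup_contrast(
    auc_table: pd.DataFrame,
    covariates: pd.DataFrame,
    subgroup_a: str,
    subgroup_b: str,
    spec: ModelSpec = ModelSpec(),
    fdr_level: float = 0.05,
    min_per_group: int = 10,
) -> pd.DataFrame:
    """Contrast two subgroups (e.g. FEDN vs NC) with the same machinery.

    ``subgroup_b`` is the reference level. The cohort is restricted to
    the two subsets, the per-site minimum-count filter is re-applied
    within the subset, and a fresh binary contrast column is fit.
    """
    for lab in (subgroup_a, subgroup_b):
        if lab not in _SUBGROUPS:
            raise ValueError(f"unknown subgroup label {lab!r}")
    a = _select_subgroup(covariates, subgroup_a)
    b = _select_subgroup(covariates, subgroup_b)
    if a.empty or b.empty:
        raise ValueError(
            f"subgroup contrast {subgroup_a} vs {subgroup_b}: "
            f"{'both subsets are' if a.empty and b.empty else (subgroup_a if a.empty else subgroup_b) + ' is'} empty"
        )
    sub = pd.concat([a, b]).copy()
    sub["contrast_group"] = np.where(sub.index.isin(a.index), subgroup_a, subgroup_b)
    sub = sub.reset_index(drop=True)
    sub, _dropped = filter_sites(sub, min_per_group, group_col="contrast_group")
    sub_spec = replace(spec, group_col="contrast_group", reference_level=subgroup_b)
    table = auc_table[auc_table["subject_id"].isin(sub["subject_id"])]
    return contrast_all_outcomes(table, sub, sub_spec, fdr_level)


def symptom_association(
    auc_table: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    fdr_level: float = 0.05,
    patients_only: bool = True,
) -> pd.DataFrame:
    """Replace the group term with the HAMD symptom score.

    Restricted to patients by default (controls lack meaningful HAMD).
    The HAMD coefficient carries the site random slope, mirroring the
    group model.
    """
    cov = covariates
    if patients_only:
        cov = cov[cov["group"] == "MDD"]
    cov = cov[pd.to_numeric(cov["hamd"], errors="coerce").notna()]
    if len(cov) < 3:
        raise ValueError("too few subjects with HAMD scores")
    cov = cov.reset_index(drop=True)
    table = auc_table[auc_table["subject_id"].isin(cov["subject_id"])]
    return contrast_all_outcomes(table, cov, spec, fdr_level, effect="hamd")


def map_significant_nodes(
    results: pd.DataFrame, node_set
) -> pd.DataFrame:
    """Tally significant nodes per functional network, with directions.

    Returns one row per (metric, network_label) over the full label
    vocabulary, with counts of significant nodes, split by effect
    direction (negative beta = patients below reference), and the mean
    |t| of significant nodes as an effect-size carry-through.
    """
    from .nodes import NETWORK_LABELS

    label_of = dict(zip(node_set.node_ids, node_set.network_labels))
    nodal = results[results["node_id"] != "GLOBAL"]
    unknown = set(nodal["node_id"]) - set(node_set.node_ids)
    if unknown:
        raise ValueError(f"node ids missing from node set: {sorted(unknown)[:5]}")
    rows = []
    for metric in nodal["metric"].unique():
        sub = nodal[nodal["metric"] == metric]
        sig = sub[sub["significant"].fillna(False)]
        labels = sig["node_id"].map(label_of)
        for lab in NETWORK_LABELS:
            here = sig[labels == lab]
            rows.append(
                {
                    "metric": metric,
                    "network_label": lab,
                    "n_significant": len(here),
                    "n_patient_lower": int((here["beta"] < 0).sum()),
                    "n_patient_higher": int((here["beta"] > 0).sum()),
                    "mean_abs_t": float(here["t"].abs().mean()) if len(here) else 0.0,
                }
            )
    return pd.DataFrame(rows)
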
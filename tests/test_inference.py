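"""Unit tests for site filtering, mixed-model fitting, FDR and network mapping."""

import numpy as np
import pandas as pd
import pytest

from fctopo.inference import (
    ContrastResult,
    ModelSpec,
    benjamini_hochberg,
    contrast_all_outcomes,
    filter_sites,
    fit_lme,
    map_significant_nodes,
    subgroup_contrast,
    symptom_association,
)
from fctopo.nodes import NodeSet

from _oracles import bh_ref


def make_covariates(rng, site_sizes, subtype="unknown", hamd=True):
    """Covariates table for (n_nc, n_mdd) per site, no time series needed."""
    rows = []
    for si, (n_nc, n_mdd) in enumerate(site_sizes):
        for g, n in (("NC", n_nc), ("MDD", n_mdd)):
            for k in range(n):
                rows.append({
                    "subject_id": f"s{si}_{g}_{k}",
                    "site_id": f"site{si}",
                    "group": g,
                    "subtype": subtype if g == "MDD" else "none",
                    "age": rng.uniform(18, 60),
                    "sex": rng.choice(["male", "female"]),
                    "education": rng.uniform(6, 20),
                    "mean_fd": abs(rng.normal(0.1, 0.05)),
                    "hamd": rng.uniform(10, 35) if (g == "MDD" and hamd) else np.nan,
                    "on_medication": bool(rng.random() < 0.4) if g == "MDD" else np.nan,
                })
    return pd.DataFrame(rows)


class TestFilterSites:
    def test_below_threshold_site_removed(self, rng):
        cov = make_covariates(rng, [(12, 9), (15, 15)])
        kept, dropped = filter_sites(cov, 10)
        assert dropped == ["site0"]
        assert set(kept["site_id"]) == {"site1"}

    def test_boundary_site_retained(self, rng):
        cov = make_covariates(rng, [(10, 10)])
        kept, dropped = filter_sites(cov, 10)
        assert dropped == [] and len(kept) == 20

    def test_hand_counted_three_sites(self, rng):
        cov = make_covariates(rng, [(12, 11), (9, 20), (15, 15)])
        kept, dropped = filter_sites(cov, 10)
        assert dropped == ["site1"]
        assert set(kept["site_id"]) == {"site0", "site2"}

    def test_empty_after_filter_raises(self, rng):
        cov = make_covariates(rng, [(3, 3)])
        with pytest.raises(ValueError, match="no sites survive"):
            filter_sites(cov, 10)


class TestFitLME:
    def test_age_slope_recovery_and_null_group(self, rng):
        """Outcome depends on age only: age beta recovered within 5% (mean
        over replicates), group beta centered on zero."""
        spec = ModelSpec(random_structure="intercept")
        true_age = 0.05
        betas_age, betas_grp = [], []
        for _ in range(100):
            cov = make_covariates(rng, [(15, 15)] * 4)
            y = true_age * cov["age"].to_numpy() + rng.normal(0, 0.5, len(cov))
            # fit with age removed from the nuisance list, as the effect
            res = fit_lme(y, cov, ModelSpec(
                covariates=("sex", "education", "mean_fd"),
                random_structure="intercept"), effect="group")
            betas_grp.append(res.beta)
            res_a = fit_lme(y, cov, spec, effect="age")
            betas_age.append(res_a.beta)
        assert abs(np.mean(betas_age) - true_age) < 0.05 * true_age
        assert abs(np.mean(betas_grp)) < 0.02

    def test_permuted_labels_give_symmetric_t(self, rng):
        """Shuffled group labels: t statistics split evenly around zero."""
        signs = []
        for _ in range(100):
            cov = make_covariates(rng, [(12, 12)] * 3)
            cov["group"] = rng.permutation(cov["group"].to_numpy())
            y = rng.normal(size=len(cov))
            try:
                res = fit_lme(y, cov, ModelSpec(random_structure="intercept"))
            except ValueError:  # permutation produced a one-group site split
                continue
            signs.append(np.sign(res.t))
        frac_pos = np.mean(np.array(signs) > 0)
        assert 0.35 < frac_pos < 0.65

    def test_fallback_chain_recorded_and_deterministic(self, rng):
        cov = make_covariates(rng, [(10, 10)] * 4)
        y = rng.normal(size=len(cov))
        r1 = fit_lme(y, cov, ModelSpec(random_structure="slope"))
        r2 = fit_lme(y, cov, ModelSpec(random_structure="slope"))
        assert r1.random_structure_used in ("slope", "intercept", "ols")
        assert r1.random_structure_used == r2.random_structure_used
        assert (r1.beta, r1.t, r1.p) == (r2.beta, r2.t, r2.p)

    def test_detectable_effect_found_by_every_structure(self, rng):
        cov = make_covariates(rng, [(20, 20)] * 4)
        grp = (cov["group"] == "MDD").to_numpy(float)
        y = -1.0 * grp + rng.normal(0, 0.5, len(cov))
        for structure in ("slope", "intercept", "ols"):
            res = fit_lme(y, cov, ModelSpec(random_structure=structure))
            assert res.p < 1e-6 and res.beta < 0
            assert np.sign(res.t) == np.sign(res.beta)

    def test_degenerate_inputs(self, rng):
        cov = make_covariates(rng, [(10, 10)] * 2)
        with pytest.raises(ValueError, match="constant"):
            fit_lme(np.ones(len(cov)), cov)
        nc_only = cov[cov.group == "NC"].reset_index(drop=True)
        with pytest.raises(ValueError, match="single group"):
            fit_lme(rng.normal(size=len(nc_only)), nc_only)
        with pytest.raises(ValueError, match="misaligned"):
            fit_lme(np.ones(3), cov)

    def test_extra_covariate_and_interaction_terms(self, rng):
        """Overall-FC covariate and group-by-sex interaction extend the
        fixed part without disturbing the group effect of interest."""
        cov = make_covariates(rng, [(20, 20)] * 4)
        cov["overall_fc"] = rng.normal(0.3, 0.05, len(cov))
        grp = (cov["group"] == "MDD").to_numpy(float)
        y = -0.8 * grp + 2.0 * cov["overall_fc"].to_numpy() + \
            rng.normal(0, 0.3, len(cov))
        spec = ModelSpec(extra_covariates=("overall_fc",),
                         interactions=("sex",),
                         random_structure="intercept")
        res = fit_lme(y, cov, spec)
        assert res.beta < 0 and res.p < 1e-4

    def test_listwise_deletion_counts(self, rng):
        cov = make_covariates(rng, [(12, 12)] * 2)
        y = rng.normal(size=len(cov))
        y[0] = np.nan
        cov.loc[1, "age"] = np.nan
        res = fit_lme(y, cov, ModelSpec(random_structure="intercept"))
        assert res.n_used == len(cov) - 2


class TestBenjaminiHochberg:
    def test_hand_example(self):
        reject, q = benjamini_hochberg([0.001, 0.02, 0.03, 0.8], 0.05)
        assert reject.sum() == 3
        assert list(reject) == [True, True, True, False]

    def test_all_ones_no_discovery(self):
        reject, q = benjamini_hochberg([1.0] * 5, 0.05)
        assert not reject.any()
        assert np.all(q == 1.0)

    def test_q_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=50)
        _, q = benjamini_hochberg(p, 0.05)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_matches_reference_step_up(self, rng):
        for _ in range(50):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            level = rng.choice([0.01, 0.05, 0.1])
            reject, _ = benjamini_hochberg(p, level)
            assert list(reject) == bh_ref(p, level)


def make_auc_table(rng, cov, metrics_nodes):
    """Tidy AUC table with pure-noise values for the given outcomes."""
    rows = []
    for metric, nodes in metrics_nodes.items():
        for nid in nodes:
            vals = rng.normal(size=len(cov))
            rows.extend(zip(cov["subject_id"], [metric] * len(cov),
                            [nid] * len(cov), vals))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "node_id", "value"])


class TestContrastAllOutcomes:
    def test_families_and_q_rules(self, rng):
        cov = make_covariates(rng, [(12, 12)] * 3)
        node_ids = [f"n{i:04d}" for i in range(8)]
        table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"],
                                          "E_nodal": node_ids})
        res = contrast_all_outcomes(
            table, cov, ModelSpec(random_structure="intercept"), 0.05)
        assert len(res) == 9
        glob = res[res.node_id == "GLOBAL"].iloc[0]
        assert glob.q == glob.p  # global metrics: no family pooling
        nodal = res[res.metric == "E_nodal"]
        reject_ref = bh_ref(nodal["p"].tolist(), 0.05)
        assert nodal["significant"].tolist() == reject_ref

    def test_injected_nodal_effect_detected(self, rng):
        cov = make_covariates(rng, [(15, 15)] * 3)
        node_ids = [f"n{i:04d}" for i in range(6)]
        table = make_auc_table(rng, cov, {"E_nodal": node_ids})
        grp = cov.set_index("subject_id")["group"] == "MDD"
        hit = table["node_id"] == "n0002"
        table.loc[hit, "value"] -= 2.0 * table.loc[hit, "subject_id"].map(grp)
        res = contrast_all_outcomes(
            table, cov, ModelSpec(random_structure="intercept"), 0.05)
        sig = res[res["significant"]]
        assert "n0002" in set(sig["node_id"])
        assert res.set_index("node_id").loc["n0002", "beta"] < 0


class TestSubgroups:
    def test_missing_subgroup_fails_loudly(self, rng):
        cov = make_covariates(rng, [(12, 12)] * 2, subtype="recurrent")
        table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"]})
        with pytest.raises(ValueError, match="FEDN"):
            subgroup_contrast(table, cov, "FEDN", "NC")

    def test_recurrent_only_effect_detected_vs_nc(self, rng):
        cov = make_covariates(rng, [(14, 14)] * 3)
        half = cov.index[(cov.group == "MDD")][::2]
        cov.loc[cov.group == "MDD", "subtype"] = "FEDN"
        cov.loc[half, "subtype"] = "recurrent"
        table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"]})
        rec = cov.set_index("subject_id")["subtype"] == "recurrent"
        table["value"] -= 1.5 * table["subject_id"].map(rec)
        spec = ModelSpec(random_structure="intercept")
        res = subgroup_contrast(table, cov, "recurrent", "NC", spec,
                                min_per_group=5)
        assert res.iloc[0]["p"] < 0.01 and res.iloc[0]["beta"] < 0
        res_f = subgroup_contrast(table, cov, "FEDN", "NC", spec,
                                  min_per_group=5)
        assert res_f.iloc[0]["p"] > res.iloc[0]["p"]


class TestSymptomAssociation:
    def test_hamd_slope_sign_recovered(self, rng):
        hits = 0
        for _ in range(30):
            cov = make_covariates(rng, [(10, 20)] * 3)
            table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"]})
            ham = cov.set_index("subject_id")["hamd"]
            table["value"] = table["value"] * 0.3 - 0.1 * table["subject_id"].map(ham)
            res = symptom_association(table, cov,
                                      ModelSpec(random_structure="intercept"))
            hits += int(res.iloc[0]["beta"] < 0)
        assert hits >= 27

    def test_single_patient_fails(self, rng):
        cov = make_covariates(rng, [(10, 1)] * 1)
        table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"]})
        with pytest.raises(ValueError, match="HAMD"):
            symptom_association(table, cov)

    def test_no_hamd_at_all_fails(self, rng):
        cov = make_covariates(rng, [(10, 10)] * 2, hamd=False)
        table = make_auc_table(rng, cov, {"E_glob": ["GLOBAL"]})
        with pytest.raises(ValueError, match="HAMD"):
            symptom_association(table, cov)


class TestNetworkMapping:
    def _node_set(self, labels):
        n = len(labels)
        return NodeSet(node_ids=[f"n{i:04d}" for i in range(n)],
                       coordinates=np.zeros((n, 3)),
                       network_labels=labels)

    def _results(self, node_ids, sig, betas):
        return pd.DataFrame({
            "metric": ["E_nodal"] * len(node_ids),
            "node_id": node_ids,
            "beta": betas,
            "t": np.sign(betas) * 2.0,
            "df": np.inf,
            "p": [0.01 if s else 0.5 for s in sig],
            "q": [0.02 if s else 0.7 for s in sig],
            "significant": sig,
            "n_used": 100,
            "converged": True,
            "random_structure_used": "slope",
        })

    def test_no_significant_nodes_gives_zero_table(self):
        ns = self._node_set(["VN", "DMN", "SMN"])
        res = self._results(ns.node_ids, [False] * 3, [-1.0, 1.0, -1.0])
        out = map_significant_nodes(res, ns)
        assert (out["n_significant"] == 0).all()
        assert set(out["network_label"]) == set(
            __import__("fctopo.nodes", fromlist=["NETWORK_LABELS"]).NETWORK_LABELS)

    def test_counts_and_directions(self):
        ns = self._node_set(["VN", "VN", "VN", "DMN"])
        res = self._results(ns.node_ids, [True, True, True, False],
                            [-1.0, -2.0, 1.0, -1.0])
        out = map_significant_nodes(res, ns).set_index("network_label")
        assert out.loc["VN", "n_significant"] == 3
        assert out.loc["VN", "n_patient_lower"] == 2
        assert out.loc["VN", "n_patient_higher"] == 1
        assert out["n_significant"].sum() == 3

    def test_unknown_node_rejected(self):
        ns = self._node_set(["VN"])
        res = self._results(["bogus"], [True], [-1.0])
        with pytest.raises(ValueError, match="missing"):
            map_significant_nodes(res, ns)


class TestContrastResultInvariants:
    def test_sign_consistency_enforced(self):
        with pytest.raises(ValueError, match="sign"):
            ContrastResult(metric="m", node_id="GLOBAL", beta=1.0, t=-2.0,
                           df=np.inf, p=0.05)

    def test_p_range_enforced(self):
        with pytest.raises(ValueError, match="p-value"):
            ContrastResult(metric="m", node_id="GLOBAL", beta=1.0, t=2.0,
                           df=np.inf, p=1.5)
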
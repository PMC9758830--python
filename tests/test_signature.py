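import warnings

import numpy as np
import pandas as pd
import pytest

from hetgeo.signature import (
    LowITHSignatureModel,
    SignatureModel,
    SurvivalCohort,
    bootstrap_stability,
    cox_screen,
    evaluate_ith_robustness,
    evaluate_prognosis,
    filter_low_ith,
    fit_signature_weights,
    forest_combination_search,
    score,
    univariate_cox_table,
)
from hetgeo.synthio import SimConfig, generate_cohort


def make_survival_cohort(name, seed, n_patients=100, n_genes=20,
                         effects=None, censoring=0.3):
    """Per-patient cohort built from a synthetic multi-region cohort."""
    cfg = SimConfig(
        n_patients=n_patients, regions_per_patient=2, n_genes=n_genes,
        survival_effects=effects or {}, censoring_rate=censoring, seed=seed,
    )
    c = generate_cohort(cfg)
    per_patient = np.log2(c.expression + 1.0).T.groupby(c.patients).mean().T
    return SurvivalCohort(
        name=name, expression=per_patient,
        time=c.survival["time"], event=c.survival["event"],
    )


@pytest.fixture(scope="module")
def trio():
    """Three training cohorts sharing one strong risk and one protective gene."""
    effects = {"g00000": 1.2, "g00001": -1.2}
    return [make_survival_cohort(f"c{i}", 30 + i, n_patients=150, effects=effects)
            for i in range(3)]


class TestFilterLowITH:
    def test_strict_threshold_boundary(self):
        ihs = pd.Series({"a": 0.1, "b": 0.25, "c": 0.4})
        assert filter_low_ith(ihs) == ["a"]

    def test_all_high_ihs_errors(self):
        ihs = pd.Series({"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError, match="relax"):
            filter_low_ith(ihs)

    def test_low_ratio_genes_recovered_from_truth(self, recovery_cohort, recovery_ihs):
        truth = recovery_cohort.truth
        truly_low = truth.index[truth["r_g"] < 0.1]
        kept = set(filter_low_ith(recovery_ihs.table))
        rate = np.mean([g in kept for g in truly_low])
        assert rate >= 0.8


class TestCoxScreen:
    def test_effect_genes_recovered_with_direction(self, trio):
        genes = list(trio[0].expression.index)
        res = cox_screen(trio, genes)
        assert "g00000" in res.risk
        assert "g00001" in res.protective

    def test_constant_gene_flagged_non_estimable(self, trio):
        c = trio[0]
        expr = c.expression.copy()
        expr.loc["flat"] = 1.0
        mod = SurvivalCohort(name="flat", expression=expr, time=c.time, event=c.event)
        t = univariate_cox_table(mod, ["flat", "g00000"])
        assert not t.loc["flat", "estimable"]
        assert t.loc["g00000", "estimable"]

    def test_score_method_agrees_with_full_fit_direction(self, trio):
        genes = ["g00000", "g00001", "g00005"]
        full = univariate_cox_table(trio[0], genes, method="full")
        fast = univariate_cox_table(trio[0], genes, method="score")
        for g in ["g00000", "g00001"]:
            assert np.sign(np.log(full.loc[g, "HR"])) == np.sign(np.log(fast.loc[g, "HR"]))
            assert fast.loc[g, "p"] < 0.05


class TestBootstrap:
    def test_overwhelming_effect_saturates(self, trio):
        stable, counts = bootstrap_stability(
            trio, ["g00000", "g00001"], n_boot=25, seed=0)
        assert counts["g00000"] == 25
        assert set(stable) == {"g00000", "g00001"}

    def test_null_gene_rarely_passes(self, trio):
        _, counts = bootstrap_stability(trio, ["g00010"], n_boot=40, seed=1)
        # p < 0.05 with a fixed direction in all three cohorts is very rare
        assert counts["g00010"] <= 4

    def test_seed_determinism(self, trio):
        _, c1 = bootstrap_stability(trio, ["g00000", "g00002"], n_boot=15, seed=42)
        _, c2 = bootstrap_stability(trio, ["g00000", "g00002"], n_boot=15, seed=42)
        assert c1.equals(c2)


class TestForestSearch:
    def test_informative_genes_selected(self, trio):
        pool = ["g00000", "g00001"] + [f"g{i:05d}" for i in range(2, 10)]
        res = forest_combination_search(trio, pool, n_replicates=2, n_trees=60,
                                        max_subset=6, seed=3)
        assert {"g00000", "g00001"} <= set(res.genes)
        assert res.best_concordance > 0.55
        assert not res.low_confidence

    def test_fixed_seed_deterministic(self, trio):
        pool = ["g00000", "g00001", "g00002", "g00003"]
        a = forest_combination_search(trio, pool, n_replicates=1, n_trees=40, seed=5)
        b = forest_combination_search(trio, pool, n_replicates=1, n_trees=40, seed=5)
        assert a.genes == b.genes
        assert a.subset_scores.equals(b.subset_scores)

    def test_too_few_genes_rejected(self, trio):
        with pytest.raises(ValueError, match="at least 2"):
            forest_combination_search(trio, ["g00000"], seed=0)


class TestScore:
    def _model(self, genes, weights):
        return SignatureModel(
            genes=genes,
            weights=weights,
            directions={g: ("risk" if w >= 0 else "protective")
                        for g, w in weights.items()},
        )

    def test_zero_weights_constant_score(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.uniform(1, 10, (2, 6)), index=["a", "b"],
                            columns=[f"s{i}" for i in range(6)])
        m = self._model(["a", "b"], {"a": 0.0, "b": 0.0})
        assert np.allclose(score(m, expr), 0.0)

    def test_single_gene_unit_weight_is_zscore(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(1, 10, (1, 8)), index=["a"],
                            columns=[f"s{i}" for i in range(8)])
        m = self._model(["a"], {"a": 1.0})
        x = expr.loc["a"]
        z = (x - x.mean()) / x.std(ddof=0)
        assert np.allclose(score(m, expr), z)

    def test_missing_genes_listed(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s0", "s1"])
        m = self._model(["a", "zz"], {"a": 1.0, "zz": 1.0})
        with pytest.raises(ValueError, match="zz"):
            score(m, expr)

    def test_weight_sign_must_match_direction(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SignatureModel(genes=["a"], weights={"a": -1.0},
                           directions={"a": "risk"})

    def test_reproduces_cox_linear_predictor(self, trio):
        genes = ["g00000", "g00001"]
        weights = fit_signature_weights(trio, genes)
        m = self._model(genes, weights)
        c = trio[0]
        s = score(m, c.expression)
        z = c.zscored(genes)
        expected = z.to_numpy() @ np.array([weights[g] for g in genes])
        assert np.allclose(s.to_numpy(), expected, atol=1e-10)

    def test_invariant_to_gene_order_and_extra_genes(self, trio):
        genes = ["g00000", "g00001"]
        weights = fit_signature_weights(trio, genes)
        c = trio[0]
        m1 = self._model(genes, weights)
        m2 = self._model(genes[::-1], weights)
        s1 = score(m1, c.expression)
        s2 = score(m2, c.expression.iloc[::-1])
        assert np.allclose(s1, s2)


class TestEvaluateRisk:
    def test_null_signature_auc_near_half(self):
        c = make_survival_cohort("null", 77, n_patients=250, n_genes=6)
        m = SignatureModel(genes=["g00002"], weights={"g00002": 1.0},
                           directions={"g00002": "risk"})
        ev = evaluate_prognosis(m, [c], eval_years=(1, 2))
        assert abs(ev.loc["null", "mean_auc"] - 0.5) < 0.12

    def test_perfect_marker_auc_one(self):
        rng = np.random.default_rng(5)
        n = 60
        time = pd.Series(rng.uniform(1, 100, n),
                         index=[f"p{i}" for i in range(n)])
        event = pd.Series(1, index=time.index)
        # expression exactly anti-ordered with survival time
        expr = pd.DataFrame([-time.to_numpy()], index=["g"], columns=time.index) + 200
        c = SurvivalCohort(name="perfect", expression=expr, time=time,
                           event=event, time_unit="months")
        m = SignatureModel(genes=["g"], weights={"g": 1.0},
                           directions={"g": "risk"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = evaluate_prognosis(m, [c], eval_years=(1, 2, 3))
        assert ev.loc["perfect", "mean_auc"] > 0.99

    def test_auc_grows_with_effect_size(self):
        aucs = []
        for beta in (0.0, 0.5, 1.2):
            c = make_survival_cohort(f"b{beta}", 55, n_patients=200, n_genes=5,
                                     effects={"g00000": beta})
            m = SignatureModel(genes=["g00000"], weights={"g00000": 1.0},
                               directions={"g00000": "risk"})
            ev = evaluate_prognosis(m, [c], eval_years=(1, 2, 3))
            aucs.append(float(ev["mean_auc"].iloc[0]))
        assert aucs[0] < aucs[1] < aucs[2]
        assert aucs[2] > 0.65


class TestITHRobustness:
    def test_zero_ith_signature_fully_concordant(self):
        cfg = SimConfig(n_patients=6, regions_per_patient=4, n_genes=12,
                        sigma_within=0.0, sigma_between=1.5, seed=13)
        c = generate_cohort(cfg)
        genes = list(c.expression.index[:4])
        m = SignatureModel(genes=genes, weights={g: 1.0 for g in genes},
                           directions={g: "risk" for g in genes})
        ihs = pd.Series(0.0, index=c.expression.index)
        res = evaluate_ith_robustness(m, c.expression, c.patients, ihs)
        assert res.discordant_proportion == 0.0
        assert res.pgor_auc == pytest.approx(res.n_patients - 1)

    def test_structure_free_signature_discordant(self):
        rng = np.random.default_rng(21)
        samples = [f"s{i}" for i in range(40)]
        pats = pd.Series(np.repeat([f"p{i}" for i in range(10)], 4), index=samples)
        expr = pd.DataFrame(rng.uniform(1, 100, (6, 40)),
                            index=[f"g{i}" for i in range(6)], columns=samples)
        m = SignatureModel(genes=list(expr.index),
                           weights={g: 1.0 for g in expr.index},
                           directions={g: "risk" for g in expr.index})
        ihs = pd.Series(0.9, index=expr.index)
        res = evaluate_ith_robustness(m, expr, pats, ihs)
        assert res.discordant_proportion > 0.4
        assert res.pgor_auc < 0.6 * (res.n_patients - 1)

    def test_missing_genes_warn_and_intersect(self):
        cfg = SimConfig(n_patients=4, regions_per_patient=3, n_genes=6,
                        sigma_within=0.0, seed=2)
        c = generate_cohort(cfg)
        genes = list(c.expression.index[:2]) + ["absent"]
        m = SignatureModel(genes=genes,
                           weights={g: 1.0 for g in genes},
                           directions={g: "risk" for g in genes})
        ihs = pd.Series(0.1, index=c.expression.index)
        with pytest.warns(UserWarning, match="absent"):
            res = evaluate_ith_robustness(m, c.expression, c.patients, ihs)
        assert np.isfinite(res.median_signature_ihs)


class TestEndToEnd:
    def test_pipeline_recovers_effect_genes_and_is_deterministic(self, trio):
        ihs = pd.Series(0.1, index=trio[0].expression.index)
        builder = LowITHSignatureModel(
            trio, ihs, n_boot=20, n_replicates=1, n_trees=40, max_subset=4,
            screen_method="full",
        )
        r1 = builder.fit(seed=7)
        r2 = builder.fit(seed=7)
        assert {"g00000", "g00001"} <= set(r1.model.genes)
        assert r1.model.genes == r2.model.genes
        assert r1.model.weights == r2.model.weights
        assert "signature size" in r1.summary()

    def test_model_json_roundtrip(self, trio, tmp_path):
        genes = ["g00000", "g00001"]
        weights = fit_signature_weights(trio, genes)
        m = SignatureModel(
            genes=genes, weights=weights,
            directions={g: ("risk" if weights[g] >= 0 else "protective")
                        for g in genes},
        )
        m.to_json(tmp_path / "model.json")
        back = SignatureModel.from_json(tmp_path / "model.json")
        assert back == m
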
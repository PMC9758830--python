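import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetgeo.diversity import (
    DiversityModel,
    PCAEmbedding,
    classify_ith,
    concordance_classify,
    dispersion_from_scores,
    distance_correlation,
    fit_pca,
    genomic_distance,
    genomic_diversity,
    normalized_diversity,
    transcriptomic_distance,
    transcriptomic_diversity,
)


def make_embedding(scores: np.ndarray, samples):
    return PCAEmbedding(
        scores=pd.DataFrame(scores, index=samples,
                            columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        explained_variance=np.ones(scores.shape[1]),
        n_pcs=scores.shape[1],
    )


class TestPCA:
    def make_inputs(self, n_samples=8, n_genes=50, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        mat = rng.uniform(0, 100, (n_genes, n_samples))
        if identical:
            mat = np.tile(mat[:, [0]], (1, n_samples))
        expr = pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n_samples)])
        meta = pd.DataFrame({"patient_id": "p", "tissue": "tumor"}, index=expr.columns)
        return expr, meta

    def test_identical_samples_give_equal_scores(self):
        expr, meta = self.make_inputs(identical=True)
        emb = fit_pca(expr, meta, n_pcs=3, gene_filter=False)
        assert np.allclose(emb.scores.to_numpy(), emb.scores.to_numpy()[[0]], atol=1e-9)

    def test_explained_variance_non_increasing(self):
        expr, meta = self.make_inputs(n_samples=20)
        emb = fit_pca(expr, meta, n_pcs=15, gene_filter=False)
        assert emb.scores.shape == (20, 15)
        assert (np.diff(emb.explained_variance) <= 1e-9).all()

    def test_matches_eigendecomposition_up_to_sign(self):
        expr, meta = self.make_inputs(n_samples=6, n_genes=50, seed=3)
        emb = fit_pca(expr, meta, n_pcs=4, gene_filter=False)
        x = np.log2(expr.to_numpy().T + 1.0)
        xc = x - x.mean(axis=0)
        cov = xc @ xc.T / 1.0
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        # reconstruct scores from the sample-space eigenvectors
        expected = evecs[:, order[:4]] * np.sqrt(evals[order[:4]])
        got = emb.scores.to_numpy()
        for j in range(4):
            assert np.allclose(got[:, j], expected[:, j], atol=1e-8) or np.allclose(
                got[:, j], -expected[:, j], atol=1e-8
            )

    def test_too_few_samples_errors_with_hint(self):
        expr, meta = self.make_inputs(n_samples=5)
        with pytest.raises(ValueError, match="smaller n_pcs"):
            fit_pca(expr, meta, n_pcs=15, gene_filter=False)

    def test_clip_option_warns_instead(self):
        expr, meta = self.make_inputs(n_samples=5)
        with pytest.warns(UserWarning, match="clipping"):
            emb = fit_pca(expr, meta, n_pcs=15, gene_filter=False, clip_n_pcs=True)
        assert emb.n_pcs == 4


class TestTranscriptomicDiversity:
    def test_two_regions_half_distance(self):
        scores = np.array([[0.0, 0.0], [3.0, 4.0]])
        emb = make_embedding(scores, ["a", "b"])
        patients = pd.Series({"a": "T1", "b": "T1"})
        assert transcriptomic_diversity(emb, patients, "T1") == pytest.approx(2.5)

    def test_identical_regions_zero(self):
        emb = make_embedding(np.ones((4, 3)), list("abcd"))
        patients = pd.Series("T1", index=list("abcd"))
        assert transcriptomic_diversity(emb, patients, "T1") == 0.0

    def test_matches_printed_formula_brute_force(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(5, 15))
        mu = scores.mean(axis=0)
        expected = np.mean([np.sqrt(((s - mu) ** 2).sum()) for s in scores])
        emb = make_embedding(scores, [f"s{i}" for i in range(5)])
        patients = pd.Series("T1", index=emb.samples)
        assert transcriptomic_diversity(emb, patients, "T1") == pytest.approx(expected)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(6, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        assert dispersion_from_scores(scores @ q) == pytest.approx(
            dispersion_from_scores(scores)
        )

    def test_single_region_errors(self):
        emb = make_embedding(np.zeros((1, 2)), ["a"])
        with pytest.raises(ValueError, match=">= 2"):
            transcriptomic_diversity(emb, pd.Series({"a": "T1"}), "T1")


class TestGenomicDistance:
    def test_identical_sets(self):
        assert genomic_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_sets(self):
        assert genomic_distance({"a"}, {"b"}) == 1.0

    def test_partial_overlap(self):
        assert genomic_distance({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(0.5)

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert genomic_distance(set(), set()) == 0.0

    def test_diversity_median_of_three(self):
        # sets engineered to give pairwise distances 0.2, 0.4, 0.6... use median check
        sets = {"r1": {1, 2, 3, 4, 5}, "r2": {1, 2, 3, 4, 6}, "r3": {1, 2, 7, 8, 9}}
        pairs = [genomic_distance(sets[a], sets[b])
                 for a, b in [("r1", "r2"), ("r1", "r3"), ("r2", "r3")]]
        assert genomic_diversity(sets) == pytest.approx(np.median(pairs))

    def test_diversity_matches_enumeration_on_five_regions(self):
        rng = np.random.default_rng(5)
        sets = {f"r{i}": set(rng.choice(30, size=12, replace=False)) for i in range(5)}
        pairs = []
        regions = sorted(sets)
        for i in range(5):
            for j in range(i + 1, 5):
                pairs.append(genomic_distance(sets[regions[i]], sets[regions[j]]))
        assert len(pairs) == 10
        assert genomic_diversity(sets) == pytest.approx(np.median(pairs))


class TestTranscriptomicDistance:
    def test_identical_profiles(self):
        a = pd.Series([1.0, 5.0, 2.0], index=list("xyz"))
        assert transcriptomic_distance(a, a) == pytest.approx(0.0)

    def test_rank_reversed_profiles(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("wxyz"))
        assert transcriptomic_distance(a, b) == pytest.approx(2.0)

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(2)
        idx = [f"g{i}" for i in range(40)]
        a = pd.Series(rng.uniform(0, 50, 40), index=idx)
        b = pd.Series(rng.uniform(0, 50, 40), index=idx)
        rho = stats.spearmanr(np.log2(a + 1), np.log2(b + 1)).statistic
        assert transcriptomic_distance(a, b) == pytest.approx(1 - rho)

    def test_constant_profile_rejected(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("xyz"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        with pytest.raises(ValueError, match="constant"):
            transcriptomic_distance(a, b)


class TestDistanceCorrelation:
    def _mats(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 5, (n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        idx = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=idx, columns=idx)

    def test_identity_gives_rho_one(self):
        m = self._mats()
        df = distance_correlation({"T1": m}, {"T1": m})
        assert df.loc["T1", "rho"] == pytest.approx(1.0)
        assert df.loc["T1", "strong_trend"]

    def test_independent_matrices_near_zero(self):
        phys = self._mats(n=40, seed=1)
        mol = self._mats(n=40, seed=2)
        rho, p, n = distance_correlation({"T1": phys}, {"T1": mol}, scope="pooled")
        assert abs(rho) < 0.15
        assert n == 40 * 39 // 2

    def test_too_few_pairs_reported_missing(self):
        m = self._mats(n=2)
        df = distance_correlation({"T1": m}, {"T1": m})
        assert np.isnan(df.loc["T1", "rho"])


class TestNormalizedScoreAndClasses:
    def test_ratio_arithmetic(self):
        assert normalized_diversity(0.6, 1.2) == pytest.approx(0.5)
        assert normalized_diversity(0.0, 3.0) == 0.0

    def test_zero_physical_diversity_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            normalized_diversity(1.0, 0.0)

    def test_coordinate_scaling_halves_score(self):
        assert normalized_diversity(1.0, 2.0) == pytest.approx(
            normalized_diversity(1.0, 1.0) / 2.0
        )

    def test_median_split(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        out = classify_ith(s)
        assert out.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_warns_all_low(self):
        s = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        with pytest.warns(UserWarning):
            assert (classify_ith(s) == "low").all()

    def test_even_cohort_splits_in_half(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.uniform(size=14), index=[f"t{i}" for i in range(14)])
        out = classify_ith(s)
        assert (out == "low").sum() == 7
        assert (out == "high").sum() == 7

    def test_concordance_uniform_and_discordant(self):
        scores = pd.Series({"a1": 0.1, "a2": 0.2, "b1": 0.9, "b2": 0.8,
                            "c1": 0.15, "c2": 0.85})
        patients = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                              "c1": "C", "c2": "C"})
        labels, prop = concordance_classify(scores, patients)
        assert labels["A"] == "uniformly_low"
        assert labels["B"] == "uniformly_high"
        assert labels["C"] == "discordant"
        assert prop == pytest.approx(1 / 3)


class TestDiversityModel:
    def test_fit_produces_consistent_table(self, small_cohort):
        c = small_cohort
        res = DiversityModel(c.expression, c.meta, c.coords, variants=c.mutations,
                             n_pcs=15).fit()
        t = res.table
        assert len(t) == 8
        assert np.allclose(t["normalized"], t["div_t"] / t["div_p"])
        assert set(t["ith_class"]) <= {"low", "high"}
        assert t["genomic_div"].between(0, 1).all()
        assert "median Div" in res.summary().replace("(t):", " Div")

    def test_pooled_transcriptomic_correlation_positive(self, small_cohort):
        c = small_cohort
        res = DiversityModel(c.expression, c.meta, c.coords, n_pcs=15).fit()
        rho, p, n = res.distance_correlations("transcriptomic", scope="pooled")
        assert rho > 0.3
        assert p < 0.01
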
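import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronomics import coexpression as cx
from chronomics.datamodel import DiffTable, OmicsMatrix, ValidationError
from tests.conftest import make_matrix


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        assert cx.bicor(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert cx.bicor(x, -x) == pytest.approx(-1.0)

    def test_agrees_with_pearson_on_gaussian_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = 0.6 * x + 0.8 * rng.normal(size=1000)
        b = cx.bicor(x, y)
        p = np.corrcoef(x, y)[0, 1]
        assert abs(b - p) < 0.05

    def test_constant_vector_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        x = np.full(20, 3.0)
        x[0] = 3.5  # zero MAD but non-constant
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="Pearson"):
            cx.bicor(x, y)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 40))
        C = cx.bicor_matrix(X)
        for i in range(6):
            for j in range(i):
                assert C[i, j] == pytest.approx(cx.bicor(X[i], X[j]),
                                                abs=1e-12)
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestTom:
    def test_triangle_hand_computed(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = cx.tom_similarity(a)
        # l = 1, k = 2: (1 + 1) / (2 + 1 - 1) = 1
        np.testing.assert_allclose(tom, np.ones((3, 3)))

    def test_isolated_edge_hand_computed(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        tom = cx.tom_similarity(a)
        # l = 0, k = 1: (0 + 1) / (1 + 1 - 1) = 1
        assert tom[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.0
        a[2, 3] = a[3, 2] = 1.0
        tom = cx.tom_similarity(a)
        assert tom[0, 1] == 0.0

    def test_bounded_on_random_adjacencies(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(3, 15)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = cx.tom_similarity(a)
            assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            cx.tom_similarity(a)


class TestSoftThreshold:
    def test_smallest_power_above_fit_threshold(self, study):
        genes = study.transcript.values.iloc[:400]
        corr = cx.bicor_matrix(genes.to_numpy())
        beta, diag = cx.pick_soft_threshold(corr, candidates=range(1, 21))
        passing = diag[diag["signed_fit"] > 0.85]
        if len(passing):
            assert beta == int(passing["beta"].iloc[0])
        else:
            assert beta == int(diag.loc[diag["signed_fit"].idxmax(), "beta"])

    def test_power_law_degree_distribution_scores_high(self):
        # expected-degree (Chung-Lu style) graph with k ~ power law
        rng = np.random.default_rng(0)
        k = 0.5 * (np.arange(1, 301) ** -0.8) * 300
        w = np.sqrt(k / k.sum()) * np.sqrt(k.sum())
        a = np.outer(w, w) / k.sum() * k.sum() / w.sum() ** 0.0
        a = np.outer(k, k) / k.sum()
        a = np.clip(a, 0, 1)
        np.fill_diagonal(a, 0.0)
        fit, slope = cx.scale_free_fit(a)
        assert slope < 0
        assert fit > 0.9

    def test_too_few_features_rejected(self):
        with pytest.raises(ValidationError):
            cx.pick_soft_threshold(np.eye(5))


class TestDetectModules:
    def test_noiseless_planted_modules_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        from chronomics import SyntheticSpec, generate_study
        from chronomics.synthetic import noiseless_spec
        # background-free: a noiseless background gene is constant, which
        # has no defined correlation
        spec = noiseless_spec(SyntheticSpec(
            seed=4, n_genes=285, n_mirna=0,
            module_sizes=(60, 50, 40, 30, 25, 20, 20, 20, 20),
            planted_enriched=(), n_background_de=0))
        s = generate_study(spec)
        net = cx.build_network(s.transcript, beta=24, min_module_size=20)
        truth = [s.truth.module_of[g] or "grey"
                 for g in s.transcript.feature_ids]
        pred = [net.modules[g] for g in s.transcript.feature_ids]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)
        assert len(net.module_labels) == 9

    def test_all_identical_features_single_module(self):
        tom = np.ones((30, 30))
        mods, _ = cx.detect_modules(tom, [f"g{i}" for i in range(30)],
                                    min_module_size=20)
        assert len(set(mods.values())) == 1
        assert set(mods.values()) != {"grey"}

    def test_permutation_invariance_up_to_labels(self, study):
        genes = study.transcript.values.iloc[:300]
        corr = cx.bicor_matrix(genes.to_numpy())
        adj = cx.signed_adjacency(corr, 24)
        tom = cx.tom_similarity(adj)
        ids = list(genes.index)
        mods, _ = cx.detect_modules(tom, ids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ids))
        mods_p, _ = cx.detect_modules(tom[np.ix_(perm, perm)],
                                      [ids[i] for i in perm])
        from sklearn.metrics import adjusted_rand_score
        a = [mods[g] for g in ids]
        b = [mods_p[g] for g in ids]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestEigengene:
    def test_identical_features_give_shared_profile(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=20)
        m = make_matrix(np.tile(prof, (5, 1)))
        me = cx.module_eigengene(m, m.feature_ids)
        std = (prof - prof.mean()) / prof.std()
        np.testing.assert_allclose(me.to_numpy(),
                                   std / np.linalg.norm(std), atol=1e-10)
        assert np.corrcoef(me, prof)[0, 1] == pytest.approx(1.0)

    def test_two_feature_matches_explicit_eigensolve(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 15))
        m = make_matrix(X)
        me = cx.module_eigengene(m, m.feature_ids).to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1,
                                                         keepdims=True)
        evals, evecs = np.linalg.eigh(Xs.T @ Xs)
        v = evecs[:, -1]
        if np.dot(v, Xs.mean(axis=0)) < 0:
            v = -v
        np.testing.assert_allclose(me, v, atol=1e-10)

    def test_negation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 12))
        m1 = make_matrix(X)
        m2 = make_matrix(-X)
        me1 = cx.module_eigengene(m1, m1.feature_ids)
        me2 = cx.module_eigengene(m2, m2.feature_ids)
        np.testing.assert_allclose(me1.to_numpy(), -me2.to_numpy(),
                                   atol=1e-10)

    def test_unit_norm_and_positive_mean_correlation(self, study):
        genes = study.transcript.subset_features(
            [f for f in study.transcript.feature_ids
             if study.truth.module_of.get(f) == "M3"])
        me = cx.module_eigengene(genes, genes.feature_ids)
        assert np.linalg.norm(me) == pytest.approx(1.0)
        mean_expr = genes.values.mean(axis=0)
        assert np.corrcoef(me, mean_expr)[0, 1] > 0


def diff_for(features, lfc_by_stage):
    out = []
    for stage, lfc in lfc_by_stage.items():
        t = pd.DataFrame({"feature": features, "log2_fc": lfc,
                          "t_stat": 0.0, "p_raw": 0.5, "p_adj": 0.5,
                          "call": "ns"})
        out.append(DiffTable(t, condition=stage, control="C0",
                             layer="transcript"))
    return out


class TestRelevance:
    def test_strong_uniform_shift_flagged(self):
        feats = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        diffs = diff_for(feats, {
            "D1": np.full(30, 2.0) + rng.normal(0, 0.01, 30),
            "D7": rng.normal(0, 0.01, 30),
            "D11": rng.normal(0, 0.01, 30),
        })
        recs = cx.module_relevance(diffs, {f: "blue" for f in feats})
        by = {(r.module, r.stage): r for r in recs}
        assert by[("blue", "D1")].relevant
        assert by[("blue", "D1")].direction == "up"
        assert not by[("blue", "D7")].relevant

    def test_sub_threshold_median_never_relevant(self):
        feats = [f"g{i}" for i in range(30)]
        diffs = diff_for(feats, {
            "D1": np.full(30, 0.5), "D7": np.full(30, -0.5)})
        recs = cx.module_relevance(diffs, {f: "blue" for f in feats})
        assert not any(r.relevant for r in recs)

    def test_module_missing_from_diff_skipped_with_warning(self):
        diffs = diff_for(["g1", "g2"], {"D1": [0.0, 0.0],
                                        "D7": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="absent"):
            recs = cx.module_relevance(diffs, {"zz1": "red", "zz2": "red"})
        assert recs == []


class TestFeatureCorrelation:
    def test_feature_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        me = pd.DataFrame({"blue": rng.normal(size=14)},
                          index=[f"c{i}" for i in range(14)])
        fp = pd.DataFrame([me["blue"].to_numpy()], index=["prot1"],
                          columns=me.index)
        recs = cx.correlate_features(me, fp, "protein")
        assert recs[0].r == pytest.approx(1.0)
        assert recs[0].significant

    def test_p_value_closed_form_r071_n14(self):
        # construct a pair with r almost exactly 0.71 over 14 conditions
        rng = np.random.default_rng(5)
        x = rng.normal(size=14)
        y = rng.normal(size=14)
        xs = (x - x.mean()) / x.std()
        resid = y - np.polyval(np.polyfit(xs, y, 1), xs)
        r_target = 0.71
        ys = r_target * xs + np.sqrt(1 - r_target ** 2) * \
            (resid / resid.std())
        me = pd.DataFrame({"m": xs}, index=[f"c{i}" for i in range(14)])
        fp = pd.DataFrame([ys], index=["f"], columns=me.index)
        rec = cx.correlate_features(me, fp, "protein")[0]
        assert rec.r == pytest.approx(0.71, abs=1e-6)
        t = 0.71 * np.sqrt(12 / (1 - 0.71 ** 2))
        assert rec.p == pytest.approx(2 * stats.t.sf(t, 12), rel=1e-6)
        assert rec.p == pytest.approx(0.0045, abs=5e-4)
        assert not rec.significant  # above the 0.001 gate

    def test_p_values_match_permutation_null(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=14)
        y = rng.normal(size=14)
        me = pd.DataFrame({"m": x}, index=[f"c{i}" for i in range(14)])
        fp = pd.DataFrame([y], index=["f"], columns=me.index)
        rec = cx.correlate_features(me, fp, "protein")[0]
        n_perm = 10000
        robs = abs(np.corrcoef(x, y)[0, 1])
        hits = 0
        for _ in range(n_perm):
            hits += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= robs
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert rec.p == pytest.approx(p_perm, abs=4 * se + 1e-4)

    def test_too_few_conditions_rejected(self):
        me = pd.DataFrame({"m": [1.0, 2, 3]}, index=["a", "b", "c"])
        fp = pd.DataFrame([[1.0, 2, 3]], index=["f"],
                          columns=["a", "b", "c"])
        with pytest.raises(ValidationError, match="4"):
            cx.correlate_features(me, fp, "protein")

    def test_planted_regulator_negative_correlation(self, study):
        # one planted miRNA regulator: significant negative r with its
        # module eigengene at condition-mean resolution
        truth = study.truth
        mid, (mod, sign) = next(iter(truth.regulator_of.items()))
        genes = [g for g, m in truth.module_of.items() if m == mod]
        sub = study.transcript.subset_features(genes)
        me = cx.module_eigengene(sub, genes)
        me_cond = OmicsMatrix("transcript", pd.DataFrame({"me": me}).T) \
            .condition_means(study.sheet)
        mir = study.transcript.subset_features([mid]) \
            .condition_means(study.sheet)
        rec = cx.correlate_features(me_cond.T, mir, "miRNA")[0]
        assert rec.r < -0.4
        assert rec.significant


class TestClusterFeatures:
    def test_anticorrelated_groups_split(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=14)
        rows = [base + rng.normal(0, 0.05, 14) for _ in range(4)] + \
               [-base + rng.normal(0, 0.05, 14) for _ in range(4)]
        fp = pd.DataFrame(rows, index=[f"f{i}" for i in range(8)])
        labels = cx.cluster_features(fp, k=2)
        g1 = {labels[f"f{i}"] for i in range(4)}
        g2 = {labels[f"f{i}"] for i in range(4, 8)}
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2

    def test_k_reduced_when_exceeding_features(self):
        rng = np.random.default_rng(1)
        fp = pd.DataFrame(rng.normal(size=(3, 10)),
                          index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="reduced"):
            labels = cx.cluster_features(fp, k=10)
        assert set(labels.values()) <= {"A", "B", "C"}

    def test_identical_features_share_cluster(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        rows = [base, base] + [rng.normal(size=10) for _ in range(5)]
        fp = pd.DataFrame(rows, index=[f"f{i}" for i in range(7)])
        labels = cx.cluster_features(fp, k=4)
        assert labels["f0"] == labels["f1"]

    def test_labels_follow_dendrogram_leaf_order(self):
        rng = np.random.default_rng(3)
        fp = pd.DataFrame(rng.normal(size=(12, 14)),
                          index=[f"f{i}" for i in range(12)])
        labels = cx.cluster_features(fp, k=5)
        assert set(labels.values()) == {"A", "B", "C", "D", "E"}
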
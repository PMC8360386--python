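import warnings

import numpy as np
import pandas as pd
import pytest

from chronomics import proteome_prep as pp
from chronomics.datamodel import OmicsMatrix, ValidationError
from tests.conftest import make_matrix

PCOLS = ["C0_pro1", "C0_pro2", "C0_pro3", "D1_pro1", "D1_pro2", "D1_pro3"]


def protein_matrix(values):
    return make_matrix(values, layer="protein", prefix="P", columns=PCOLS)


class TestFilterQuantified:
    def test_complete_in_one_condition_kept(self, toy_sheet):
        nan = np.nan
        m = protein_matrix([
            [1.0, 2, 3, nan, nan, nan],   # complete in C0 -> kept
            [1.0, nan, 3, 1, 2, nan],     # 2/3 everywhere -> removed
            [nan, nan, nan, 4, 5, 6],     # complete in D1 -> kept
            [nan, nan, nan, nan, nan, 6],
            [1.0, 2, 3, 4, 5, 6],         # fully complete -> kept
        ])
        out = pp.filter_quantified(m, toy_sheet, 3)
        assert out.feature_ids == ["P1", "P3", "P5"]

    def test_excessive_requirement_rejected(self, toy_sheet):
        m = protein_matrix(np.ones((2, 6)))
        with pytest.raises(ValidationError, match="min_complete_reps"):
            pp.filter_quantified(m, toy_sheet, 4)

    def test_wrong_layer_rejected(self, toy_sheet):
        m = make_matrix(np.ones((2, 6)), layer="transcript", columns=PCOLS)
        with pytest.raises(ValidationError, match="protein"):
            pp.filter_quantified(m, toy_sheet, 3)


class TestNormalize:
    def test_log2_median_centering_by_hand(self):
        m = protein_matrix(np.tile([[1.0], [4.0], [16.0]], (1, 6)))
        out = pp.normalize_protein(m)
        np.testing.assert_allclose(out.values["C0_pro1"], [-2.0, 0.0, 2.0])

    def test_idempotent_on_centered_log_data(self):
        vals = np.array([[-1.0, 0.5], [0.0, -0.5], [1.0, 0.5],
                         [0.0, -0.5], [0.5, 0.0]])
        m = OmicsMatrix("protein",
                        pd.DataFrame(2.0 ** vals, columns=["a", "b"],
                                     index=list("vwxyz")))
        out = pp.normalize_protein(m)
        np.testing.assert_allclose(out.values.to_numpy(), vals, atol=1e-12)

    def test_non_positive_rejected(self):
        m = protein_matrix(np.full((2, 6), -1.0))
        with pytest.raises(ValidationError, match="positive"):
            pp.normalize_protein(m)

    def test_all_missing_column_rejected(self):
        vals = np.ones((3, 6))
        m = protein_matrix(vals)
        m.values["C0_pro1"] = np.nan
        with pytest.raises(ValidationError, match="C0_pro1"):
            pp.normalize_protein(m)


class TestClassifyMissingness:
    def test_labels(self, toy_sheet):
        nan = np.nan
        m = protein_matrix([
            [5.0, 5, 5, 5, 5, 5],          # complete both blocks
            [5.0, 5, 5, nan, nan, nan],    # D1 fully missing -> MNAR
            [5.0, 5, 5, 5, 5, nan],        # high block, one missing -> MAR
            [-9.0, -9, -9, -9, -9, nan],   # lowest-quartile mean -> MNAR
        ])
        mm = pp.classify_missingness(m, toy_sheet)
        assert mm.of("P1", "C0") == "complete"
        assert mm.of("P1", "D1") == "complete"
        assert mm.of("P2", "D1") == "MNAR"
        assert mm.of("P3", "D1") == "MAR"
        assert mm.of("P4", "D1") == "MNAR"

    def test_recovers_planted_censoring(self, study, prepared_proteome):
        # >= 70 % of blocks containing true left-censored entries labelled MNAR
        _, mmap = prepared_proteome
        kept = mmap.labels.index
        hits = total = 0
        for cid in mmap.labels.columns:
            samp = [s for s in study.protein.values.columns
                    if s.startswith(cid + "_")]
            mn = study.truth.mnar_mask.loc[kept, samp].any(axis=1)
            total += int(mn.sum())
            hits += int((mmap.labels.loc[mn[mn].index, cid] == "MNAR").sum())
        assert total > 0
        assert hits / total >= 0.7


class TestImputeMindet:
    def test_missing_gets_column_minimum(self):
        nan = np.nan
        m = protein_matrix([[5.0, 1, 1, 1, 1, 1],
                            [2.0, 1, 1, 1, 1, 1],
                            [nan, 1, 1, 1, 1, 1],
                            [nan, 1, 1, 1, 1, 1]])
        out = pp.impute_mindet(m)
        assert out.values.at["P3", "C0_pro1"] == 2.0
        assert out.values.at["P4", "C0_pro1"] == 2.0  # deterministic

    def test_identity_without_missing(self):
        m = protein_matrix(np.arange(12.0).reshape(2, 6))
        out = pp.impute_mindet(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_result_bounded_by_observed_minimum(self, study):
        norm = pp.normalize_protein(
            pp.filter_quantified(study.protein, study.sheet, 3))
        out = pp.impute_mindet(norm)
        mins = norm.values.min(axis=0, skipna=True)
        assert (out.values.min(axis=0) >= mins - 1e-12).all()


class TestImputeMinprob:
    def test_draw_location_matches_quantile(self):
        rng = np.random.default_rng(0)
        n = 200
        vals = rng.normal(0, 1, size=(n, 6))
        vals[:50, 0] = np.nan
        m = protein_matrix(np.vstack([vals] * 1))
        m = OmicsMatrix("protein", pd.DataFrame(
            vals, index=[f"P{i}" for i in range(n)], columns=PCOLS))
        draws = []
        for seed in range(200):
            out = pp.impute_minprob(m, q=0.1, seed=seed)
            draws.append(out.values.iloc[:50, 0].to_numpy())
        draws = np.concatenate(draws)
        loc = np.nanquantile(vals[:, 0], 0.1)
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(loc, abs=3 * se)

    def test_seeded_determinism_and_observed_untouched(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, size=(30, 6))
        vals[3, 2] = np.nan
        m = protein_matrix(vals)
        a = pp.impute_minprob(m, seed=7)
        b = pp.impute_minprob(m, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)
        obs = ~np.isnan(vals)
        np.testing.assert_array_equal(a.values.to_numpy()[obs], vals[obs])

    def test_identity_without_missing(self):
        m = protein_matrix(np.arange(12.0).reshape(2, 6))
        out = pp.impute_minprob(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_constant_data_falls_back_to_mindet(self):
        vals = np.ones((4, 6))
        vals[0, 0] = np.nan
        m = protein_matrix(vals)
        with pytest.warns(UserWarning, match="MinDet"):
            out = pp.impute_minprob(m, seed=0)
        assert out.values.at["P1", "C0_pro1"] == 1.0


class TestImputeKnn:
    def test_identical_neighbour_copied(self):
        nan = np.nan
        m = protein_matrix([[1.0, 2, 3, 4, 5, 6],
                            [1.0, 2, 3, 4, 5, nan],
                            [9.0, 9, 9, 9, 9, 9]])
        out = pp.impute_knn(m, k=1)
        assert out.values.at["P2", "D1_pro3"] == 6.0

    def test_k_exceeding_features_uses_all(self):
        nan = np.nan
        m = protein_matrix([[1.0, 2, 3, 4, 5, nan],
                            [1.0, 2, 3, 4, 5, 6]])
        out = pp.impute_knn(m, k=50)
        assert out.values.at["P1", "D1_pro3"] == 6.0

    def test_weighted_mean_arithmetic_oracle(self):
        nan = np.nan
        m = OmicsMatrix("protein", pd.DataFrame(
            [[1.5, 2.5, nan],
             [1.4, 2.4, 3.0],
             [2.4, 3.4, 4.0]],
            index=["P1", "P2", "P3"], columns=["a", "b", "c"]))
        out = pp.impute_knn(m, k=2)
        d2 = np.sqrt(0.01 + 0.01)
        d3 = np.sqrt(0.81 + 0.81)
        expect = (3.0 / d2 + 4.0 / d3) / (1 / d2 + 1 / d3)
        assert out.values.at["P1", "c"] == pytest.approx(expect, rel=1e-12)

    def test_no_neighbour_falls_back_to_feature_mean(self):
        nan = np.nan
        m = OmicsMatrix("protein", pd.DataFrame(
            [[1.0, 3.0, nan],
             [2.0, 4.0, nan]],
            index=["P1", "P2"], columns=["a", "b", "c"]))
        with pytest.warns(UserWarning, match="feature mean"):
            out = pp.impute_knn(m, k=2)
        assert out.values.at["P1", "c"] == pytest.approx(2.0)


class TestPipelineOrder:
    def test_prepared_matrix_complete_and_observed_preserved(
            self, study, prepared_proteome):
        prepared, _ = prepared_proteome
        assert not prepared.values.isna().to_numpy().any()
        norm = pp.normalize_protein(
            pp.filter_quantified(study.protein, study.sheet, 3))
        obs = norm.values.notna()
        np.testing.assert_allclose(
            prepared.values.to_numpy()[obs.to_numpy()],
            norm.values.to_numpy()[obs.to_numpy()])
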
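import math

import numpy as np
import pandas as pd
import pytest

from omnifiber import (
    ExpressionMatrix,
    FormatError,
    StudyDesign,
    log2_transform,
    read_expression_matrix,
    stage_correlations,
    stage_mean_profiles,
    write_expression_matrix,
)
from omnifiber.summaries import run_pca

from conftest import make_matrix


def design_frame(regions=("LD", "SD"), stages=("E57", "E73", "E90", "P1", "P28", "P120"), reps=3):
    rows = [
        {"sample_id": f"{r}_{s}_r{i}", "region": r, "stage": s, "replicate": i}
        for r in regions
        for s in stages
        for i in range(1, reps + 1)
    ]
    return pd.DataFrame(rows)


class TestReadWrite:
    def test_well_formed_file_reads_back_as_printed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\ts2\nA\t1\t2\nB\t0\t4.5\nC\t3\t0\n")
        m = read_expression_matrix(p, "protein")
        assert m.feature_ids == ["A", "B", "C"]
        assert m.sample_ids == ["s1", "s2"]
        assert m.values.tolist() == [[1, 2], [0, 4.5], [3, 0]]

    def test_missing_cells_become_zero(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\ts2\nA\t\t2\nB\t1\t\n")
        m = read_expression_matrix(p, "protein")
        assert m.values.tolist() == [[0, 2], [1, 0]]

    def test_duplicate_feature_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\nA\t1\nA\t2\n")
        with pytest.raises(FormatError, match="duplicate feature"):
            read_expression_matrix(p, "protein")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\ts1\nA\t1\t2\n")
        with pytest.raises(FormatError, match="duplicate sample"):
            read_expression_matrix(p, "protein")

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\nA\t-3\n")
        with pytest.raises(FormatError, match="negative"):
            read_expression_matrix(p, "protein")

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("feature\ts1\ts2\nA\t1\tabc\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_expression_matrix(p, "protein")

    def test_round_trip_is_lossless(self, tmp_path):
        m = make_matrix({"A": [1.5, 0.0], "B": [2.25, 7.0]}, ["s1", "s2"])
        p = tmp_path / "out.tsv"
        write_expression_matrix(m, p)
        back = read_expression_matrix(p, "protein")
        pd.testing.assert_frame_equal(m.data, back.data)


class TestLog2Transform:
    @pytest.mark.parametrize("x,expected", [(1.0, 1.0), (0.0, 0.0), (7.0, 3.0)])
    def test_pseudocount_one_values(self, x, expected):
        m = make_matrix({"A": [x, x]}, ["s1", "s2"])
        out = log2_transform(m, pseudocount=1.0)
        assert out.scale == "log2"
        assert out.values[0, 0] == pytest.approx(expected)

    def test_zero_pseudocount_with_zero_value_rejected(self):
        m = make_matrix({"A": [0.0, 1.0]}, ["s1", "s2"])
        with pytest.raises(ValueError):
            log2_transform(m, pseudocount=0.0)

    def test_requires_linear_scale(self):
        m = make_matrix({"A": [1.0, 2.0]}, ["s1", "s2"], scale="log2")
        with pytest.raises(ValueError):
            log2_transform(m)


class TestStageMeans:
    def test_replicate_mean(self):
        d = StudyDesign(design_frame(regions=("LD",), stages=("E57",), reps=3),
                        stages=("E57",), regions=("LD",))
        m = make_matrix({"A": [2, 4, 6]}, d.sample_ids)
        out = stage_mean_profiles(m, d)
        assert out.values[0, 0] == pytest.approx(4.0)

    def test_unpooled_regions_give_region_by_stage_columns(self):
        d = StudyDesign(design_frame())
        m = make_matrix({"A": list(range(36))}, d.sample_ids)
        out = stage_mean_profiles(m, d, pool_regions=False)
        assert out.n_samples == 12
        assert out.sample_ids[0] == "LD:E57"

    def test_constant_replicates_give_constant_profile(self):
        d = StudyDesign(design_frame())
        m = make_matrix({"A": [5.0] * 36}, d.sample_ids)
        out = stage_mean_profiles(m, d)
        assert np.allclose(out.values, 5.0)

    def test_empty_stage_named_in_error(self):
        frame = design_frame(regions=("LD",), stages=("E57",))
        d = StudyDesign(frame, stages=("E57", "E73"), regions=("LD",))
        m = make_matrix({"A": [1, 2, 3]}, d.sample_ids)
        with pytest.raises(ValueError, match="E73"):
            stage_mean_profiles(m, d)


def pearson_by_sums(x, y):
    """Textbook Pearson r via the raw sum formula (independent oracle)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestStageCorrelations:
    def _design_two_stage(self):
        return StudyDesign(
            design_frame(regions=("LD",), stages=("S1", "S2"), reps=1),
            stages=("S1", "S2"), regions=("LD",),
        )

    def test_identical_profiles_correlate_perfectly(self):
        # S1 and S2 identical; S3 provides the across-stage variance that
        # keeps features from being globally constant
        d = StudyDesign(
            design_frame(regions=("LD",), stages=("S1", "S2", "S3"), reps=1),
            stages=("S1", "S2", "S3"), regions=("LD",),
        )
        m = make_matrix({"A": [1, 1, 2], "B": [2, 2, 4], "C": [5, 5, 9]},
                        d.sample_ids, scale="log2")
        out = stage_correlations(m, d)
        assert out.r.loc["S1", "S2"] == pytest.approx(1.0)

    def test_reversed_profiles_anticorrelate(self):
        d = self._design_two_stage()
        m = make_matrix({"A": [1, 3], "B": [2, 2], "C": [3, 1]}, d.sample_ids,
                        scale="log2")
        out = stage_correlations(m, d)
        assert out.r.loc["S1", "S2"] == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        d = self._design_two_stage()
        m = make_matrix({"A": [1, 2], "B": [2, 3], "C": [4, 9]}, d.sample_ids,
                        scale="log2")
        out = stage_correlations(m, d)
        assert out.r.loc["S1", "S2"] == pytest.approx(
            pearson_by_sums([1, 2, 4], [2, 3, 9])
        )

    def test_symmetric_unit_diagonal_and_feature_order_invariant(self, study):
        from omnifiber import log2_transform

        logm = log2_transform(study.protein)
        out = stage_correlations(logm, study.design)
        assert np.allclose(np.diag(out.r.to_numpy()), 1.0)
        assert np.allclose(out.r.to_numpy(), out.r.to_numpy().T)
        shuffled = ExpressionMatrix(
            logm.data.sample(frac=1, random_state=0), logm.modality, logm.scale
        )
        out2 = stage_correlations(shuffled, study.design)
        assert np.allclose(out.r.to_numpy(), out2.r.to_numpy())

    def test_too_few_usable_features_rejected(self):
        d = self._design_two_stage()
        m = make_matrix({"A": [1, 2], "B": [3, 3]}, d.sample_ids, scale="log2")
        with pytest.raises(ValueError, match="fewer than 2"):
            stage_correlations(m, d)


class TestPca:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        df = pd.DataFrame(
            np.hstack([X, X]), columns=["a", "b", "c", "a2", "b2", "c2"]
        )
        m = ExpressionMatrix(df, "protein", "log2")
        res = run_pca(m, 2)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["a2"])

    def test_two_samples_span_one_axis(self):
        m = make_matrix({"A": [1, 2], "B": [0, 5], "C": [2, 1]}, ["s1", "s2"],
                        scale="log2")
        res = run_pca(m, 1)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_scores_match_covariance_eigensolve(self):
        # independent oracle: eigendecomposition of the sample covariance
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 3))  # features x samples
        m = ExpressionMatrix(
            pd.DataFrame(X, index=list("ABC"), columns=["s1", "s2", "s3"]),
            "protein", "log2",
        )
        res = run_pca(m, 2)
        Xc = X.T - X.T.mean(axis=0)  # samples x features, feature-centered
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order[:2]]
        assert np.allclose(np.abs(res.scores.to_numpy()), np.abs(oracle), atol=1e-9)
        total_var = (Xc**2).sum()
        assert res.explained_fraction[0] == pytest.approx(
            evals[order[0]] / total_var
        )

    def test_all_components_explain_everything(self, study):
        logm = log2_transform(study.protein)
        res = run_pca(logm, min(logm.n_features, logm.n_samples) - 1)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.explained_fraction) <= 1e-12).all()

    def test_constant_matrix_rejected(self):
        m = make_matrix({"A": [1, 1], "B": [2, 2]}, ["s1", "s2"], scale="log2")
        with pytest.raises(ValueError, match="constant"):
            run_pca(m, 1)
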
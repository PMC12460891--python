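import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omnifiber import (
    POLICIES,
    ContrastSpec,
    StudyDesign,
    bh_adjust,
    call_contrast,
    enumerate_stage_contrasts,
    summarize_dap_sets,
    two_group_test,
)

from conftest import make_matrix


class TestTwoGroupTest:
    def test_identical_groups(self):
        res = two_group_test([1, 2, 3], [1, 2, 3])
        assert res.log2fc == 0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_variance_formula(self):
        # hand oracle: s_a^2 = s_b^2 = 1, pooled sp = 1, t = -10 / sqrt(2/3), df = 4
        res = two_group_test([10, 12, 11], [20, 22, 21])
        t_oracle = -10 / math.sqrt(2 / 3)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), 4)
        assert res.log2fc == pytest.approx(-10)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_swap_negates_effect_preserves_p(self):
        r1 = two_group_test([1.0, 2.5, 2.0], [4.0, 4.5, 3.5])
        r2 = two_group_test([4.0, 4.5, 3.5], [1.0, 2.5, 2.0])
        assert r1.log2fc == pytest.approx(-r2.log2fc)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_constant_unequal_groups_flagged_degenerate(self):
        res = two_group_test([2, 2, 2], [5, 5, 5])
        assert res.p_value == 0.0
        assert res.degenerate

    def test_constant_equal_groups(self):
        res = two_group_test([2, 2], [2, 2])
        assert res.p_value == 1.0
        assert not res.degenerate

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1], [1, 2])

    def test_welch_differs_under_unequal_variance(self):
        a, b = [1, 2, 3, 10], [4.0, 4.1, 4.2, 3.9]
        rs = two_group_test(a, b, variant="student")
        rw = two_group_test(a, b, variant="welch")
        assert rs.p_value != pytest.approx(rw.p_value)


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=6))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def region_stage_design(stages=("E57",), reps=3):
    rows = [
        {"sample_id": f"{r}_{s}_r{i}", "region": r, "stage": s, "replicate": i}
        for r in ("LD", "SD")
        for s in stages
        for i in range(1, reps + 1)
    ]
    return StudyDesign(pd.DataFrame(rows), stages=stages)


class TestCallContrast:
    contrast = ContrastSpec("region_within_stage", ("LD", "E57"), ("SD", "E57"))

    def _matrix(self, a_vals, b_vals, extra=None):
        rows = {"F1": list(a_vals) + list(b_vals)}
        if extra:
            rows.update(extra)
        d = region_stage_design()
        return make_matrix(rows, d.sample_ids), d

    def test_fc_boundary_is_inclusive(self):
        # group means 12 vs 10 -> ratio exactly 1.2; tiny within-group spread
        m, d = self._matrix([12.001, 12, 11.999], [10.001, 10, 9.999])
        rec = call_contrast(m, d, self.contrast, POLICIES["region_dap"])[0]
        assert rec.fc_linear == pytest.approx(1.2, abs=1e-9)
        assert rec.p_value < 0.05
        assert rec.called

    def test_subthreshold_fold_change_not_called(self):
        m, d = self._matrix([11.001, 11, 10.999], [10.001, 10, 9.999])
        rec = call_contrast(m, d, self.contrast, POLICIES["region_dap"])[0]
        assert rec.p_value < 0.001
        assert not rec.called

    def test_single_feature_bh_is_identity(self):
        m, d = self._matrix([20.0, 24, 22], [10.0, 12, 11])
        rec = call_contrast(m, d, self.contrast, POLICIES["stage_dap"])[0]
        assert rec.q_value == pytest.approx(rec.p_value)
        assert rec.called == (rec.q_value < 0.05)

    def test_log2fc_consistent_with_linear_fc(self):
        m, d = self._matrix([20.0, 24, 22], [10.0, 12, 11])
        rec = call_contrast(m, d, self.contrast, POLICIES["region_dap"])[0]
        assert rec.log2fc == pytest.approx(np.log2(rec.fc_linear), abs=1e-9)

    def test_protein_zeros_skip_feature(self):
        m, d = self._matrix(
            [12.0, 12, 12], [10.0, 10, 10], extra={"F2": [5, 0, 0, 7, 8, 9]}
        )
        recs = call_contrast(m, d, self.contrast, POLICIES["region_dap"])
        assert [r.feature_id for r in recs] == ["F1"]

    def test_transcript_zeros_are_kept(self):
        m, d = self._matrix([12.0, 12, 12], [10.0, 10, 10],
                            extra={"F2": [5, 0, 0, 7, 8, 9]})
        m2 = make_matrix(
            {k: list(v) for k, v in zip(m.feature_ids, m.values)},
            m.sample_ids, modality="transcript",
        )
        recs = call_contrast(m2, d, self.contrast, POLICIES["region_deg"])
        assert {r.feature_id for r in recs} == {"F1", "F2"}

    def test_reversed_contrast_inverts_fc_and_preserves_calls(self, study):
        # region_deg has a symmetric gate (0.5, 2); the region_dap gate is
        # slightly asymmetric because 0.833 is a rounding of 1/1.2
        c = ContrastSpec("region_within_stage", ("LD", "P28"), ("SD", "P28"))
        c_rev = ContrastSpec("region_within_stage", ("SD", "P28"), ("LD", "P28"))
        fwd = call_contrast(study.protein, study.design, c, POLICIES["region_deg"])
        rev = call_contrast(study.protein, study.design, c_rev, POLICIES["region_deg"])
        fwd_by = {r.feature_id: r for r in fwd}
        for r in rev:
            assert r.fc_linear == pytest.approx(1.0 / fwd_by[r.feature_id].fc_linear)
        assert {r.feature_id for r in fwd if r.called} == {
            r.feature_id for r in rev if r.called
        }

    def test_unresolvable_selector_rejected(self):
        m, d = self._matrix([1.0, 2, 3], [4.0, 5, 6])
        bad = ContrastSpec("region_within_stage", ("LD", "E57"), ("XX", "E57"))
        with pytest.raises(ValueError, match="empty group"):
            call_contrast(m, d, bad, POLICIES["region_dap"])


class TestEnumerateContrasts:
    def test_adjacent_two_regions(self):
        d = region_stage_design(stages=("E57", "E73", "E90", "P1", "P28", "P120"))
        assert len(enumerate_stage_contrasts(d, "adjacent")) == 10

    def test_all_pairs_two_regions(self):
        d = region_stage_design(stages=("E57", "E73", "E90", "P1", "P28", "P120"))
        assert len(enumerate_stage_contrasts(d, "all_pairs")) == 30

    def test_single_region_in_stage_order(self):
        rows = [
            {"sample_id": f"LD_{s}_r{i}", "region": "LD", "stage": s, "replicate": i}
            for s in ("E57", "E73", "E90", "P1", "P28", "P120")
            for i in (1, 2)
        ]
        d = StudyDesign(pd.DataFrame(rows), regions=("LD",))
        out = enumerate_stage_contrasts(d, "adjacent")
        assert len(out) == 5
        assert [c.group_a[1] for c in out] == ["E57", "E73", "E90", "P1", "P28"]


class TestSummarizeDapSets:
    def test_disjoint_sets(self):
        s = summarize_dap_sets({"c1": {"a", "b"}, "c2": {"x", "y", "z"}})
        assert s.union_size == 5
        assert s.pairwise_intersections.loc["c1", "c2"] == 0

    def test_identical_sets(self):
        s = summarize_dap_sets({"c1": {"a", "b"}, "c2": {"a", "b"}})
        assert s.pairwise_intersections.loc["c1", "c2"] == s.union_size == 2

    def test_upset_counts_match_enumeration(self):
        sets = {"c1": {"A", "B"}, "c2": {"B", "C"}, "c3": {"C"}}
        s = summarize_dap_sets(sets)
        # brute-force oracle: membership pattern of every feature
        expected = {}
        for feat in {"A", "B", "C"}:
            pat = frozenset(n for n, mem in sets.items() if feat in mem)
            expected[pat] = expected.get(pat, 0) + 1
        assert s.upset_counts == expected

    def test_stage_shares_sum_to_one(self):
        s = summarize_dap_sets(
            {"c1": {"a", "b"}, "c2": {"b", "c"}, "c3": {"d"}},
            stage_of={"c1": "P1", "c2": "P1", "c3": "P28"},
        )
        assert sum(s.stage_shares.values()) == pytest.approx(1.0)
        assert s.stage_shares["P1"] == pytest.approx(3 / 4)
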
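"""Occlusion contributions and the relative-contribution statistic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from emrisk import attribution as att
from emrisk.encoding import build_vocabulary
from emrisk.models import predict_risk


class TestOcclusion:
    def test_absent_feature_contributes_zero(self, trained_lstm, packed_folds):
        X, _ = packed_folds["val"]
        seq = X[0]
        missing = max(t for v in seq for t in v) + 1
        if missing <= packed_folds["vocab"].n_tokens:
            assert att.occlusion_contribution(trained_lstm, seq, missing) == 0.0

    def test_zero_embedding_feature_contributes_zero(self, trained_lstm, packed_folds):
        X, _ = packed_folds["val"]
        seq = [list(v) for v in X[0]]
        tok = seq[0][0]
        saved = trained_lstm.net_.params["E"][tok].copy()
        trained_lstm.net_.params["E"][tok] = 0.0
        try:
            fc = att.occlusion_contribution(trained_lstm, seq, tok)
        finally:
            trained_lstm.net_.params["E"][tok] = saved
        assert fc == pytest.approx(0.0, abs=1e-12)

    def test_total_equals_sum_of_single_occurrence_deltas(self, trained_lstm,
                                                          packed_folds):
        X, _ = packed_folds["val"]
        seq = [list(v) for v in X[0]]
        seq[0].append(seq[-1][0] if seq[-1] else seq[0][0])  # force a repeat
        tok = seq[0][-1]
        p0 = predict_risk(trained_lstm, seq)
        expected = 0.0
        for t, visit in enumerate(seq):
            for j, tk in enumerate(visit):
                if tk == tok:
                    var = [list(v) for v in seq]
                    del var[t][j]
                    expected += p0 - predict_risk(trained_lstm, var)
        assert att.occlusion_contribution(trained_lstm, seq, tok) == \
            pytest.approx(expected, abs=1e-10)


class TestNormalizeV15:
    def test_equal_split(self):
        assert att.normalize_fc_v15(np.array([0.2, 0.2])) == pytest.approx([0.5, 0.5])

    def test_mixed_signs_use_absolute_denominator(self):
        out = att.normalize_fc_v15(np.array([0.3, -0.1]))
        assert out == pytest.approx([0.75, -0.25])

    def test_all_zero_passes_through_with_warning(self):
        with pytest.warns(UserWarning):
            out = att.normalize_fc_v15(np.zeros(3))
        assert np.all(out == 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            att.normalize_fc_v15(np.array([1.0, np.nan]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    def test_absolute_values_sum_to_one(self, vec):
        vec = np.asarray(vec)
        if np.abs(vec).sum() == 0:
            return
        assert np.abs(att.normalize_fc_v15(vec)).sum() == pytest.approx(1.0)


class TestRelativeContribution:
    def test_identical_groups_give_one(self):
        assert att.relative_contribution([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_ratio(self):
        assert att.relative_contribution([0.04, 0.04], [0.02, 0.02]) == \
            pytest.approx(2.0)

    def test_opposite_sign_means_excluded(self):
        assert att.relative_contribution([-0.01, -0.01], [0.02, 0.02]) is None

    def test_both_negative_means_defined(self):
        # protective features have negative contributions in both groups
        rc = att.relative_contribution([-0.01, -0.01], [-0.02, -0.02])
        assert rc == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            att.relative_contribution([], [1.0])


class TestVarianceLnRC:
    def test_hand_arithmetic(self):
        # sd(1,2,3)=1, mean=2 -> (1/2)^2/3 ; second group constant -> 0
        assert att.variance_ln_rc([1, 2, 3], [2, 2, 2]) == pytest.approx(1 / 12)

    def test_constant_groups_give_zero(self):
        assert att.variance_ln_rc([2, 2], [3, 3]) == 0.0

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 5.0]
        v1 = att.variance_ln_rc(a, b)
        v2 = att.variance_ln_rc([2 * x for x in a], [2 * x for x in b])
        assert v1 == pytest.approx(v2)

    def test_requires_two_values_per_group(self):
        with pytest.raises(ValueError):
            att.variance_ln_rc([1.0], [1.0, 2.0])


class TestConfidenceInterval:
    def test_zero_variance_collapses_to_point(self):
        assert att.confidence_interval(1.7, 0.0) == (1.7, 1.7)

    def test_plug_in_example(self):
        var = (math.log(2) / att.Z95) ** 2
        lo, hi = att.confidence_interval(2.0, var)
        assert (lo, hi) == pytest.approx((1.0, 4.0))

    def test_geometric_mean_of_bounds_is_rc(self):
        for rc, var in [(0.5, 0.04), (1.0, 0.3), (3.2, 1.1)]:
            lo, hi = att.confidence_interval(rc, var)
            assert math.sqrt(lo * hi) == pytest.approx(rc, rel=1e-12)

    def test_published_row_consistency(self):
        # reported bounds (0.85, 0.606) imply the reported ratio 0.718
        assert math.exp((math.log(0.85) + math.log(0.606)) / 2) == \
            pytest.approx(0.718, abs=5e-4)

    def test_nonpositive_rc_rejected(self):
        with pytest.raises(ValueError):
            att.confidence_interval(0.0, 0.1)


class TestPValue:
    def test_null_rc_gives_one(self):
        assert att.p_value(1.0, 0.5) == pytest.approx(1.0)

    def test_boundary_z(self):
        rc = math.exp(att.Z95 * math.sqrt(0.04))
        assert att.p_value(rc, 0.04) == pytest.approx(0.05, abs=1e-6)

    def test_matches_normal_cdf_oracle(self):
        rc, var = 2.0, 0.25
        z = abs(math.log(rc)) / math.sqrt(var)
        assert att.p_value(rc, var) == pytest.approx(2 * (1 - norm.cdf(z)))

    def test_zero_variance_nonunit_rc(self):
        with pytest.warns(UserWarning):
            assert att.p_value(2.0, 0.0) == 0.0


def bh_step_up(pvals):
    """Independent step-up oracle: q_i = min_{j >= i} p_(j) * m / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestAdjustPvalues:
    def test_bonferroni_multiplies_by_m(self):
        q = att.adjust_pvalues([0.01, 0.2, 0.3, 0.5, 0.9], "bonferroni")
        assert q[0] == pytest.approx(0.05)
        assert np.all(q <= 1.0)

    def test_bh_hand_example(self):
        q = att.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "benjamini_hochberg")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_by_bh(self):
        assert att.adjust_pvalues([0.037], "benjamini_hochberg") == \
            pytest.approx([0.037])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_bh_matches_step_up_oracle_and_dominates_p(self, pvals):
        q = att.adjust_pvalues(pvals, "benjamini_hochberg")
        assert q == pytest.approx(bh_step_up(np.array(pvals)), abs=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            att.adjust_pvalues([1.2])


def _toy_table():
    rows = []
    for feat, rc, var in [("DX:G30", 2.0, 0.01), ("DX:AAA", 3.0, 0.04),
                          ("RX:BBB", 0.8, 0.02)]:
        lo, hi = att.confidence_interval(rc, var)
        rows.append(dict(feature=feat, feature_type=feat.split(":")[0],
                         n_event=50, n_nonevent=50, mean_fc_event=0.1,
                         mean_fc_nonevent=0.05, rc=rc, ci_low=lo, ci_high=hi,
                         variance_ln_rc=var, p=att.p_value(rc, var), q=np.nan,
                         excluded=False, exclude_reason=""))
    t = pd.DataFrame(rows).set_index("feature")
    t["q"] = att.adjust_pvalues(t["p"].to_numpy())
    return t


class TestScaleToAnchor:
    def test_anchor_becomes_exactly_one(self):
        out = att.scale_to_anchor(_toy_table(), "DX:G30")
        assert out.loc["DX:G30", "rc"] == 1.0

    def test_simple_factor(self):
        out = att.scale_to_anchor(_toy_table(), "DX:G30")
        assert out.loc["DX:AAA", "rc"] == pytest.approx(1.5)

    def test_unit_anchor_leaves_table_unchanged(self):
        t = _toy_table()
        t.loc["DX:G30", ["rc", "ci_low", "ci_high"]] = [1.0, 1.0, 1.0]
        out = att.scale_to_anchor(t, "DX:G30")
        assert out.loc["DX:AAA", "rc"] == pytest.approx(3.0)

    def test_log_symmetry_preserved(self):
        out = att.scale_to_anchor(_toy_table(), "DX:G30")
        for _, r in out[~out["excluded"]].iterrows():
            assert math.sqrt(r.ci_low * r.ci_high) == pytest.approx(r.rc, rel=1e-9)

    def test_rank_order_preserved(self):
        t = _toy_table()
        out = att.scale_to_anchor(t, "DX:G30")
        assert list(t["rc"].rank()) == list(out["rc"].rank())

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError):
            att.scale_to_anchor(_toy_table(), "DX:NONE")


class TestReportSignificant:
    def _table(self):
        t = _toy_table()
        t["q"] = [0.01, 0.01, 0.06]
        return t

    def test_low_prevalence_diagnosis_excluded(self):
        prev = pd.Series({"DX:G30": 1.0, "DX:AAA": 0.05, "RX:BBB": 0.05})
        rep = att.report_significant(self._table(), prev)
        assert "DX:AAA" not in rep.index

    def test_prevalence_filter_spares_drugs(self):
        t = self._table()
        t["q"] = [0.01, 0.06, 0.01]
        prev = pd.Series({"DX:G30": 1.0, "DX:AAA": 0.05, "RX:BBB": 0.05})
        rep = att.report_significant(t, prev)
        assert "RX:BBB" in rep.index

    def test_q_threshold(self):
        prev = pd.Series({"DX:G30": 1.0, "DX:AAA": 0.5, "RX:BBB": 0.5})
        rep = att.report_significant(self._table(), prev)
        assert "RX:BBB" not in rep.index

    def test_sorted_by_type_then_increasing_rc(self, small_cohort):
        t = _toy_table()
        t["q"] = 0.01
        prev = pd.Series(1.0, index=t.index)
        rep = att.report_significant(t, prev)
        for ftype, grp in rep.groupby("feature_type"):
            assert list(grp["rc"]) == sorted(grp["rc"])


@pytest.fixture(scope="module")
def cm(trained_lstm, packed_folds):
    X, y = packed_folds["val"]
    return att.contribution_matrix(trained_lstm, X[:30], y[:30],
                                   packed_folds["vocab"])


class TestContributionMatrix:
    def test_rows_normalized_to_unit_absolute_mass(self, cm):
        mass = cm.normalized.abs().sum(axis=1)
        nonzero = cm.raw.abs().sum(axis=1) > 0
        assert np.allclose(mass[nonzero], 1.0)

    def test_absent_features_have_zero_fc(self, cm, packed_folds):
        X, _ = packed_folds["val"]
        vocab = packed_folds["vocab"]
        present = {vocab.code_of[t] for v in X[0] for t in v}
        absent = [c for c in cm.features if c not in present]
        assert (cm.raw.loc[0, absent] == 0).all()
        assert not cm.occurs.loc[0, absent].any()

    def test_occurrence_mask_matches_sequences(self, cm, packed_folds):
        X, _ = packed_folds["val"]
        vocab = packed_folds["vocab"]
        present = {vocab.code_of[t] for v in X[5] for t in v}
        assert set(cm.occurs.columns[cm.occurs.loc[5]]) == present
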
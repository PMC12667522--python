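"""ANOVA, Tukey, BH adjustment, fold-change rules and the two screens."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphodyn import (SampleDesign, ValidationError, anova_oneway,
                        bh_adjust, fold_change_maxmin, screen_multigroup,
                        screen_twogroup, tukey_hsd)
from phosphodyn.differential import P_FLOOR
from phosphodyn.normalize import RelativeAbundance


def _rel_from_frame(frame: pd.DataFrame, design) -> RelativeAbundance:
    return RelativeAbundance(
        r=frame,
        provenance=pd.Series("protein-calibrated", index=frame.index),
        zero_replaced=pd.DataFrame(False, index=frame.index,
                                   columns=frame.columns),
        meta=pd.DataFrame({"protein_id": "P1", "residue": "S",
                           "position": range(1, len(frame) + 1)},
                          index=frame.index),
        design=design, dropped_all_zero=[])


class TestAnova:
    def test_hand_computed_f(self):
        F, p = anova_oneway([(1, 2, 3), (4, 5, 6)])
        assert F == pytest.approx(13.5, abs=1e-12)
        assert p == pytest.approx(scipy.stats.f.sf(13.5, 1, 4), abs=1e-12)

    def test_equal_groups_give_null_result(self):
        F, p = anova_oneway([(1, 2), (1, 2), (1, 2)])
        assert (F, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_floors_p(self):
        F, p = anova_oneway([(1, 1), (2, 2)])
        assert np.isinf(F) and p == P_FLOOR

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([(1,), (2, 3)])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(2, 7)) for _ in range(4)]
            F, p = anova_oneway(groups)
            ref = scipy.stats.f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(size=7) + 0.5
            F, _ = anova_oneway([a, b])
            t = scipy.stats.ttest_ind(a, b).statistic
            assert F == pytest.approx(t ** 2, rel=1e-9)


class TestTukey:
    def test_equal_means_give_unit_p(self):
        pmap = tukey_hsd([(1.0, 2.0), (1.0, 2.0), (1.0, 2.0)])
        assert all(p == pytest.approx(1.0, abs=1e-9) for p in pmap.values())

    def test_two_groups_match_pooled_t_test(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=4) + 1
            p_tukey = tukey_hsd([a, b])[(0, 1)]
            p_t = scipy.stats.ttest_ind(a, b).pvalue
            assert p_tukey == pytest.approx(p_t, abs=1e-9)

    def test_separated_pair_is_significant(self):
        pmap = tukey_hsd([(1, 2, 3), (4, 5, 6)])
        assert pmap[(0, 1)] < 0.05

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            groups = [rng.normal(size=rng.integers(3, 7)) + rng.normal()
                      for _ in range(4)]
            mine = tukey_hsd(groups)
            ref = scipy.stats.tukey_hsd(*groups)
            for (i, j), p in mine.items():
                assert p == pytest.approx(ref.pvalue[i, j], abs=1e-9)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.4])[0] == 0.4

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @staticmethod
    def _oracle(p):
        p = np.asarray(p, float)
        n = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    def test_against_definition_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), self._oracle(p),
                                       atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFoldChange:
    @pytest.mark.parametrize("means, expected", [
        ((1, 2, 4, 0.5), 8.0),
        ((3, 3, 3, 3), 1.0),
    ])
    def test_max_over_min(self, means, expected):
        assert fold_change_maxmin(means) == expected

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            fold_change_maxmin((0, 1, 1, 1))


class TestScreenMultigroup:
    def test_fc_boundary_is_strict(self, design4):
        # exact group means (2,1,1,1): FC exactly 2.0 -> NOT significant
        rows = {"exact2": [2.0] * 4 + [1.0] * 12,
                "above2": [2.5] * 4 + [1.0] * 12}
        frame = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list(design4.samples))
        diff = screen_multigroup(_rel_from_frame(frame, design4))
        assert not diff.loc["exact2", "significant"]
        assert diff.loc["exact2", "fc"] == 2.0
        assert diff.loc["above2", "significant"]

    def test_flat_zero_noise_sites_not_significant(self, design4):
        frame = pd.DataFrame(np.ones((5, 16)),
                             index=[f"s{i}" for i in range(5)],
                             columns=list(design4.samples))
        diff = screen_multigroup(_rel_from_frame(frame, design4))
        assert not diff["significant"].any()
        assert (diff["pvalue"] == 1.0).all()

    def test_planted_effect_detected(self, design4):
        rng = np.random.default_rng(11)
        base = np.tile([2.5, 1.0, 1.0, 1.0], (30, 1)).repeat(4, axis=1)
        noisy = base * np.exp(rng.normal(0, 0.05, base.shape))
        frame = pd.DataFrame(noisy, index=[f"s{i}" for i in range(30)],
                             columns=list(design4.samples))
        diff = screen_multigroup(_rel_from_frame(frame, design4))
        assert diff["significant"].mean() > 0.9
        pair = "pair_significant.step1-2.vs.step3-4"
        assert diff[pair].mean() > 0.9


class TestScreenTwogroup:
    def _frame(self, rows, design):
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(design.samples))

    def test_identical_groups_not_significant(self, design2x2):
        frame = self._frame({"s1": (1, 1, 1, 1)}, design2x2)
        diff = screen_twogroup(_rel_from_frame(frame, design2x2),
                               require_intensity1=False)
        assert diff.loc["s1", "pvalue"] == 1.0
        assert not diff.loc["s1", "significant"]

    def test_fc_gate_blocks_small_effects(self):
        design = SampleDesign.from_layout(["control", "ko"], 4)
        rng = np.random.default_rng(13)
        vals = np.concatenate([np.full(4, 1.4), np.full(4, 1.0)])
        frame = self._frame(
            {"s1": vals * np.exp(rng.normal(0, 1e-4, 8))}, design)
        diff = screen_twogroup(_rel_from_frame(frame, design),
                               require_intensity1=False)
        assert diff.loc["s1", "pvalue"] < 0.001
        assert not diff.loc["s1", "significant"]  # FC 1.4 < 1.5 gate

    def test_planted_down_effect_detected_with_direction(self):
        design = SampleDesign.from_layout(["control", "ko"], 3)
        rng = np.random.default_rng(14)
        vals = np.concatenate([np.full(3, 2.0), np.full(3, 1.0)])
        frame = self._frame(
            {"s1": vals * np.exp(rng.normal(0, 0.05, 6))}, design)
        diff = screen_twogroup(_rel_from_frame(frame, design),
                               require_intensity1=False)
        assert diff.loc["s1", "significant"]
        assert diff.loc["s1", "direction"] == "down"

    def test_intensity1_filter(self):
        design = SampleDesign.from_layout(["control", "ko"], 2)
        frame = self._frame({"s1": (1.6, 1.4, 0.4, 0.6)}, design)
        raw = self._frame({"s1": (0.0, 0.0, 5.0, 5.0)}, design)
        diff = screen_twogroup(_rel_from_frame(frame, design),
                               raw_intensities=raw)
        assert not diff.loc["s1", "intensity1_positive"]
        assert not diff.loc["s1", "significant"]

    def test_requires_two_groups(self, design4, make_quant):
        frame = pd.DataFrame(np.ones((2, 16)), index=["a", "b"],
                             columns=list(design4.samples))
        with pytest.raises(ValidationError):
            screen_twogroup(_rel_from_frame(frame, design4),
                            require_intensity1=False)
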
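"""Fold changes, t-test/BH significance, fences and empirical FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcnorm import (
    CutoffBounds,
    NormalizedMatrix,
    TwoGroupConfig,
    differential_table,
    empirical_fdr,
    estimate_fc_cutoffs,
    fold_changes,
    normalize,
    simulate_two_group,
    t_test_bh,
)

from conftest import make_matrix


def linear_norm(values, runs, proteins=None, scale="linear"):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"p{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=proteins, columns=runs),
        method="cbn_p" if scale == "linear" else "rsc",
        scale=scale,
    )


DESIGN4 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
RUNS4 = list(DESIGN4)


class TestFoldChanges:
    def test_identical_conditions_give_unit_fc(self):
        nm = linear_norm([[1, 2, 1, 2], [5, 5, 5, 5]], RUNS4)
        fc = fold_changes(nm, DESIGN4, ("A", "B"))
        assert fc["fc"].tolist() == pytest.approx([1.0, 1.0])

    def test_linear_ratio_of_means(self):
        nm = linear_norm([[0.001, 0.001, 0.002, 0.002]], RUNS4)
        fc = fold_changes(nm, DESIGN4, ("A", "B"))
        assert fc["fc"].iloc[0] == pytest.approx(2.0)

    def test_log_odds_difference_of_means(self):
        nm = linear_norm([[-4, -4, -3, -3]], RUNS4, scale="log2_odds")
        fc = fold_changes(nm, DESIGN4, ("A", "B"))
        assert fc["fc"].iloc[0] == pytest.approx(2.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_zero_mean_recorded_as_inf_and_flagged(self):
        nm = linear_norm([[0, 0, 0.5, 0.5], [0.5, 0.5, 0, 0]], RUNS4)
        fc = fold_changes(nm, DESIGN4, ("A", "B"))
        assert np.isposinf(fc["fc"].iloc[0])
        assert fc["fc"].iloc[1] == 0.0
        assert fc["degenerate"].all()

    @settings(max_examples=30, derandomize=True)
    @given(
        means=st.lists(
            st.tuples(st.floats(0.01, 10), st.floats(0.01, 10)), min_size=1, max_size=6
        )
    )
    def test_swapping_conditions_inverts_fc(self, means):
        vals = [[a, a, b, b] for a, b in means]
        nm = linear_norm(vals, RUNS4)
        ab = fold_changes(nm, DESIGN4, ("A", "B"))["fc"]
        ba = fold_changes(nm, DESIGN4, ("B", "A"))["fc"]
        assert np.allclose(ab * ba, 1.0)

    def test_rsc_antisymmetry_via_sign_flip(self):
        nm = linear_norm([[-4, -3.5, -2, -2.5]], RUNS4, scale="log2_odds")
        ab = fold_changes(nm, DESIGN4, ("A", "B"))["log2fc"].iloc[0]
        ba = fold_changes(nm, DESIGN4, ("B", "A"))["log2fc"].iloc[0]
        assert ab == pytest.approx(-ba)


class TestTTestBH:
    def test_identical_values_give_p_one(self):
        nm = linear_norm([[2, 2, 2, 2], [1, 2, 3, 4]], RUNS4)
        res = t_test_bh(nm, DESIGN4, ("A", "B"))
        assert res["p_value"].iloc[0] == 1.0
        assert res["q_value"].iloc[0] == 1.0

    def test_degenerate_variance_unequal_means_flagged(self):
        nm = linear_norm([[1, 1, 2, 2]], RUNS4)
        res = t_test_bh(nm, DESIGN4, ("A", "B"))
        assert res["p_value"].iloc[0] == 0.0
        assert bool(res["degenerate_variance"].iloc[0])

    def test_bh_step_up_matches_hand_computation(self):
        # p = (0.01, 0.02, 0.03, 0.9): q_i = min_j>=i p_j * m / j
        # = (0.04, 0.04, 0.04, 0.9) -> first three rejected at alpha 0.05
        from statsmodels.stats.multitest import multipletests

        reject, q, _, _ = multipletests(
            [0.01, 0.02, 0.03, 0.9], alpha=0.05, method="fdr_bh"
        )
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.9])
        assert reject.tolist() == [True, True, True, False]

    def test_student_vs_welch_switch(self):
        nm = linear_norm([[1.0, 1.2, 1.1, 2.0, 2.2, 2.4]],
                         ["a1", "a2", "a3", "b1", "b2", "b3"])
        design = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        p_student = t_test_bh(nm, design, ("A", "B"))["p_value"].iloc[0]
        p_welch = t_test_bh(nm, design, ("A", "B"), equal_var=False)["p_value"].iloc[0]
        assert p_student != p_welch

    def test_needs_two_replicates(self):
        nm = linear_norm([[1, 2]], ["a1", "b1"])
        with pytest.raises(ValueError, match="2 replicates"):
            t_test_bh(nm, {"a1": "A", "b1": "B"}, ("A", "B"))

    def test_null_data_raw_p_uniformity(self):
        """Permutation-null: ~alpha of raw p-values fall below alpha."""
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 1, size=(1000, 6))
        runs = [f"r{i}" for i in range(6)]
        design = dict(zip(runs, ["A"] * 3 + ["B"] * 3))
        nm = linear_norm(vals, runs)
        res = t_test_bh(nm, design, ("A", "B"))
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_bh_rejections_nested_in_alpha(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 1, size=(300, 6))
        vals[:30, 3:] += 3  # some real effects
        runs = [f"r{i}" for i in range(6)]
        design = dict(zip(runs, ["A"] * 3 + ["B"] * 3))
        nm = linear_norm(vals, runs)
        res = t_test_bh(nm, design, ("A", "B"))
        strict = res["q_value"] < 0.01
        loose = res["q_value"] < 0.10
        assert (loose | ~strict).all()  # strict subset of loose
        # q is a monotone transform of p
        ordered = res.sort_values("p_value")
        assert (ordered["q_value"].diff().dropna() >= -1e-12).all()


class TestCutoffs:
    def test_degenerate_all_equal(self):
        table = pd.DataFrame({"fc": [1.0] * 10, "p_value": [0.5] * 10})
        with pytest.warns(UserWarning, match="IQR is 0"):
            b = estimate_fc_cutoffs(table)
        assert b.lower == b.upper == 1.0

    def test_hand_computed_quartiles(self):
        # linear interpolation on (0.8, 0.9, 1.0, 1.1, 1.25):
        # Q1 = 0.9, Q3 = 1.1, IQR = 0.2 -> fences 0.6 / 1.4
        table = pd.DataFrame(
            {"fc": [0.8, 0.9, 1.0, 1.1, 1.25, 0.95, 1.05, 1.0],
             "p_value": [0.5] * 8}
        )
        b = estimate_fc_cutoffs(table)
        q1, q3 = np.quantile(table["fc"], [0.25, 0.75])
        assert b.q1 == pytest.approx(q1)
        assert b.q3 == pytest.approx(q3)
        assert b.lower == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert b.upper == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_mask_uses_raw_p(self):
        fcs = [0.9, 1.0, 1.1, 1.05, 0.95, 1.0, 1.02, 0.98, 50.0]
        ps = [0.5] * 8 + [0.001]  # the FC=50 protein is significant -> excluded
        b = estimate_fc_cutoffs(pd.DataFrame({"fc": fcs, "p_value": ps}))
        assert b.upper < 2

    def test_small_mask_is_error(self):
        table = pd.DataFrame({"fc": [1.0] * 5, "p_value": [0.5] * 5})
        with pytest.raises(ValueError, match=">= 8"):
            estimate_fc_cutoffs(table)

    def test_empty_mask_is_error(self):
        table = pd.DataFrame({"fc": [1.0] * 5, "p_value": [0.001] * 5})
        with pytest.raises(ValueError, match="no unchanged"):
            estimate_fc_cutoffs(table)

    def test_fences_widen_with_dispersion(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 0.1, 400)
        widths = []
        for scale in (1.0, 2.0, 4.0):
            table = pd.DataFrame(
                {"fc": np.exp(base * scale), "p_value": np.full(400, 0.5)}
            )
            b = estimate_fc_cutoffs(table)
            widths.append(b.upper - b.lower)
        assert widths[0] < widths[1] < widths[2]


class TestEmpiricalFDRAndPipeline:
    def test_no_calls_is_zero(self):
        table = pd.DataFrame({"significant": [False] * 5}, index=list("abcde"))
        assert empirical_fdr(table, list("abcde")) == 0.0

    def test_false_positive_percentage_arithmetic(self):
        # 25 false positives among 409 proteins -> 6.11%
        idx = [f"p{i}" for i in range(409)]
        sig = pd.Series([True] * 25 + [False] * 384, index=idx)
        table = pd.DataFrame({"significant": sig})
        assert empirical_fdr(table, idx) == pytest.approx(6.11, abs=0.01)

    def test_significance_requires_both_q_and_fence(self):
        rng = np.random.default_rng(11)
        vals = np.abs(rng.normal(1.0, 0.01, size=(50, 6)))
        vals[0, 3:] *= 1.15  # small but clear shift: significant q, inside fences
        vals[1, 3:] *= 30.0  # huge shift: q and fence both fire
        runs = [f"r{i}" for i in range(6)]
        design = dict(zip(runs, ["A"] * 3 + ["B"] * 3))
        nm = linear_norm(vals, runs)
        table, bounds = differential_table(nm, design, ("A", "B"),
                                           cutoffs=(0.5, 2.0))
        assert bool(table["significant"].iloc[1])
        assert table["direction"].iloc[1] == "up"
        # protein 0 has q < alpha but FC ~1.08, inside the fences
        assert table["q_value"].iloc[0] < 0.05
        assert not bool(table["significant"].iloc[0])

    def test_pipeline_on_simulated_null_keeps_fdr_low(self):
        cfg = TwoGroupConfig(n_proteins=300, fraction_changed=0.0, seed=4)
        m, truth = simulate_two_group(cfg)
        nm = normalize(m, "cbn_p")
        design = m.run_meta["condition"].to_dict()
        table, _ = differential_table(nm, design, cfg.conditions)
        fdr = empirical_fdr(table, truth.index[truth["is_null"]])
        assert fdr <= 5.0
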
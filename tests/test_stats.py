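"""Benjamini–Hochberg step-up, mixed-model contrasts, paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from vibemg.exceptions import StatsError
from vibemg.simulate import SimConfig, fmv_table_profile, simulate_ratio_table
from vibemg.stats import (
    RmsRatioModel,
    benjamini_hochberg,
    compare_groups,
    fit_intragroup,
    summarize,
)


def bh_bruteforce(pvals):
    """Independent step-up oracle: adjusted_(i) = min_{j>=i} m * p_(j) / j, capped."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = []
    for pos in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        adj_sorted.append(min(1.0, min(candidates)))
    out = [0.0] * m
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return np.array(out)


class TestBenjaminiHochberg:
    def test_handworked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(adj, bh_bruteforce([0.01, 0.02, 0.03, 0.04]))

    def test_equal_inputs_give_equal_outputs(self):
        adj = benjamini_hochberg([0.03] * 5)
        assert len(set(adj)) == 1
        np.testing.assert_allclose(adj, bh_bruteforce([0.03] * 5))

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([-0.1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1),
           m=st.integers(min_value=1, max_value=20))
    def test_matches_bruteforce_and_statsmodels(self, seed, m):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        ours = benjamini_hochberg(p)
        np.testing.assert_allclose(ours, bh_bruteforce(p), rtol=0, atol=0)
        np.testing.assert_allclose(ours, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_order_preserving(self, seed):
        p = np.sort(np.random.default_rng(seed).uniform(0, 1, 10))
        adj = benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-15)


def _ratio_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "session", "follow_up_min", "ratio"])


class TestFitIntragroup:
    def test_degenerate_all_unit_ratios(self):
        rows = [(f"P{i}", "control", 0, 1.0) for i in range(6)]
        res = fit_intragroup(_ratio_frame(rows), "control")
        assert res.table.loc[0, "coef"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc[0, "p_raw"] == 1.0

    def test_requires_two_participants(self):
        rows = [("P1", "control", m, 1.0) for m in (0, 5)]
        with pytest.raises(StatsError, match="participants"):
            fit_intragroup(_ratio_frame(rows), "control")

    def test_non_positive_ratio_rejected_on_log_scale(self):
        rows = [(f"P{i}", "control", 0, r) for i, r in enumerate([1.0, -0.2, 0.9])]
        with pytest.raises(StatsError, match="log"):
            fit_intragroup(_ratio_frame(rows), "control")

    def test_parameter_recovery_within_tolerance(self):
        """exp(coefficient) recovers injected attenuation to ±0.05 at n=30."""
        truth = fmv_table_profile()
        cfg = SimConfig()  # subject SD 0.3 on the log-ratio scale
        estimates = {m: [] for m in truth}
        n_rep = 25
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            rt = simulate_ratio_table(cfg, rng)
            res = fit_intragroup(rt, "fmv")
            for _, row in res.table.iterrows():
                estimates[int(row["follow_up_min"])].append(row["ratio_estimate"])
        for m, vals in estimates.items():
            assert abs(np.mean(vals) - truth[m]) < 0.05, f"minute {m}"

    def test_raw_ratio_scale_variant(self):
        rng = np.random.default_rng(3)
        rt = simulate_ratio_table(SimConfig(), rng)
        res = fit_intragroup(rt, "fmv", scale="ratio")
        # coefficient is the modelled mean ratio; attenuated points sit below 1
        assert res.table.set_index("follow_up_min").loc[5, "coef"] < 1.0
        assert (res.table["p_adj"] <= 1.0).all()


class TestCompareGroups:
    def _paired_table(self, diffs, base=None):
        rows = []
        n = len(diffs)
        base = np.ones(n) if base is None else base
        for i in range(n):
            rows.append((f"P{i:02d}", "control", 0, base[i]))
            rows.append((f"P{i:02d}", "fmv", 0, base[i] + diffs[i]))
        return _ratio_frame(rows)

    def test_paired_t_df_is_n_minus_1(self, rng):
        diffs = rng.normal(-0.1, 0.05, 30)
        res = compare_groups(self._paired_table(diffs))
        row = res.table.iloc[0]
        assert row["test_used"] == "paired_t"
        assert row["df"] == 29
        assert row["n_pairs"] == 30

    def test_identical_sessions_degenerate(self):
        res_warn = pytest.warns(UserWarning, match="zero")
        with res_warn:
            res = compare_groups(self._paired_table(np.zeros(10)))
        assert res.table.iloc[0]["p_raw"] == 1.0
        assert res.table.iloc[0]["test_used"] == "degenerate"

    def test_non_normal_differences_use_wilcoxon(self, rng):
        # heavy-tailed differences: Shapiro rejects, Wilcoxon applies
        diffs = np.exp(rng.normal(0, 1, 40)) - 1.0
        from scipy.stats import shapiro

        assert shapiro(diffs).pvalue < 0.05  # construction check
        res = compare_groups(self._paired_table(diffs))
        assert res.table.iloc[0]["test_used"] == "wilcoxon"
        assert np.isnan(res.table.iloc[0]["df"])

    def test_fewer_than_three_pairs_raises(self):
        with pytest.raises(StatsError, match="pair"):
            compare_groups(self._paired_table(np.array([0.1, 0.2])))

    def test_shifted_fmv_detected_in_majority_of_replicates(self):
        """A -0.25 fmv shift at minutes 0-20 yields adjusted p<0.05 at those points."""
        profile = {
            "control": {m: 1.0 for m in (0, 5, 10, 15, 20, 25, 30)},
            "fmv": {m: (0.75 if m <= 20 else 1.0) for m in (0, 5, 10, 15, 20, 25, 30)},
        }
        cfg = SimConfig(effect_profile=profile)
        hits = {m: 0 for m in (0, 5, 10, 15, 20)}
        n_rep = 11
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            rt = simulate_ratio_table(cfg, rng)
            res = compare_groups(rt)
            tab = res.table.set_index("follow_up_min")
            for m in hits:
                if tab.loc[m, "p_adj"] < 0.05:
                    hits[m] += 1
        for m, h in hits.items():
            assert h > n_rep / 2, f"minute {m}: {h}/{n_rep}"


class TestModelFacade:
    def test_fit_summary_and_significance(self):
        rng = np.random.default_rng(11)
        rt = simulate_ratio_table(SimConfig(), rng)
        model = RmsRatioModel(rt)
        res = model.fit()
        text = res.summary()
        assert "Within-session" in text and "Between-session" in text
        assert set(res.intragroup) == {"control", "fmv"}
        assert res.intergroup is not None
        assert len(res.report.summary) == 14  # 2 sessions x 7 points

    def test_attenuated_points_significant_in_majority_of_replicates(self):
        hits = 0
        n_rep = 7
        for rep in range(n_rep):
            rng = np.random.default_rng(60 + rep)
            res = RmsRatioModel(simulate_ratio_table(SimConfig(), rng)).fit()
            if 5 in res.significant_points("fmv"):
                hits += 1
        assert hits > n_rep / 2

    def test_from_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        rt = simulate_ratio_table(SimConfig(n_participants=8), rng)
        rt.to_csv(tmp_path / "ratios.csv", index=False)
        res = RmsRatioModel.from_csv(tmp_path / "ratios.csv").fit()
        assert len(res.intergroup.table) == 7

    def test_empty_table_rejected(self):
        with pytest.raises(StatsError, match="empty"):
            RmsRatioModel(_ratio_frame([]))

    def test_save_report_files(self, tmp_path):
        rng = np.random.default_rng(13)
        rt = simulate_ratio_table(SimConfig(n_participants=6), rng)
        res = RmsRatioModel(rt).fit()
        res.save(tmp_path)
        for name in ("ratio_summary.csv", "intragroup_fmv.csv", "intergroup.csv", "report.txt"):
            assert (tmp_path / name).exists()

    def test_boxplot_written(self, tmp_path):
        rng = np.random.default_rng(14)
        rt = simulate_ratio_table(SimConfig(n_participants=6), rng)
        res = RmsRatioModel(rt).fit()
        out = tmp_path / "box.png"
        res.plot_boxplots(out)
        assert out.stat().st_size > 0


def test_summarize_row_count_and_means():
    rng = np.random.default_rng(15)
    rt = simulate_ratio_table(SimConfig(), rng)
    report = summarize(rt, {}, None)
    assert len(report.summary) == 14
    ctrl = report.summary[report.summary.session == "control"]
    assert np.all(np.abs(ctrl["ratio_mean"] - 1.0) < 0.25)
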
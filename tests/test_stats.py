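from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isochron import (fit_random_intercept, interaction_perm_test, perm_test,
                      variance_perm_test)


class TestPermTest:
    def test_identical_samples_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = perm_test(a, a, seed=0)
        assert res.observed == 0.0
        assert res.p == 1.0

    def test_p_is_never_zero_and_deterministic(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(10), rng.standard_normal(10) + 5
        r1 = perm_test(a, b, seed=7)
        r2 = perm_test(a, b, seed=7)
        assert r1.p == r2.p > 0
        assert np.array_equal(r1.null_distribution, r2.null_distribution)

    def test_complete_separation_matches_exhaustive_enumeration(self):
        """6 vs 6 fully separated: exact two-sided tail is 2/C(12,6)."""
        a = np.arange(1.0, 7.0)
        b = np.arange(101.0, 107.0)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = sum(
            abs(pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()) >= obs - 1e-9
            for idx in combinations(range(12), 6))
        exact = count / 924  # C(12,6) assignments
        assert exact == pytest.approx(2 / 924, rel=1e-12)
        n_perm = 2000
        res = perm_test(a, b, n_perm=n_perm, seed=11)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p - exact) < 2 * se + 1.0 / (n_perm + 1)

    def test_relabeling_flips_sign_same_p(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(9), rng.standard_normal(9) + 1
        r1 = perm_test(a, b, seed=3)
        r2 = perm_test(b, a, seed=3)
        assert r2.observed == pytest.approx(-r1.observed)
        assert r2.p == r1.p

    def test_input_order_invariance_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(8), rng.standard_normal(8) + 1
        r1 = perm_test(a, b, seed=5)
        r2 = perm_test(a[::-1], rng.permutation(b), seed=5)
        assert r1.p == r2.p

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_p_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        res = perm_test(rng.standard_normal(6), rng.standard_normal(6),
                        n_perm=99, seed=seed)
        assert 0 < res.p <= 1

    def test_variance_statistic(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(20) * 0.5
        b = rng.standard_normal(20) * 3.0
        res = perm_test(a, b, statistic="var", n_perm=500, seed=1)
        assert res.p < 0.05
        assert res.statistic_name == "variance-difference"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            perm_test([1.0], [2.0, 3.0])


class TestVariancePermTest:
    @staticmethod
    def variability_frame(sds, n_obs=120, seed=0):
        rng = np.random.default_rng(seed)
        rows = [{"subject": f"S{i}",
                 "var_amplitude": np.var(rng.standard_normal(n_obs) * sd,
                                         ddof=1)}
                for i, sd in enumerate(sds)]
        return pd.DataFrame(rows)

    def test_calibration_p_uniform_under_null(self):
        """Equal jitter in both groups: p-values uniform (KS, 200 reps)."""
        from scipy.stats import kstest
        ps = []
        for rep in range(200):
            df = self.variability_frame([1.0] * 20, seed=rep)
            groups = {f"S{i}": ("a" if i < 10 else "b") for i in range(20)}
            ps.append(variance_perm_test(df, groups, n_perm=199,
                                         seed=rep).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_jitter_difference(self):
        """4 ms vs 12 ms latency jitter SD, 18 vs 18: power >= 0.8."""
        hits = 0
        for rep in range(60):
            df = self.variability_frame([0.004] * 18 + [0.012] * 18,
                                        seed=500 + rep)
            groups = {f"S{i}": ("a" if i < 18 else "b") for i in range(36)}
            hits += variance_perm_test(df, groups, n_perm=200,
                                       seed=rep).p < 0.05
        assert hits / 60 >= 0.8


class TestRandomIntercept:
    @staticmethod
    def balanced_frame(n_per_group=18, m=5, group_effect=-1.66,
                       sd_intercept=1.27, sd_resid=1.93, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, label in enumerate(["g0", "g1"]):
            for i in range(n_per_group):
                u = rng.standard_normal() * sd_intercept
                base = 0.54 + (group_effect if label == "g1" else 0.0) + u
                for _ in range(m):
                    rows.append((base + rng.standard_normal() * sd_resid,
                                 f"{label}_s{i}", label))
        return pd.DataFrame(rows, columns=["y", "subject", "group"])

    def test_zero_residual_recovery_matches_draw_oracle(self):
        """With no residual noise the estimates equal the sample statistics
        of the drawn offsets, computed independently here."""
        rng = np.random.default_rng(9)
        offsets = {f"s{i}": rng.standard_normal() * 1.27 for i in range(36)}
        rows = []
        for i, (subj, u) in enumerate(offsets.items()):
            grp = "g0" if i < 18 else "g1"
            base = 0.54 + (-1.66 if grp == "g1" else 0.0) + u
            rows += [(base, subj, grp)] * 5
        df = pd.DataFrame(rows, columns=["y", "subject", "group"])
        vc = fit_random_intercept(df["y"], df["subject"], df["group"])
        us = np.array(list(offsets.values()))
        expected_ge = -1.66 + us[18:].mean() - us[:18].mean()
        expected_sd = np.sqrt((np.var(us[:18], ddof=1) * 17
                               + np.var(us[18:], ddof=1) * 17) / 34)
        assert vc.group_effect == pytest.approx(expected_ge, abs=1e-9)
        assert vc.sd_residual == 0.0
        assert vc.sd_intercept == pytest.approx(expected_sd, abs=1e-9)
        assert vc.n_obs == 180 and vc.n_participants == 36

    def test_constant_data_gives_zero_components(self):
        df = self.balanced_frame(seed=1)
        df["y"] = 7.0
        vc = fit_random_intercept(df["y"], df["subject"], df["group"])
        assert vc.group_effect == 0.0
        assert vc.sd_intercept == 0.0 and vc.sd_residual == 0.0

    def test_scaling_law(self):
        df = self.balanced_frame(seed=2)
        v1 = fit_random_intercept(df["y"], df["subject"], df["group"])
        v2 = fit_random_intercept(2 * df["y"], df["subject"], df["group"])
        assert v2.group_effect == pytest.approx(2 * v1.group_effect)
        assert v2.sd_intercept == pytest.approx(2 * v1.sd_intercept)
        assert v2.sd_residual == pytest.approx(2 * v1.sd_residual)

    def test_unbalanced_design_rejected(self):
        df = self.balanced_frame(seed=3).iloc[:-2]
        with pytest.raises(ValueError, match="unbalanced"):
            fit_random_intercept(df["y"], df["subject"], df["group"])


class TestInteractionPermTest:
    @staticmethod
    def peaks_frame(trend_by_group, n_per_group=12, noise=0.5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for label, trend in trend_by_group.items():
            for i in range(n_per_group):
                offset = rng.standard_normal()
                for pos in range(3, 8):
                    rows.append({"subject": f"{label}_s{i}", "position": pos,
                                 "amplitude": offset + trend * pos
                                 + rng.standard_normal() * noise})
        groups = {f"{label}_s{i}": label for label in trend_by_group
                  for i in range(n_per_group)}
        return pd.DataFrame(rows), pd.Series(groups)

    def test_constant_data_null(self):
        peaks, groups = self.peaks_frame({"a": 0.0, "b": 0.0}, noise=0.0)
        res = interaction_perm_test(peaks, groups, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_offset_only_difference_is_not_an_interaction(self):
        """Same position trend, different intercepts: mostly null."""
        null_rate = 0
        for rep in range(60):
            peaks, groups = self.peaks_frame({"a": -0.2, "b": -0.2},
                                             seed=rep)
            peaks.loc[groups[peaks["subject"]].values == "b", "amplitude"] += 3.0
            res = interaction_perm_test(peaks, groups, n_perm=200, seed=rep)
            null_rate += res.p > 0.05
        assert null_rate / 60 >= 0.9

    def test_power_for_trend_difference(self):
        """Repetition suppression in one group only (0.3/position)."""
        hits = 0
        for rep in range(60):
            peaks, groups = self.peaks_frame({"a": 0.0, "b": 0.3},
                                             seed=100 + rep)
            res = interaction_perm_test(peaks, groups, n_perm=200, seed=rep)
            hits += res.p < 0.05
        assert hits / 60 >= 0.8
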
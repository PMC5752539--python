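import numpy as np
import pandas as pd
import pytest

from _oracles import (
    cox_beta_bruteforce,
    km_median_ci_bruteforce,
    logrank_bruteforce,
)
from conftest import small_sim_config
from mirtarkey import RunConfig
from mirtarkey.datatypes import ClinicalTable
from mirtarkey.simulate import simulate_expression, simulate_survival
from mirtarkey.survival import (
    assign_outcome_groups,
    cox_screen_passes,
    cox_univariate,
    expression_ratio,
    km_median_ci,
    logrank_test,
    pattern_split,
    resampled_cox_screen,
)


def _clinical(times, events, index=None):
    n = len(times)
    idx = index or [f"p{i}" for i in range(n)]
    return ClinicalTable(
        pd.DataFrame(
            {
                "time": times,
                "event": events,
                "age": [60.0] * n,
                "gender": ["male"] * n,
            },
            index=idx,
        )
    )


class TestKMMedianCI:
    def test_uncensored_median_is_empirical(self):
        times = list(range(1, 6)) * 2  # n >= 10
        median, lower, upper = km_median_ci(times, [1] * 10)
        assert median == 3

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="censored"):
            km_median_ci(list(range(1, 11)), [0] * 10)

    def test_matches_brute_force_log_log_inversion(self, survival_fixture):
        _, time, event = survival_fixture
        got = km_median_ci(time, event)
        expected = km_median_ci_bruteforce(time, event)
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_median_never_reached_errors(self):
        times = [1, 2, 3] + [100] * 9
        events = [1, 1, 1] + [0] * 9
        with pytest.raises(ValueError, match="median"):
            km_median_ci(times, events)


class TestOutcomeGroups:
    def _cohort(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(100, size=80).round(1)
        events = np.ones(80, dtype=int)
        return times, events

    def test_censored_beyond_upper_counts_as_good(self):
        times, events = self._cohort()
        _, _, upper = km_median_ci(times, events)
        times = np.append(times, upper + 50)
        events = np.append(events, 0)  # censored but alive past the bound
        groups = assign_outcome_groups(_clinical(times, events))
        assert f"p{len(times) - 1}" in groups.good

    def test_censored_before_lower_is_unassigned(self):
        times, events = self._cohort()
        lower = km_median_ci(times, events)[1]
        times = np.append(times, lower / 2)
        events = np.append(events, 0)
        groups = assign_outcome_groups(_clinical(times, events))
        last = f"p{len(times) - 1}"
        assert last not in groups.poor and last not in groups.good

    def test_groups_disjoint_and_exclude_ci_interior(self):
        times, events = self._cohort()
        groups = assign_outcome_groups(_clinical(times, events))
        assert not set(groups.good) & set(groups.poor)
        clin = _clinical(times, events).data
        assert (clin.loc[groups.good, "time"] > groups.upper).all()
        assert (clin.loc[groups.poor, "time"] < groups.lower).all()

    def test_tiny_groups_rejected(self):
        # nearly identical times -> almost nobody outside the median CI
        times = [10.0] * 30
        with pytest.raises(ValueError, match="group"):
            assign_outcome_groups(_clinical(times, [1] * 30))


class TestExpressionRatio:
    def test_log_difference(self):
        a = pd.Series([5.0, 4.0], index=["s1", "s2"])
        b = pd.Series([3.0, 4.0], index=["s1", "s2"])
        assert expression_ratio(a, b).tolist() == [2.0, 0.0]

    def test_shift_invariance(self):
        a = pd.Series([5.0, 4.0], index=["s1", "s2"])
        b = pd.Series([3.0, 4.0], index=["s1", "s2"])
        pd.testing.assert_series_equal(expression_ratio(a, b), expression_ratio(a + 3, b + 3))

    def test_sample_mismatch_errors(self):
        a = pd.Series([1.0], index=["s1"])
        b = pd.Series([1.0], index=["s2"])
        with pytest.raises(ValueError, match="samples"):
            expression_ratio(a, b)


class TestCoxUnivariate:
    def test_matches_bruteforce_with_ties(self, survival_fixture):
        x, time, event = survival_fixture
        beta, se, p = cox_univariate(x, time, event)
        expected = cox_beta_bruteforce(x - x.mean(), time, event)
        np.testing.assert_allclose(beta, expected, rtol=1e-6)

    def test_matches_bruteforce_without_ties(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        time = rng.exponential(1 / np.exp(0.5 * x))
        event = (rng.uniform(size=40) < 0.8).astype(int)
        if event.sum() < 2:
            event[:2] = 1
        beta, _, _ = cox_univariate(x, time, event)
        np.testing.assert_allclose(
            beta, cox_beta_bruteforce(x - x.mean(), time, event), rtol=1e-6
        )

    def test_matches_lifelines(self, survival_fixture):
        from lifelines import CoxPHFitter

        x, time, event = survival_fixture
        beta, se, _ = cox_univariate(x, time, event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e"
        )
        np.testing.assert_allclose(beta, cph.params_["x"], rtol=1e-4)
        np.testing.assert_allclose(se, cph.standard_errors_["x"], rtol=1e-4)

    def test_sign_equivariance(self, survival_fixture):
        x, time, event = survival_fixture
        b1, _, p1 = cox_univariate(x, time, event)
        b2, _, p2 = cox_univariate(-x, time, event)
        assert b1 == pytest.approx(-b2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_null_covariate_small_beta(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        time = rng.exponential(1.0, size=500)
        beta, se, _ = cox_univariate(x, time, np.ones(500, int))
        assert abs(beta) < 3 * se

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1.0] * 10, range(1, 11), [1] * 10)

    def test_too_few_events_errors(self):
        with pytest.raises(ValueError, match="events"):
            cox_univariate(np.arange(10.0), range(1, 11), [1] + [0] * 9)


class TestResampledCoxScreen:
    def _setup(self, seed=0, n=150):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(0.8 * x))
        clin = _clinical(time, np.ones(n, int))
        groups = assign_outcome_groups(clin)
        ratio = pd.Series(x, index=clin.samples)
        return ratio, clin, groups

    def test_reproducible_given_seed(self):
        ratio, clin, groups = self._setup()
        cfg = RunConfig(n_resamples=50, rng_seed=3)
        from mirtarkey.config import stage_rng

        r1 = resampled_cox_screen(ratio, clin, groups, cfg, rng=stage_rng(3, "r"))
        r2 = resampled_cox_screen(ratio, clin, groups, cfg, rng=stage_rng(3, "r"))
        assert r1 == r2

    def test_strong_signal_passes(self):
        ratio, clin, groups = self._setup()
        cfg = RunConfig(n_resamples=50, rng_seed=1)
        res = resampled_cox_screen(ratio, clin, groups, cfg)
        assert res.passed and res.sig_freq > 0.9 and res.median_beta > 0

    def test_null_signal_rarely_passes(self):
        # resamples of one pair are strongly correlated, so judge the null
        # over many independent pairs rather than a single draw
        rng = np.random.default_rng(21)
        n = 150
        time = rng.exponential(1.0, size=n)
        clin = _clinical(time, np.ones(n, int))
        groups = assign_outcome_groups(clin)
        cfg = RunConfig(n_resamples=50, rng_seed=2)
        results = [
            resampled_cox_screen(
                pd.Series(rng.normal(size=n), index=clin.samples), clin, groups, cfg
            )
            for _ in range(12)
        ]
        assert sum(r.passed for r in results) <= 1
        assert np.median([r.sig_freq for r in results]) < 0.2

    def test_sig_freq_boundary_is_strict(self):
        cfg = RunConfig()
        assert not cox_screen_passes(True, 0.60, cfg)
        assert cox_screen_passes(True, 0.601, cfg)
        assert not cox_screen_passes(False, 0.99, cfg)

    def test_monotone_in_simulated_effect_size(self):
        avg_freqs = []
        for beta in (0.0, 0.4, 0.8, 1.2):
            cfg = small_sim_config(seed=77, cox_beta=beta)
            mirna, mrna, truth = simulate_expression(cfg)
            tumor = mirna.condition == "tumor"
            lm = np.log2(
                mirna.values.loc[:, tumor]
                / (mirna.values.loc[:, tumor].sum(axis=0) / 1e6)
                + 1
            )
            lg = np.log2(
                mrna.values.loc[:, tumor]
                / (mrna.values.loc[:, tumor].sum(axis=0) / 1e6)
                + 1
            )
            prog = truth.pairs[truth.pairs["is_prognostic"]]
            ratios = np.array(
                [
                    (lm.loc[r.mirna] - lg.loc[r.target]) * r.sign
                    for r in prog.itertuples()
                ]
            )
            clin = simulate_survival(cfg, ratios, tumor_samples=lm.columns)
            groups = assign_outcome_groups(clin)
            run_cfg = RunConfig(n_resamples=50, rng_seed=5)
            freqs = [
                resampled_cox_screen(
                    pd.Series(row, index=lm.columns), clin, groups, run_cfg
                ).sig_freq
                for row in ratios
            ]
            avg_freqs.append(np.mean(freqs))
        assert all(b >= a - 0.05 for a, b in zip(avg_freqs, avg_freqs[1:]))
        assert avg_freqs[-1] > avg_freqs[0]


class TestPatternSplitAndLogrank:
    def _states(self, values, n):
        return pd.DataFrame(
            {f"s{j}": [values[f][j] for f in values] for j in range(n)},
            index=list(values),
        )

    def test_perfect_anticorrelation_covers_everyone(self):
        sm = self._states({"m": [True] * 5 + [False] * 5}, 10)
        sg = self._states({"g": [False] * 5 + [True] * 5}, 10)
        a, b = pattern_split("m", "g", sm, sg)
        assert len(a) + len(b) == 10 and not set(a) & set(b)

    def test_independent_states_quarter_each(self):
        rng = np.random.default_rng(3)
        sizes_a, sizes_b = [], []
        for _ in range(100):
            sm = self._states({"m": rng.permutation([True] * 10 + [False] * 10).tolist()}, 20)
            sg = self._states({"g": rng.permutation([True] * 10 + [False] * 10).tolist()}, 20)
            a, b = pattern_split("m", "g", sm, sg)
            sizes_a.append(len(a) / 20)
            sizes_b.append(len(b) / 20)
        assert np.mean(sizes_a) == pytest.approx(0.25, abs=0.03)
        assert np.mean(sizes_b) == pytest.approx(0.25, abs=0.03)

    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2, 3, 4, 5]
        events = [1, 0, 1, 1, 0]
        stat, p = logrank_test(times, events, times, events)
        assert stat == pytest.approx(0, abs=1e-12) and p == pytest.approx(1)

    def test_symmetric_in_group_labels(self, survival_fixture):
        _, time, event = survival_fixture
        ta, tb = time[:25], time[25:]
        ea, eb = event[:25], event[25:]
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-9) and p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_bruteforce_oracle(self, survival_fixture):
        x, time, event = survival_fixture
        split = x > np.median(x)
        got = logrank_test(time[split], event[split], time[~split], event[~split])
        expected = logrank_bruteforce(time[split], event[split], time[~split], event[~split])
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
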
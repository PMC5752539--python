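import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import chi2_uncorrected_bruteforce, fisher_bruteforce
from mirtarkey import RunConfig
from mirtarkey.datatypes import ClinicalTable, ExpressionMatrix
from mirtarkey.evaluate import (
    chi_square_2x2,
    cluster_patients,
    cross_cohort_evaluation,
    evaluate_signature,
    fisher_exact_2x2,
    ratio_matrix,
    secondary_outcome_tests,
)


def _expr(values, kind, samples=None):
    df = pd.DataFrame(
        values,
        index=[f"{kind[0]}{i}" for i in range(len(values))],
        columns=samples or [f"s{j}" for j in range(len(values[0]))],
    )
    cond = pd.Series("tumor", index=df.columns)
    return ExpressionMatrix(df, kind, cond, scale="log2")


def _clinical(times, events, index, **extra):
    n = len(times)
    data = {
        "time": times,
        "event": events,
        "age": extra.pop("age", list(np.linspace(40, 80, n))),
        "gender": extra.pop("gender", ["male", "female"] * (n // 2) + ["male"] * (n % 2)),
    }
    data.update(extra)
    return ClinicalTable(pd.DataFrame(data, index=index))


class TestRatioMatrix:
    def _pairs(self):
        return pd.DataFrame({"mirna": ["m0", "m1"], "target": ["g0", "g1"]})

    def test_log_difference_matrix(self):
        m = _expr([[5.0, 6, 7], [1, 2, 3]], "mirna")
        g = _expr([[1.0, 1, 1], [2, 2, 2]], "gene")
        out = ratio_matrix(self._pairs(), m, g)
        assert out.shape == (2, 3)
        assert out.iloc[0].tolist() == [4.0, 5.0, 6.0]
        assert list(out.index) == ["m0:g0", "m1:g1"]

    def test_missing_feature_dropped_with_count(self, caplog):
        m = _expr([[5.0, 6]], "mirna")  # only m0
        g = _expr([[1.0, 1], [2.0, 2]], "gene")
        with caplog.at_level("WARNING"):
            out = ratio_matrix(self._pairs(), m, g)
        assert list(out.index) == ["m0:g0"]

    def test_all_missing_errors(self):
        m = _expr([[5.0]], "mirna")
        g = _expr([[1.0]], "gene")
        pairs = pd.DataFrame({"mirna": ["mX"], "target": ["gX"]})
        with pytest.raises(ValueError, match="measurable"):
            ratio_matrix(pairs, m, g)


class TestClusterPatients:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, size=(4, 30))
        b = rng.normal(5, 0.2, size=(4, 30))
        ratios = pd.DataFrame(np.hstack([a, b]), columns=[f"s{j}" for j in range(60)])
        clustering = cluster_patients(ratios, seed=1)
        labels = clustering.labels
        assert labels.iloc[:30].nunique() == 1 and labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(1)
        ratios = pd.DataFrame(rng.normal(size=(5, 40)))
        l1 = cluster_patients(ratios, seed=9).labels
        l2 = cluster_patients(ratios, seed=9).labels
        pd.testing.assert_series_equal(l1, l2)

    def test_degenerate_identical_patients_rejected(self):
        ratios = pd.DataFrame(np.ones((3, 10)))
        with pytest.raises(ValueError, match="degenerate"):
            cluster_patients(ratios, seed=0)

    def test_fewer_patients_than_k_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            cluster_patients(pd.DataFrame([[1.0]]), seed=0)


class TestEvaluateSignature:
    def _risky_cohort(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        risk = np.repeat([0, 1], n // 2)
        time = rng.exponential(1 / np.exp(1.2 * risk))
        samples = [f"s{j}" for j in range(n)]
        clin = _clinical(time, np.ones(n, int), samples,
                         age=rng.uniform(40, 80, n).tolist())
        labels = pd.Series(risk + 1, index=samples, name="cluster")
        from mirtarkey.evaluate import PatientClustering

        clustering = PatientClustering(labels, 0.0, 25, seed, 3)
        return clustering, clin

    def test_planted_risk_split_significant_with_hr_above_one(self):
        clustering, clin = self._risky_cohort()
        ev = evaluate_signature(clustering, clin)
        assert ev.logrank_p < 1e-6
        assert ev.hazard_ratio > 1.5 and ev.hr_p < 1e-6

    def test_label_swap_leaves_oriented_hr_unchanged(self):
        clustering, clin = self._risky_cohort()
        ev1 = evaluate_signature(clustering, clin)
        swapped = clustering
        swapped.labels = 3 - swapped.labels  # 1<->2
        ev2 = evaluate_signature(swapped, clin)
        assert ev1.hazard_ratio == pytest.approx(ev2.hazard_ratio, rel=1e-6)
        assert ev1.logrank_p == pytest.approx(ev2.logrank_p, rel=1e-9)

    def test_random_clusters_null_p_uniform(self):
        pvals = []
        for rep in range(40):
            rng = np.random.default_rng(200 + rep)
            n = 80
            samples = [f"s{j}" for j in range(n)]
            clin = _clinical(rng.exponential(1, n), np.ones(n, int), samples)
            labels = pd.Series(rng.choice([1, 2], n), index=samples)
            from mirtarkey.evaluate import PatientClustering

            ev = evaluate_signature(PatientClustering(labels, 0, 1, 0, 1), clin)
            pvals.append(ev.logrank_p)
        assert np.mean(np.array(pvals) < 0.05) <= 0.15
        ks = stats.kstest(pvals, "uniform").pvalue
        assert ks > 0.01

    def test_patient_order_invariance(self):
        clustering, clin = self._risky_cohort()
        ev1 = evaluate_signature(clustering, clin)
        perm = np.random.default_rng(5).permutation(clin.data.index)
        clin2 = ClinicalTable(clin.data.loc[perm])
        ev2 = evaluate_signature(clustering, clin2)
        assert ev1.logrank_p == pytest.approx(ev2.logrank_p, rel=1e-9)
        assert ev1.hazard_ratio == pytest.approx(ev2.hazard_ratio, rel=1e-6)


class TestCrossCohort:
    def test_self_transfer_reproduces_direct_evaluation(self):
        rng = np.random.default_rng(3)
        n = 60
        m = _expr(rng.normal(5, 1, (4, n)), "mirna")
        g = _expr(rng.normal(3, 1, (4, n)), "gene")
        pairs = pd.DataFrame(
            {"mirna": [f"m{i}" for i in range(4)], "target": [f"g{i}" for i in range(4)]}
        )
        clin = _clinical(rng.exponential(1, n), np.ones(n, int), list(m.samples))
        direct_ratios = ratio_matrix(pairs, m, g)
        direct = evaluate_signature(cluster_patients(direct_ratios, seed=4), clin)
        transfer = cross_cohort_evaluation(pairs, m, g, clin, seed=4)
        assert transfer.logrank_p == direct.logrank_p
        assert transfer.hazard_ratio == direct.hazard_ratio
        assert transfer.n_transferable == 4

    def test_too_few_transferable_errors(self):
        rng = np.random.default_rng(4)
        m = _expr(rng.normal(size=(1, 10)), "mirna")
        g = _expr(rng.normal(size=(1, 10)), "gene")
        pairs = pd.DataFrame({"mirna": ["m0", "mX", "mY"], "target": ["g0", "gX", "gY"]})
        clin = _clinical(rng.exponential(1, 10), np.ones(10, int), list(m.samples))
        with pytest.raises(ValueError, match="transferable"):
            cross_cohort_evaluation(pairs, m, g, clin)


class TestContingencyTests:
    def test_literature_risk_table_p(self):
        _, p = chi_square_2x2([[42, 9], [45, 35]])
        assert round(p, 3) == 0.004

    def test_literature_metastasis_table_p(self):
        _, p = chi_square_2x2([[34, 17], [32, 48]])
        assert round(p, 3) == 0.005

    def test_independent_table_statistic_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0) and p == pytest.approx(1)

    def test_uncorrected_matches_textbook_formula(self):
        table = [[42, 9], [45, 35]]
        stat, _ = chi_square_2x2(table, continuity=False)
        assert stat == pytest.approx(chi2_uncorrected_bruteforce(table), rel=1e-9)

    def test_zero_marginal_suggests_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_fisher_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_bruteforce(t.tolist()), rel=1e-9
            )

    def test_fisher_transpose_invariance(self):
        t = [[3, 8], [12, 2]]
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_exact_2x2(np.transpose(t)), rel=1e-12
        )

    def test_chi2_and_fisher_agree_on_large_cells(self):
        rng = np.random.default_rng(7)
        agree = 0
        n_tables = 100
        for _ in range(n_tables):
            t = rng.integers(10, 60, size=(2, 2))
            _, p_chi = chi_square_2x2(t)
            p_f = fisher_exact_2x2(t)
            agree += (p_chi < 0.05) == (p_f < 0.05)
        assert agree >= 95


class TestSecondaryOutcomes:
    def _clustering(self, samples, labels):
        from mirtarkey.evaluate import PatientClustering

        return PatientClustering(pd.Series(labels, index=samples), 0, 1, 0, 1)

    def test_missing_kps_reported_unavailable(self):
        n = 20
        samples = [f"s{j}" for j in range(n)]
        clin = _clinical(np.arange(1, n + 1), [1] * n, samples)
        out = secondary_outcome_tests(
            self._clustering(samples, [1, 2] * (n // 2)), clin
        ).set_index("test")
        assert not out.loc["kps_fisher", "available"]
        assert np.isnan(out.loc["kps_fisher", "p"])

    def test_kps_sixty_counts_as_not_impaired(self):
        n = 40
        samples = [f"s{j}" for j in range(n)]
        kps = [60] * 20 + [50] * 20  # exactly-60 must not count as < 60
        labels = [1] * 20 + [2] * 20
        clin = _clinical(np.arange(1, n + 1), [1] * n, samples, kps=kps)
        out = secondary_outcome_tests(self._clustering(samples, labels), clin).set_index("test")
        # all KPS<60 patients sit in cluster 2: maximally unbalanced table
        expected = fisher_exact_2x2([[0, 20], [20, 0]])
        assert out.loc["kps_fisher", "p"] == pytest.approx(expected)

    def test_null_kps_p_uniform(self):
        pvals = []
        for rep in range(30):
            rng = np.random.default_rng(300 + rep)
            n = 60
            samples = [f"s{j}" for j in range(n)]
            clin = _clinical(
                rng.exponential(1, n), [1] * n, samples,
                kps=rng.choice([40, 50, 60, 70, 80], n).tolist(),
            )
            labels = rng.choice([1, 2], n)
            out = secondary_outcome_tests(self._clustering(samples, labels), clin)
            pvals.append(out.set_index("test").loc["kps_fisher", "p"])
        assert np.mean(np.array(pvals) < 0.05) <= 0.15
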
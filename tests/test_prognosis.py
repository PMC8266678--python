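import numpy as np
import pytest

from reode.model import AlterationMatrix, ContingencyTable2x2, IDEProfile
from reode.prognosis import (
    SurvivalRecord,
    cluster_two_classes,
    compare_classes_continuous,
    compare_classes_frequency,
    logrank_test,
    prognostic_filter,
    tmb_counts,
)
from reode.simulate import two_archetype_profile


def records(times, events, prefix="s"):
    return [SurvivalRecord(f"{prefix}{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


def profile_from_calls(gene_ids, sample_ids, calls):
    calls = np.asarray(calls, dtype=np.int8)
    shape = calls.shape
    return IDEProfile(gene_ids, sample_ids, calls, np.full(shape, np.nan),
                      np.full(shape, np.nan))


class TestLogRank:
    def test_identical_groups(self):
        a = records([1, 2, 3], [1, 1, 0], "a")
        b = records([1, 2, 3], [1, 1, 0], "b")
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_subject_toy(self):
        # direct evaluation of the O/E/V sums gives 2.882
        a = records([1, 2], [1, 1], "a")
        b = records([3, 4], [1, 1], "b")
        chi2, _ = logrank_test(a, b)
        assert chi2 == pytest.approx(2.882, abs=1e-3)

    def test_no_events_error(self):
        a = records([1, 2], [0, 0], "a")
        b = records([3, 4], [1, 1], "b")
        with pytest.raises(ValueError):
            logrank_test(a, b)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        a = records(rng.exponential(10, 20), rng.random(20) < 0.8, "a")
        b = records(rng.exponential(20, 15), rng.random(15) < 0.8, "b")
        chi2, p = logrank_test(a, b)
        res = lifelines.statistics.logrank_test(
            [r.time for r in a], [r.time for r in b],
            [r.event for r in a], [r.event for r in b])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)


class TestPrognosticFilter:
    def test_separating_gene_kept(self):
        n = 24
        samples = [f"s{j}" for j in range(n)]
        calls = np.zeros((1, n), dtype=np.int8)
        calls[0, :8] = 1  # called samples die early
        surv = {}
        for j, s in enumerate(samples):
            if j < 8:
                surv[s] = SurvivalRecord(s, 10.0 + j, 1)
            else:
                surv[s] = SurvivalRecord(s, 500.0 + j, 1 if j < 12 else 0)
        profile = profile_from_calls(["g1"], samples, calls)
        kept, detail = prognostic_filter(profile, surv)
        assert kept == ["g1"]
        assert detail.p[0] < 0.05

    def test_sparse_gene_skipped(self):
        samples = [f"s{j}" for j in range(10)]
        calls = np.zeros((1, 10), dtype=np.int8)
        calls[0, 0] = 1
        surv = {s: SurvivalRecord(s, 100.0 + j, 1)
                for j, s in enumerate(samples)}
        profile = profile_from_calls(["g1"], samples, calls)
        kept, detail = prognostic_filter(profile, surv)
        assert kept == []
        assert detail.empty

    def test_type_one_rate_under_permutation(self):
        """Keep rate under label permutation is ~alpha (binomial bounds)."""
        rng = np.random.default_rng(12)
        n = 40
        samples = [f"s{j}" for j in range(n)]
        calls = np.zeros((1, n), dtype=np.int8)
        calls[0, :15] = 1
        profile = profile_from_calls(["g1"], samples, calls)
        times = rng.exponential(100, n)
        keeps = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(n)
            surv = {samples[j]: SurvivalRecord(samples[j], float(times[perm[j]]), 1)
                    for j in range(n)}
            kept, _ = prognostic_filter(profile, surv, alpha=0.05)
            keeps += bool(kept)
        # 3 binomial sd around 0.05 at 200 draws
        assert keeps / n_perm <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_perm)


class TestClustering:
    def test_hamming_distance_example(self):
        from scipy.spatial.distance import hamming
        assert hamming([1, 0, -1], [1, 1, -1]) == pytest.approx(1 / 3)

    def test_two_identical_pairs(self):
        calls = np.array([[1, 1, -1, -1],
                          [0, 0, 1, 1],
                          [-1, -1, 0, 0]])
        profile = profile_from_calls(["g1", "g2", "g3"],
                                     ["s1", "s2", "s3", "s4"], calls)
        res = cluster_two_classes(profile)
        assert res.assignments["s1"] == res.assignments["s2"]
        assert res.assignments["s3"] == res.assignments["s4"]
        assert res.assignments["s1"] != res.assignments["s3"]

    def test_larger_class_is_one(self):
        calls = np.array([[1, 1, 1, -1]])
        profile = profile_from_calls(["g1"], ["s1", "s2", "s3", "s4"], calls)
        res = cluster_two_classes(profile)
        assert res.assignments["s4"] == 2
        assert [res.assignments[s] for s in ("s1", "s2", "s3")] == [1, 1, 1]

    def test_archetype_recovery_rand(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        profile, classes = two_archetype_profile(n_genes=30, n_class1=30,
                                                 n_class2=10, noise=0.1, seed=5)
        res = cluster_two_classes(profile)
        y_true = [classes[s] for s in sorted(classes)]
        y_pred = [res.assignments[s] for s in sorted(classes)]
        assert sklearn_metrics.rand_score(y_true, y_pred) >= 0.9

    def test_invariant_to_gene_and_sample_order(self):
        profile, _ = two_archetype_profile(seed=9)
        res = cluster_two_classes(profile)
        shuffled = IDEProfile(
            list(reversed(profile.gene_ids)), list(reversed(profile.sample_ids)),
            profile.calls[::-1, ::-1].copy(),
            profile.p_values[::-1, ::-1].copy(),
            profile.q_values[::-1, ::-1].copy())
        res2 = cluster_two_classes(shuffled)
        agree = [res.assignments[s] == res2.assignments[s]
                 for s in profile.sample_ids]
        assert all(agree) or not any(agree)  # equal up to label swap

    def test_degenerate_flagged(self):
        calls = np.ones((2, 3), dtype=np.int8)
        profile = profile_from_calls(["g1", "g2"], ["s1", "s2", "s3"], calls)
        res = cluster_two_classes(profile)
        assert res.degenerate


class TestCompareClasses:
    def test_identical_distributions(self):
        cov = {"x": {f"s{j}": float(j % 3) for j in range(12)}}
        assignments = {f"s{j}": 1 if j < 6 else 2 for j in range(12)}
        res = compare_classes_continuous(cov, assignments)
        assert res["x"].test.p_value == pytest.approx(1.0)

    def test_rank_enumeration(self):
        cov = {"x": {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0, "f": 6.0}}
        assignments = {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}
        res = compare_classes_continuous(cov, assignments)
        assert res["x"].test.p_value == pytest.approx(0.1, rel=1e-9)

    def test_constant_covariate_flagged(self):
        cov = {"x": {f"s{j}": 1.0 for j in range(8)}}
        assignments = {f"s{j}": 1 if j < 4 else 2 for j in range(8)}
        res = compare_classes_continuous(cov, assignments)
        assert res["x"].constant
        assert res["x"].test.p_value == 1.0

    def test_missing_class_errors_with_name(self):
        cov = {"hrd": {"s0": 1.0, "s1": 2.0}}
        assignments = {"s0": 1, "s1": 1, "s2": 2, "s3": 2}
        with pytest.raises(ValueError, match="hrd"):
            compare_classes_continuous(cov, assignments)

    def test_frequency_printed_tables(self):
        # class 1: 42 upregulated / 24 not; class 2: 7 / 15
        n1, n2 = 66, 22
        samples = [f"s{j}" for j in range(n1 + n2)]
        calls = np.zeros((1, n1 + n2), dtype=np.int8)
        calls[0, :42] = 1
        calls[0, n1:n1 + 7] = 1
        assignments = {s: 1 if j < n1 else 2 for j, s in enumerate(samples)}
        profile = profile_from_calls(["pd1"], samples, calls)
        res = compare_classes_frequency(profile, assignments, ["pd1"])
        assert round(res.p[0], 3) == 0.013

    def test_frequency_equal_proportions(self):
        samples = [f"s{j}" for j in range(20)]
        calls = np.zeros((1, 20), dtype=np.int8)
        calls[0, :5] = 1
        calls[0, 10:15] = 1
        assignments = {s: 1 if j < 10 else 2 for j, s in enumerate(samples)}
        profile = profile_from_calls(["g"], samples, calls)
        res = compare_classes_frequency(profile, assignments, ["g"])
        assert res.p[0] == pytest.approx(1.0)


class TestTMB:
    def test_column_sums(self):
        mut = AlterationMatrix("mutation", ["g1", "g2", "g3"], ["s1", "s2"],
                              np.array([[1, 0], [1, 1], [1, 0]]))
        nsm = AlterationMatrix("nonsilent_mutation", ["g1", "g2", "g3"],
                               ["s1", "s2"], np.array([[1, 0], [0, 1], [1, 0]]))
        df = tmb_counts(mut, nsm)
        assert df.n_mutations.tolist() == [3, 1]
        assert df.n_nonsilent.tolist() == [2, 1]

    def test_nonsilent_subset_in_simulation(self, small_dataset):
        df = tmb_counts(small_dataset.alterations["mutation"],
                        small_dataset.alterations["nonsilent_mutation"])
        assert (df.n_nonsilent <= df.n_mutations).all()

    def test_all_zero(self):
        mut = AlterationMatrix("mutation", ["g1"], ["s1"], np.array([[0]]))
        nsm = AlterationMatrix("nonsilent_mutation", ["g1"], ["s1"],
                               np.array([[0]]))
        df = tmb_counts(mut, nsm)
        assert df.n_mutations.tolist() == [0]
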
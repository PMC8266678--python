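import numpy as np
import pytest

from reode.individualize import build_profile
from reode.model import AlterationMatrix, IDEProfile
from reode.pairs import find_stable_pairs
from reode.simulate import SimulationConfig, generate_dataset
from reode.stats import hypergeom_upper_tail
from reode.subtypes import (
    cooccurrence_network,
    intersection_counts,
    ora_hypergeometric,
    over_represented,
    subtype_specific,
)


def profile_from_calls(gene_ids, sample_ids, calls):
    calls = np.asarray(calls, dtype=np.int8)
    shape = calls.shape
    return IDEProfile(gene_ids, sample_ids, calls, np.full(shape, np.nan),
                      np.full(shape, np.nan))


class TestOverRepresented:
    def test_enriched_gene_single_test(self):
        # DE in 8/10 of subtype A vs 2/30 of the rest
        calls = np.zeros((1, 40), dtype=np.int8)
        calls[0, :8] = 1          # 8 of the 10 A samples
        calls[0, 10:12] = -1      # 2 of the 30 B samples
        samples = [f"s{j}" for j in range(40)]
        labels = {s: ("A" if j < 10 else "B") for j, s in enumerate(samples)}
        profile = profile_from_calls(["g1"], samples, calls)
        sets, detail = over_represented(profile, labels)
        assert "g1" in sets["A"]
        row = detail[(detail.subtype == "A") & (detail.gene_id == "g1")].iloc[0]
        assert row.p == pytest.approx(
            hypergeom_upper_tail(40, 10, 10, 8), rel=1e-9)
        assert row.p == pytest.approx(2.3448e-5, rel=1e-3)

    def test_uniform_frequency_not_enriched(self):
        rng = np.random.default_rng(4)
        calls = (rng.random((5, 60)) < 0.10).astype(np.int8)
        samples = [f"s{j}" for j in range(60)]
        labels = {s: ("A" if j < 30 else "B") for j, s in enumerate(samples)}
        profile = profile_from_calls([f"g{i}" for i in range(5)], samples, calls)
        sets, _ = over_represented(profile, labels)
        assert not sets["A"] and not sets["B"]

    def test_frequency_gate(self):
        # 1/20 in subtype A is under the 5% gate regardless of significance
        calls = np.zeros((1, 40), dtype=np.int8)
        calls[0, 0] = 1
        samples = [f"s{j}" for j in range(40)]
        labels = {s: ("A" if j < 20 else "B") for j, s in enumerate(samples)}
        profile = profile_from_calls(["g1"], samples, calls)
        sets, _ = over_represented(profile, labels, min_freq=0.05)
        assert "g1" not in sets["A"]

    def test_small_subtype_skipped_with_warning(self):
        calls = np.zeros((1, 5), dtype=np.int8)
        samples = [f"s{j}" for j in range(5)]
        labels = {samples[0]: "tiny", **{s: "B" for s in samples[1:]}}
        profile = profile_from_calls(["g1"], samples, calls)
        with pytest.warns(UserWarning, match="tiny"):
            sets, _ = over_represented(profile, labels)
        assert "tiny" not in sets

    def test_planted_subtype_recovery(self):
        cfg = SimulationConfig(n_genes=120, n_normals=40, n_tumors=90,
                               n_subtypes=3, subtype_genes_per_subtype=3,
                               subtype_de_frac=0.4, background_de_frac=0.02,
                               seed=19)
        ds = generate_dataset(cfg)
        pairs = find_stable_pairs(ds.normals, 0.99)
        profile = build_profile(ds.tumors, pairs)
        labels = {a.sample_id: a.subtype for a in ds.annotations}
        sets, _ = over_represented(profile, labels)
        recovered = sum(g in sets.get(home, set())
                        for g, home in ds.truth.subtype_of_gene.items())
        assert recovered >= 0.8 * len(ds.truth.subtype_of_gene)


class TestSubtypeSpecific:
    def test_exclusivity(self):
        sets = {"A": {"x", "y"}, "B": {"y", "z"}}
        specific = subtype_specific(sets)
        assert specific == {"A": {"x"}, "B": {"z"}}

    def test_empty(self):
        assert subtype_specific({"A": set()}) == {"A": set()}

    def test_disjoint_and_subset_properties(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        sets = {name: {g for g in universe if rng.random() < 0.3}
                for name in "ABC"}
        specific = subtype_specific(sets)
        names = list(specific)
        for i, a in enumerate(names):
            assert specific[a] <= sets[a]
            for b in names[i + 1:]:
                assert not (specific[a] & specific[b])


class TestIntersectionCounts:
    def test_basic(self):
        counts = intersection_counts({"A": {"x", "y"}, "B": {"y", "z"}})
        assert counts == {frozenset({"A"}): 1, frozenset({"B"}): 1,
                          frozenset({"A", "B"}): 1}

    def test_disjoint(self):
        counts = intersection_counts({"A": {"x"}, "B": {"y"}})
        assert frozenset({"A", "B"}) not in counts

    def test_identical_sets(self):
        counts = intersection_counts({"A": {"x", "y"}, "B": {"x", "y"}})
        assert counts == {frozenset({"A", "B"}): 2}

    def test_sums_to_union(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "d"}, "C": {"e"}}
        counts = intersection_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            intersection_counts({})


class TestCooccurrence:
    def _setup(self, lnc_samples, alt_samples, n=10):
        samples = [f"s{j}" for j in range(n)]
        calls = np.zeros((1, n), dtype=np.int8)
        for s in lnc_samples:
            calls[0, s] = 1
        flags = np.zeros((1, n), dtype=np.int8)
        for s in alt_samples:
            flags[0, s] = 1
        profile = profile_from_calls(["lnc1"], samples, calls)
        alt = AlterationMatrix("mutation", ["pc1"], samples, flags)
        return profile, alt, samples

    def test_perfect_cooccurrence_edge(self):
        profile, alt, samples = self._setup(range(5), range(5))
        edges = cooccurrence_network(profile, alt, samples, ["lnc1"], ["pc1"])
        assert len(edges) == 1
        assert edges[0].p == pytest.approx(2 / 252, rel=1e-9)
        assert edges[0].odds_ratio == np.inf

    def test_mutual_exclusion_no_edge(self):
        profile, alt, samples = self._setup(range(5), range(5, 10))
        edges = cooccurrence_network(profile, alt, samples, ["lnc1"], ["pc1"])
        assert edges == []

    def test_independent_pattern_no_edge(self):
        # table [[2,3],[2,3]]: identical proportions, p = 1 -> no edge
        profile, alt, samples = self._setup(range(5), [0, 1, 5, 6], n=10)
        edges = cooccurrence_network(profile, alt, samples, ["lnc1"], ["pc1"])
        assert edges == []

    def test_symmetry_in_binary_vectors(self):
        profile, alt, samples = self._setup([0, 1, 2, 5], [0, 1, 2, 6], n=12)
        edges = cooccurrence_network(profile, alt, samples, ["lnc1"], ["pc1"],
                                     p_cut=1.01)
        # swap roles: calls become flags and vice versa
        calls = np.zeros((1, 12), dtype=np.int8)
        calls[0, [0, 1, 2, 6]] = 1
        flags = np.zeros((1, 12), dtype=np.int8)
        flags[0, [0, 1, 2, 5]] = 1
        profile_swapped = profile_from_calls(["lnc1"], samples, calls)
        alt_swapped = AlterationMatrix("mutation", ["pc1"], samples, flags)
        swapped = cooccurrence_network(profile_swapped, alt_swapped, samples,
                                       ["lnc1"], ["pc1"], p_cut=1.01)
        assert len(edges) == len(swapped) == 1
        assert edges[0].p == pytest.approx(swapped[0].p, rel=1e-12)
        assert edges[0].odds_ratio == pytest.approx(swapped[0].odds_ratio,
                                                    rel=1e-12)

    def test_constant_vectors_skipped(self):
        profile, alt, samples = self._setup(range(10), range(3))
        edges = cooccurrence_network(profile, alt, samples, ["lnc1"], ["pc1"],
                                     p_cut=1.01)
        assert edges == []  # all-called lncRNA carries no contrast

    def test_empty_samples_rejected(self):
        profile, alt, _ = self._setup(range(3), range(3))
        with pytest.raises(ValueError):
            cooccurrence_network(profile, alt, [], ["lnc1"], ["pc1"])


class TestORA:
    def test_single_term(self):
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        res = ora_hypergeometric(pathway, {"p1": pathway}, universe)
        assert res.p[0] == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_is_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = ora_hypergeometric({"g0"}, {"p1": {"g10", "g11"}}, universe)
        assert res.p[0] == pytest.approx(1.0)

    def test_pathway_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_hypergeometric({"g0", "g1"}, {"p1": set(universe)}, universe)
        assert res.p[0] == pytest.approx(1.0)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"p": set()}, set())

    def test_selected_outside_universe(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"gX"}, {"p": set()}, {"g0"})
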
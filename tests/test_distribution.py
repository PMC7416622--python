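"""Family building, subfamily splitting, 1/m node weighting, KDE peaks."""

import math
import random

import numpy as np
import pytest

import wgdkit as w
from wgdkit.distribution import pairwise_ks, subfamily_tree, weight_node_ks
from wgdkit.ks import KsResult
from wgdkit.model import HomologyEdge, WeightedKsEntry

from oracles import complete_linkage_oracle, components_oracle


def _edge(a, b, ev=1e-50):
    return HomologyEdge(a, b, bitscore=100.0, evalue=ev)


def _ksmat(pairs):
    """Build a fake Ks matrix from {(a,b): ks}."""
    out = {}
    for (a, b), ks in pairs.items():
        key = (a, b) if a < b else (b, a)
        out[key] = KsResult(
            ks=ks, ka=0.1, pS=0.1, pN=0.1, S_sites=100, N_sites=200,
            Sd=1, Nd=1, saturated=not math.isfinite(ks), n_codons=100,
        )
    return out


class TestFamilies:
    def test_transitive_components(self):
        fams = w.build_families([_edge("a", "b"), _edge("b", "c")])
        assert len(fams) == 1 and fams[0].members == ["a", "b", "c"]

    def test_no_edges_no_families(self):
        assert w.build_families([]) == []

    def test_cutoff_splits_graph(self):
        fams = w.build_families(
            [_edge("a", "b"), _edge("b", "c", ev=1e-3)], evalue_cutoff=1e-10
        )
        assert [f.members for f in fams] == [["a", "b"]]

    def test_random_graph_matches_component_oracle(self):
        rnd = random.Random(7)
        genes = [f"g{i:02d}" for i in range(50)]
        edges = [
            _edge(*rnd.sample(genes, 2))
            for _ in range(60)
        ]
        fams = w.build_families(edges)
        expected = [c for c in components_oracle(50, [(e.gene_a, e.gene_b) for e in edges]) if len(c) >= 2]
        assert [f.members for f in fams] == expected


class TestSubfamilies:
    def test_threshold_forces_split(self):
        km = _ksmat({("a", "b"): 0.5, ("a", "c"): 6.0, ("b", "c"): 6.0})
        assert w.split_subfamilies(["a", "b", "c"], km, max_ks=5) == [["a", "b"], ["c"]]

    def test_all_below_ceiling_stays_whole(self):
        km = _ksmat({("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 3.0})
        assert w.split_subfamilies(["a", "b", "c"], km, max_ks=5) == [["a", "b", "c"]]

    def test_saturated_pairs_treated_as_distant(self):
        km = _ksmat({("a", "b"): 0.5, ("a", "c"): math.inf, ("b", "c"): math.inf})
        assert w.split_subfamilies(["a", "b", "c"], km, max_ks=5) == [["a", "b"], ["c"]]

    def test_matches_naive_complete_linkage(self):
        rnd = random.Random(3)
        for _ in range(20):
            members = [f"m{i}" for i in range(8)]
            dist = {}
            pairs = {}
            for i in range(8):
                for j in range(i + 1, 8):
                    d = rnd.uniform(0.1, 10.0)
                    dist[frozenset((members[i], members[j]))] = d
                    pairs[(members[i], members[j])] = d
            km = _ksmat(pairs)
            got = w.split_subfamilies(members, km, max_ks=5)
            expected = complete_linkage_oracle(members, dist, cutoff=5)
            assert sorted(got) == expected
            # all-pairs condition holds
            for sub in got:
                for i, a in enumerate(sub):
                    for b in sub[i + 1 :]:
                        assert pairs[(a, b) if a < b else (b, a)] <= 5


class TestSubfamilyTree:
    def test_two_members_join_at_half_ks(self):
        km = _ksmat({("a", "b"): 0.8})
        tree = subfamily_tree(["a", "b"], km)
        assert tree.height == pytest.approx(0.4)
        assert sorted(tree.leaves()) == ["a", "b"]

    def test_ultrametric_matrix_recovers_topology(self):
        km = _ksmat({("a", "b"): 0.2, ("a", "c"): 1.0, ("b", "c"): 1.0})
        tree = subfamily_tree(["a", "b", "c"], km)
        shallow = min(tree.internal_nodes(), key=lambda n: n.height)
        assert sorted(shallow.leaves()) == ["a", "b"]

    def test_six_taxa_ultrametric_recovery(self):
        # true clades: ((a,b),(c,d)) at heights .1/.1/.4 and (e,f) at .2; root 1.0
        ages = {
            ("a", "b"): 0.2, ("c", "d"): 0.2, ("e", "f"): 0.4,
            ("a", "c"): 0.8, ("a", "d"): 0.8, ("b", "c"): 0.8, ("b", "d"): 0.8,
        }
        members = list("abcdef")
        pairs = {}
        for i, x in enumerate(members):
            for y in members[i + 1 :]:
                pairs[(x, y)] = ages.get((x, y), 2.0)
        tree = subfamily_tree(members, _ksmat(pairs))
        clades = {tuple(sorted(n.leaves())) for n in tree.internal_nodes()}
        assert {("a", "b"), ("c", "d"), ("e", "f"), ("a", "b", "c", "d")} <= clades


class TestWeighting:
    def test_three_leaf_weights(self):
        km = _ksmat({("a", "b"): 0.2, ("a", "c"): 1.0, ("b", "c"): 1.0})
        entries = weight_node_ks(subfamily_tree(["a", "b", "c"], km), km)
        by_pair = {(e.gene_a, e.gene_b): e.weight for e in entries}
        assert by_pair == {("a", "b"): 1.0, ("a", "c"): 0.5, ("b", "c"): 0.5}

    def test_five_members_mass(self):
        rnd = random.Random(1)
        members = list("abcde")
        pairs = {
            (x, y): rnd.uniform(0.1, 2.0)
            for i, x in enumerate(members)
            for y in members[i + 1 :]
        }
        km = _ksmat(pairs)
        entries = weight_node_ks(subfamily_tree(members, km), km)
        assert len(entries) == 10  # n(n-1)/2 pairwise estimates
        assert sum(e.weight for e in entries) == pytest.approx(4.0)  # n-1 events

    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_random_trees_conserve_mass(self, n):
        rnd = random.Random(n)
        members = [f"g{i}" for i in range(n)]
        pairs = {
            (x, y): rnd.uniform(0.05, 3.0)
            for i, x in enumerate(members)
            for y in members[i + 1 :]
        }
        km = _ksmat(pairs)
        entries = weight_node_ks(subfamily_tree(members, km), km)
        assert len(entries) == n * (n - 1) // 2
        per_node = {}
        for e in entries:
            per_node[e.node_id] = per_node.get(e.node_id, 0.0) + e.weight
        for mass in per_node.values():
            assert mass == pytest.approx(1.0, abs=1e-9)
        assert sum(per_node.values()) == pytest.approx(n - 1, abs=1e-9)

    def test_distribution_invariant_to_duplicated_input_rows(self, single_wgd_result):
        """Weights come from the subfamily tree, not from row counts."""
        res = single_wgd_result
        sub = res.homology[:400]
        d1 = w.paranome_distribution(res.cds, sub)
        d2 = w.paranome_distribution(res.cds, sub + sub)
        key = lambda d: sorted((e.gene_a, e.gene_b, round(e.ks, 9), round(e.weight, 9)) for e in d.entries)
        assert key(d1) == key(d2)


class TestKdePeaks:
    def test_point_mass(self):
        peak, lo, hi = w.bootstrap_peak_ci([1.3] * 20, B=100, seed=1)
        assert peak == pytest.approx(1.3)
        assert hi - lo == pytest.approx(0.0)

    def test_normal_sample_peak_location(self, rng):
        vals = rng.normal(1.0, 0.2, 500)
        peak, lo, hi = w.bootstrap_peak_ci(vals, B=200, seed=2)
        assert abs(peak - 1.0) <= 0.05
        assert lo <= 1.0 <= hi

    def test_mixture_reports_secondary_peak(self, rng):
        vals = np.concatenate(
            [rng.normal(0.9, 0.15, 700), rng.normal(3.0, 0.3, 300)]
        )
        peaks = w.kde_peaks(vals)
        assert abs(peaks[0][0] - 0.9) <= 0.1  # global mode
        assert any(abs(p - 3.0) <= 0.25 for p, _d in peaks[1:])

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="more data"):
            w.kde_peak([1.0] * 9)

    def test_deterministic_given_seed(self, rng):
        vals = rng.normal(1.0, 0.2, 200)
        assert w.bootstrap_peak_ci(vals, B=100, seed=9) == w.bootstrap_peak_ci(
            vals, B=100, seed=9
        )


class TestWindow:
    def _entries(self, values):
        return [
            WeightedKsEntry("a", "b", ks=v, weight=1.0, node_id="n", m=1)
            for v in values
        ]

    def test_closed_interval_boundaries(self):
        kept = w.select_window(self._entries([0.59, 0.6, 1.0, 1.4, 1.41]), 0.6, 1.4)
        assert [e.ks for e in kept] == [0.6, 1.0, 1.4]

    def test_empty_input(self):
        assert w.select_window([], 0.6, 1.4) == []

    def test_matches_brute_force_filter(self, rng):
        vals = rng.uniform(0, 3, 1000)
        kept = w.select_window(self._entries(vals), 0.6, 1.4)
        assert len(kept) == int(np.sum((vals >= 0.6) & (vals <= 1.4)))


class TestParanomePipeline:
    def test_weighted_peak_near_true_age(self, single_wgd_result):
        res = single_wgd_result
        dist = w.paranome_distribution(res.cds, res.homology)
        assert len(dist) > 10
        peak = w.kde_peak(dist.values, dist.weights)
        assert 0.85 <= peak <= 1.15


class TestAlternativeBackends:
    def test_single_linkage_is_looser_than_complete(self):
        # chain a-b-c with 3.0 steps but a-c at 6.0: single keeps the chain
        km = _ksmat({("a", "b"): 3.0, ("b", "c"): 3.0, ("a", "c"): 6.0})
        assert w.split_subfamilies(["a", "b", "c"], km, max_ks=5) == [["a", "b"], ["c"]]
        assert w.split_subfamilies(
            ["a", "b", "c"], km, max_ks=5, method="single"
        ) == [["a", "b", "c"]]

    def test_nj_fallback_conserves_weight_mass(self):
        rnd = random.Random(9)
        members = [f"g{i}" for i in range(6)]
        pairs = {
            (x, y): rnd.uniform(0.2, 2.0)
            for i, x in enumerate(members)
            for y in members[i + 1 :]
        }
        km = _ksmat(pairs)
        tree = subfamily_tree(members, km, method="nj")
        entries = weight_node_ks(tree, km)
        assert len(entries) == 15
        per_node = {}
        for e in entries:
            per_node[e.node_id] = per_node.get(e.node_id, 0.0) + e.weight
        for mass in per_node.values():
            assert mass == pytest.approx(1.0, abs=1e-9)
        assert sum(per_node.values()) == pytest.approx(5.0, abs=1e-9)

    def test_nj_fallback_recovers_ultrametric_topology(self):
        km = _ksmat({("a", "b"): 0.2, ("a", "c"): 1.0, ("b", "c"): 1.0})
        tree = subfamily_tree(["a", "b", "c"], km, method="nj")
        clades = {tuple(sorted(n.leaves())) for n in tree.internal_nodes()}
        assert ("a", "b") in clades

    def test_records_export(self, single_wgd_result):
        res = single_wgd_result
        dist = w.paranome_distribution(res.cds, res.homology)
        recs = w.distribution_to_records(dist)
        assert len(recs) == len(dist)
        assert set(recs[0]) == {"gene_a", "gene_b", "ks", "weight", "node_id", "m"}
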
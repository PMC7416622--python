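"""Gene-tree building, rooting, reconciliation and anchor placement."""

import random

import numpy as np
import pytest

import wgdkit as w
from wgdkit.model import GeneFamily
from wgdkit.placement import (
    Placement,
    _aa_matrix,
    bootstrap_support,
    nj_tree,
    poisson_distance_matrix,
)
from wgdkit.tree import GeneTreeNode


def _gene_tree(newick_like):
    """Tiny helper: build a rooted GeneTreeNode from nested tuples
    ((name, species, length) | subtree, ...)."""

    def build(spec):
        if isinstance(spec, tuple) and len(spec) == 3 and isinstance(spec[0], str):
            name, species, length = spec
            return GeneTreeNode(name=name, species=species, length=length)
        node = GeneTreeNode(length=spec[-1] if isinstance(spec[-1], float) else 1.0)
        for child in spec[0]:
            node.add(build(child))
        return node

    return build(newick_like)


def _clade(*children, length=1.0, support=None):
    node = GeneTreeNode(length=length, support=support)
    for c in children:
        node.add(c)
    return node


def _tip(name, species=None, length=1.0):
    return GeneTreeNode(name=name, species=species or name[0].upper(), length=length)


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self):
        # ((a,b),(c,d)) with internal branch 3
        labels = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0, 2, 7, 7],
                [2, 0, 7, 7],
                [7, 7, 0, 2],
                [7, 7, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, labels)
        clades = {
            frozenset(n.tip_names()) for n in tree.postorder() if not n.is_tip
        }
        assert frozenset({"a", "b"}) in clades or frozenset({"c", "d"}) in clades

    def test_matches_dendropy_on_random_additive_matrices(self):
        """Cross-check the numpy NJ against dendropy's implementation."""
        import dendropy

        rnd = random.Random(6)
        for _ in range(10):
            n = rnd.randint(4, 8)
            labels = [f"t{i}" for i in range(n)]
            # random additive matrix from a random tree: use random splits
            base = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
                rng=random.Random(rnd.randint(0, 10**6)),
            )
            for edge in base.preorder_edge_iter():
                edge.length = rnd.uniform(0.5, 3.0)
            pdm = base.phylogenetic_distance_matrix()
            taxa = list(base.taxon_namespace)
            D = np.array(
                [[pdm.distance(a, b) for b in taxa] for a in taxa]
            )
            mine = nj_tree(D, [t.label for t in taxa])
            ref = pdm.nj_tree()
            ref_bips = {
                frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                for e in ref.preorder_edge_iter()
                if e.head_node.parent_node is not None
            }
            all_tips = frozenset(t.label for t in taxa)
            mine_bips = set()
            for node in mine.postorder():
                if node is mine or node.is_tip:
                    continue
                mine_bips.add(frozenset(node.tip_names()))
            for bip in mine_bips:
                assert bip in ref_bips or (all_tips - bip) in ref_bips

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((1, 1)), ["a"])


class TestBootstrap:
    def test_constant_alignment_gives_full_support(self):
        cds = w.CodingSequenceSet(
            {t: "ATGAAATTTGGG" * 10 for t in ("a", "b", "c", "d")}, validate=False
        )
        fam = GeneFamily("f", ["a", "b", "c", "d"], {t: t.upper() for t in "abcd"})
        X = _aa_matrix(["a", "b", "c", "d"], cds)
        tree = nj_tree(poisson_distance_matrix(X), ["a", "b", "c", "d"])
        tree = bootstrap_support(tree, X, ["a", "b", "c", "d"], B=50, seed=0)
        for node in tree.postorder():
            if node is tree or node.is_tip:
                continue
            assert node.support == 100.0

    def test_long_internal_branch_has_high_support(self, rng):
        """((a,b),(c,d)) truth with a long internal branch: the central
        bipartition is recovered in nearly every replicate."""
        from wgdkit.simulate import evolve_sequence
        from wgdkit.ks import SENSE_CODONS

        root = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 200))
        left = evolve_sequence(root, 0.4, 0.5, rng)
        right = evolve_sequence(root, 0.4, 0.5, rng)
        seqs = {
            "a": evolve_sequence(left, 0.05, 0.5, rng),
            "b": evolve_sequence(left, 0.05, 0.5, rng),
            "c": evolve_sequence(right, 0.05, 0.5, rng),
            "d": evolve_sequence(right, 0.05, 0.5, rng),
        }
        cds = w.CodingSequenceSet(seqs, validate=False)
        labels = ["a", "b", "c", "d"]
        X = _aa_matrix(labels, cds)
        tree = nj_tree(poisson_distance_matrix(X), labels)
        tree = bootstrap_support(tree, X, labels, B=100, seed=3)
        central = [
            n
            for n in tree.postorder()
            if not n.is_tip and n is not tree and len(n.tip_names()) == 2
        ]
        assert central and all(n.support >= 95 for n in central)


class TestRooting:
    def test_single_outgroup_tip_roots_on_its_edge(self):
        tree = _clade(
            _tip("a1", "A"), _clade(_tip("b1", "B"), _tip("o1", "O")), _tip("a2", "A")
        )
        rooted = w.root_gene_tree(tree, "O")
        sides = [frozenset(c.tip_names()) for c in rooted.children]
        assert frozenset({"o1"}) in sides

    def test_non_monophyletic_outgroup_falls_back_to_midpoint(self):
        # two outgroup tips that cannot form a clade on any rooting
        tree = _clade(
            _clade(_tip("o1", "O", 1.0), _tip("a1", "A", 1.0)),
            _clade(_tip("o2", "O", 1.0), _tip("a2", "A", 5.0)),
        )
        rooted = w.root_gene_tree(tree, "O")
        # midpoint of the longest path (o1/a1 .. a2, length 8) splits a2's
        # pendant edge: one side holds a2 alone
        sides = [frozenset(c.tip_names()) for c in rooted.children]
        assert frozenset({"a2"}) in sides

    def test_symmetric_tree_midpoint_is_deterministic(self):
        t = _clade(
            _clade(_tip("a1", "A", 1.0), _tip("b1", "B", 1.0), length=1.0),
            _clade(_tip("c1", "C", 1.0), _tip("d1", "D", 1.0), length=1.0),
        )
        r1 = w.root_gene_tree(t, "Z")  # no outgroup genes -> midpoint
        t2 = _clade(
            _clade(_tip("a1", "A", 1.0), _tip("b1", "B", 1.0), length=1.0),
            _clade(_tip("c1", "C", 1.0), _tip("d1", "D", 1.0), length=1.0),
        )
        r2 = w.root_gene_tree(t2, "Z")
        assert [sorted(c.tip_names()) for c in r1.children] == [
            sorted(c.tip_names()) for c in r2.children
        ]


class TestClassification:
    def _species_tree(self, nwk="((A,B),C);"):
        return w.SpeciesTree.from_newick(nwk)

    def test_root_duplication_children_speciation(self):
        st = self._species_tree("(A,B);")
        gt = _clade(
            _clade(_tip("a1", "A"), _tip("b1", "B")),
            _clade(_tip("a2", "A"), _tip("b2", "B")),
        )
        w.classify_nodes(gt, st)
        assert gt.label == "duplication"
        assert [c.label for c in gt.children] == ["speciation", "speciation"]

    def test_within_species_duplication(self):
        st = self._species_tree("(A,B);")
        gt = _clade(_clade(_tip("a1", "A"), _tip("a2", "A")), _tip("b1", "B"))
        w.classify_nodes(gt, st)
        assert gt.children[0].label == "duplication"
        assert gt.label == "speciation"

    def test_incongruent_node_is_dubious(self):
        st = self._species_tree("((A,B),C);")
        gt = _clade(_clade(_tip("a1", "A"), _tip("c1", "C")), _tip("b1", "B"))
        w.classify_nodes(gt, st)
        assert gt.children[0].label == "speciation"  # maps to root, strict anc of A and C
        assert gt.label == "dubious"

    def test_congruent_single_copy_tree_is_all_speciation(self):
        st = self._species_tree("((A,B),C);")
        gt = _clade(_clade(_tip("a1", "A"), _tip("b1", "B")), _tip("c1", "C"))
        w.classify_nodes(gt, st)
        for node in gt.postorder():
            if not node.is_tip:
                assert node.label == "speciation"

    def test_missing_species_is_an_error(self):
        st = self._species_tree("(A,B);")
        gt = _clade(_tip("a1", "A"), _tip("x1", "X"))
        with pytest.raises(KeyError, match="X"):
            w.classify_nodes(gt, st)

    def test_duplication_label_matches_brute_force_species_intersection(
        self, stem_wgd_result
    ):
        res = stem_wgd_result
        fams = w.build_families(
            res.homology, evalue_cutoff=1e-5, species_of=lambda g: g.split("_")[0]
        )
        fam = next(f for f in fams if len(f) >= 6)
        tree = w.build_gene_tree(fam, res.cds, "O", B=10, seed=1)
        w.classify_nodes(tree, res.species_tree)
        for node in tree.postorder():
            if node.is_tip:
                continue
            sets = [
                {t.species for t in c.tips()} for c in node.children
            ]
            expected_dup = bool(sets[0] & sets[1])
            assert (node.label == "duplication") == expected_dup


class TestPlacement:
    def test_stem_placement(self):
        st = w.SpeciesTree.from_newick("((A,D),O);")
        gt = _clade(
            _clade(
                _clade(_tip("a1", "A"), _tip("d1", "D")),
                _clade(_tip("a2", "A"), _tip("d2", "D")),
                support=92.0,
            ),
            _tip("o1", "O"),
        )
        w.classify_nodes(gt, st)
        p = w.place_anchor(("a1", "a2"), gt, st)
        assert p.placed
        ad = st.mrca(["A", "D"])
        assert p.lower_node == ad and p.upper_node == st.root_id
        assert p.assigned_branch == (st.root_id, ad)
        assert p.support == 92.0

    def test_anchor_at_speciation_node_is_unplaced(self):
        st = w.SpeciesTree.from_newick("(A,B);")
        gt = _clade(_tip("a1", "A"), _tip("b1", "B"))
        w.classify_nodes(gt, st)
        p = w.place_anchor(("a1", "b1"), gt, st)
        assert not p.placed and "speciation" in p.reason

    def test_no_speciation_ancestor_gives_open_interval(self):
        st = w.SpeciesTree.from_newick("(A,B);")
        gt = _clade(_clade(_tip("a1", "A"), _tip("a2", "A")), _tip("a3", "A"))
        w.classify_nodes(gt, st)
        p = w.place_anchor(("a1", "a2"), gt, st)
        assert p.placed and p.unbounded and p.assigned_branch is None

    def test_missing_gene_reported(self):
        st = w.SpeciesTree.from_newick("(A,B);")
        gt = _clade(_tip("a1", "A"), _tip("b1", "B"))
        w.classify_nodes(gt, st)
        p = w.place_anchor(("a1", "zz"), gt, st)
        assert not p.placed and "missing" in p.reason


class TestFamilyFilter:
    def _families(self):
        return [
            GeneFamily("f0", ["a1", "a2", "o1"], {"a1": "A", "a2": "A", "o1": "O"}),
            GeneFamily("f1", ["a3", "a4"], {"a3": "A", "a4": "A"}),
            GeneFamily("f2", ["a5", "o2"], {"a5": "A", "o2": "O"}),
        ]

    def test_high_ks_anchor_dropped(self):
        fams, anchors = w.filter_families_for_placement(
            self._families(),
            [("a1", "a2")],
            {("a1", "a2"): 5.2},
            "O",
            {"a1": "A", "a2": "A", "o1": "O", "a3": "A", "a4": "A", "a5": "A", "o2": "O"},
        )
        assert fams == []

    def test_anchor_spanning_families_merges_them(self):
        species_of = {
            "a1": "A", "a2": "A", "o1": "O", "a3": "A", "a4": "A", "a5": "A", "o2": "O"
        }
        fams, anchors = w.filter_families_for_placement(
            self._families(),
            [("a3", "a5")],  # spans f1 and f2
            {("a3", "a5"): 1.0},
            "O",
            species_of,
        )
        assert len(fams) == 1
        assert fams[0].members == ["a3", "a4", "a5", "o2"]

    def test_oversized_family_excluded(self):
        members = [f"a{i}" for i in range(301)] + ["o1"]
        species_of = {m: "A" for m in members}
        species_of["o1"] = "O"
        fams = [GeneFamily("big", members, species_of)]
        out, _ = w.filter_families_for_placement(
            fams, [("a0", "a1")], {("a0", "a1"): 1.0}, "O", species_of
        )
        assert out == []

    def test_family_without_outgroup_excluded(self):
        out, _ = w.filter_families_for_placement(
            self._families(),
            [("a3", "a4")],
            {("a3", "a4"): 1.0},
            "O",
            {"a3": "A", "a4": "A"},
        )
        assert out == []


class TestCounts:
    def _placements(self):
        br = (9, 5)
        mk = lambda a, b, fam, sup: Placement(
            a, b, fam, placed=True, lower_node=5, upper_node=9,
            branch_path=[br], assigned_branch=br, support=sup,
        )
        return [
            mk("A_g1", "A_g2", "f1", 90.0),
            mk("A_g3", "A_g4", "f1", 85.0),
            mk("A_g5", "A_g6", "f2", 40.0),
        ]

    def test_threshold_counting(self):
        counts = w.count_events_per_branch(self._placements(), (50, 80))
        br = (9, 5)
        assert counts[80][br]["anchor_pairs"] == 2
        assert counts[80][br]["families"] == 1
        assert counts[50][br]["anchor_pairs"] == 2
        assert counts[50][br]["by_species"] == {"A": 2}

    def test_no_single_branch_placements(self):
        p = Placement("a", "b", "f", placed=True, lower_node=1, upper_node=None)
        assert w.count_events_per_branch([p], (50, 80)) == {50: {}, 80: {}}

    def test_counts_monotone_in_threshold(self):
        counts = w.count_events_per_branch(self._placements(), (50, 80))
        for br, rec in counts[80].items():
            assert rec["anchor_pairs"] <= counts[50][br]["anchor_pairs"]
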
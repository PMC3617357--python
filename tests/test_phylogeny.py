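import numpy as np
import pytest

import dendropy

from endoclone import LineageTree, child_code
from endoclone.config import make_fixture


def random_tree(rng, n_leaves, alive_fraction=1.0):
    """Grow a random bifurcating tree by splitting random leaves, then mark
    a random subset of leaves alive."""
    codes = ["1"]
    leaves = ["1"]
    while len(leaves) < n_leaves:
        i = rng.integers(len(leaves))
        parent = leaves.pop(i)
        for which in (1, 2):
            c = child_code(parent, which)
            codes.append(c)
            leaves.append(c)
    n_alive = max(1, int(round(alive_fraction * len(leaves))))
    alive = list(rng.choice(leaves, size=n_alive, replace=False))
    return LineageTree.from_codes(codes, alive), codes, alive


def brute_force_counts(tree):
    codes = [tree.code(i) for i in range(len(tree))]
    alive_codes = [c for c, a in zip(codes, tree.alive) if a]
    return np.array([sum(1 for a in alive_codes if a.startswith(c)) for c in codes])


def brute_force_mrca(tree, x):
    counts = brute_force_counts(tree)
    need = int(np.ceil(x * tree.n_final))
    best = None
    for i in range(len(tree)):
        if counts[i] < need:
            continue
        key = (-tree.d[i], -counts[i], tree.code(i))
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


class TestChildCode:
    def test_digit_append(self):
        assert child_code("1", 2) == "12"   # the integer scheme's 10*1 + 2
        assert child_code("12", 1) == "121"

    def test_root_depth_is_one(self):
        t = LineageTree.from_codes(["1"], alive=["1"])
        assert t.d[0] == 1

    def test_deep_codes_representable(self):
        # tumor lineages reach ~47 divisions; the digit-sequence encoding
        # has no overflow (the literal integer would exceed 64 bits)
        code = "1"
        for _ in range(46):
            code = child_code(code, 2)
        assert len(code) == 47
        t = LineageTree.from_codes(
            ["1" + "2" * i for i in range(47)], alive=[code])
        assert t.d[-1] == 47

    @pytest.mark.parametrize("bad", [0, 3, -1])
    def test_invalid_digit(self, bad):
        with pytest.raises(ValueError):
            child_code("1", bad)

    def test_orphan_rejected(self):
        with pytest.raises(ValueError, match="orphan"):
            LineageTree.from_codes(["1", "121"], alive=["121"])


class TestDescendantCounts:
    def test_three_node_tree(self):
        t = LineageTree.from_codes(["1", "11", "12"], alive=["11", "12"])
        counts = {t.code(i): c for i, c in enumerate(t.descendant_counts())}
        assert counts == {"1": 2, "11": 1, "12": 1}

    def test_depth_two_full_binary(self):
        codes = ["1", "11", "12", "111", "112", "121", "122"]
        t = LineageTree.from_codes(codes, alive=codes[3:])
        counts = {t.code(i): c for i, c in enumerate(t.descendant_counts())}
        assert counts == {"1": 4, "11": 2, "12": 2,
                          "111": 1, "112": 1, "121": 1, "122": 1}

    def test_additivity_on_random_trees(self, rng):
        for frac in (1.0, 0.6):
            t, _, _ = random_tree(rng, 200, alive_fraction=frac)
            counts = t.descendant_counts()
            assert np.array_equal(counts, brute_force_counts(t))
            kids = t.children()
            for i in range(len(t)):
                assert counts[i] == t.alive[i] + sum(counts[j] for j in kids[i])
            assert counts[0] == t.n_final


class TestMrca:
    def test_full_mass_is_root(self, rng):
        t, _, _ = random_tree(rng, 50)
        res = t.mrca(1.0)
        assert res.index == 0 and res.d == 1

    def test_symmetric_tie_breaks_to_first_daughter(self):
        codes = ["1", "11", "12", "111", "112", "121", "122"]
        t = LineageTree.from_codes(codes, alive=codes[3:])
        assert t.mrca(0.5).code == "11"

    def test_matches_brute_force_on_skewed_trees(self, rng):
        t, _, _ = random_tree(rng, 1000, alive_fraction=0.7)
        for x in (0.999, 0.9, 0.5, 0.2):
            res = t.mrca(x)
            assert res.index == brute_force_mrca(t, x)

    def test_depth_monotone_in_fraction(self, rng):
        for _ in range(3):
            t, _, _ = random_tree(rng, 300, alive_fraction=0.8)
            depths = [t.mrca(x).d for x in (1.0, 0.99, 0.9, 0.7, 0.5, 0.3)]
            assert all(d2 >= d1 for d1, d2 in zip(depths, depths[1:]))

    def test_invalid_fraction_and_empty_mass(self, rng):
        t, _, _ = random_tree(rng, 10)
        for x in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                t.mrca(x)
        dead = LineageTree.from_codes(["1"], alive=[])
        with pytest.raises(ValueError, match="empty"):
            dead.mrca(0.5)


class TestNewick:
    def test_single_root(self):
        t = LineageTree.from_codes(["1"], alive=["1"],
                                   t_event={"1": 2.0})
        assert t.to_newick() == "1:60;"

    def test_three_node_shape(self):
        t = LineageTree.from_codes(["1", "11", "12"], alive=["11", "12"])
        nwk = t.to_newick()
        assert nwk.startswith("(") and nwk.endswith("1:0;")
        assert "11:" in nwk and "12:" in nwk

    def test_round_trip_topology_and_labels(self, rng):
        t, codes, alive = random_tree(rng, 60)
        nwk = t.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick",
                                   suppress_internal_node_taxa=False)
        leaf_labels = {lf.taxon.label for lf in parsed.leaf_node_iter()}
        kids = t.children()
        expected_leaves = {t.code(i) for i in range(len(t)) if not kids[i]}
        assert leaf_labels == expected_leaves
        # depth is recoverable from the label path
        for node in parsed.preorder_node_iter():
            label = node.taxon.label
            assert len(label) == len(list(node.ancestor_iter())) + 1

    def test_annotated_fixture_deterministic(self):
        a = make_fixture("toy-tree", seed=4).to_newick(annotate=True)
        b = make_fixture("toy-tree", seed=4).to_newick(annotate=True)
        assert a == b and "[&d=" in a
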
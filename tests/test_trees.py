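import math

import numpy as np
import pytest

from planctotaxa import synthetic_data as sim
from planctotaxa import trees as tr

from helpers import tip_depths


class TestNewickIO:
    def test_parse_simple(self):
        t = tr.parse_newick("(A:1,B:2);")
        assert t.tip_labels() == ["A", "B"]
        assert tip_depths(t) == {"A": 1.0, "B": 2.0}

    def test_parse_nested(self, quartet_tree):
        assert quartet_tree.tip_labels() == ["A", "B", "C", "D"]
        internals = [n for n in quartet_tree.postorder() if not n.is_tip]
        assert len(internals) == 3  # two cherries + root

    @pytest.mark.parametrize("bad", ["(A:1,B:2", "", "((A,B);", "A:1)('"])
    def test_malformed_raises(self, bad):
        with pytest.raises(tr.NewickParseError):
            tr.parse_newick(bad)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(tr.TreeError, match="duplicate"):
            tr.parse_newick("(A:1,A:2);")

    def test_roundtrip_preserves_everything(self, rng):
        for seed in range(5):
            t = sim.simulate_tree(12, seed=seed, rate_sigma=0.4)
            text = tr.write_newick(t)
            back = tr.parse_newick(text)
            assert tr.write_newick(back) == text
            assert tip_depths(back) == tip_depths(t)

    def test_internal_labels_survive(self):
        text = "((A:1.0,B:1.0)support99:1.0,C:2.0);"
        t = tr.parse_newick(text)
        assert "support99" in tr.write_newick(t)

    def test_unrooted_trifurcation_retained(self):
        t = tr.parse_newick("(A:1,B:1,C:1);")
        assert not t.rooted
        assert len(tr.parse_newick(tr.write_newick(t)).root.children) == 3


class TestPatristic:
    def test_worked_example(self, quartet_tree):
        assert tr.patristic_distance(quartet_tree, "A", "B") == 2.0
        assert tr.patristic_distance(quartet_tree, "A", "C") == 4.5
        assert tr.patristic_distance(quartet_tree, "A", "A") == 0.0

    def test_symmetry(self, quartet_tree):
        for a in "ABCD":
            for b in "ABCD":
                assert tr.patristic_distance(quartet_tree, a, b) == \
                    tr.patristic_distance(quartet_tree, b, a)

    def test_unknown_tip(self, quartet_tree):
        with pytest.raises(tr.TreeError, match="unknown tip"):
            tr.patristic_distance(quartet_tree, "A", "Z")

    def test_missing_branch_length_rejected(self):
        t = tr.parse_newick("((A:1,B),C:1);")
        with pytest.raises(tr.TreeError, match="missing"):
            tr.patristic_distance(t, "A", "C")


class TestMonophyly:
    def test_cherry_is_monophyletic(self, quartet_tree):
        flag, _ = tr.is_monophyletic(quartet_tree, tr.CladeSpec("x", {"A", "B"}))
        assert flag

    def test_split_pair_is_not(self, quartet_tree):
        flag, _ = tr.is_monophyletic(quartet_tree, tr.CladeSpec("x", {"A", "C"}))
        assert not flag

    def test_whole_tree_is_monophyletic(self, quartet_tree):
        flag, anc = tr.is_monophyletic(
            quartet_tree, tr.CladeSpec("all", {"A", "B", "C", "D"}))
        assert flag and anc is quartet_tree.root

    def test_unrooted_tree_rejected(self):
        t = tr.parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(tr.TreeError, match="root"):
            tr.is_monophyletic(t, tr.CladeSpec("x", {"A", "B"}))


class TestMidpointRoot:
    def test_two_tips(self):
        m = tr.midpoint_root(tr.parse_newick("(A:1,B:3);"))
        assert tip_depths(m) == {"A": 2.0, "B": 2.0}

    def test_idempotent(self):
        t = tr.midpoint_root(tr.parse_newick("((A:1,B:2):0.5,(C:1,D:4):0.5);"))
        again = tr.midpoint_root(t)
        d1, d2 = tip_depths(t), tip_depths(again)
        assert d1.keys() == d2.keys()
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_max_depth_is_half_diameter(self, seed):
        t = sim.simulate_tree(10, seed=seed, rate_sigma=0.5)
        rooted = tr.midpoint_root(t)
        depths = tip_depths(rooted)
        labels = t.tip_labels()
        diameter = max(
            tr.patristic_distance(t, a, b)
            for i, a in enumerate(labels) for b in labels[i + 1:]
        )
        two_deepest = sorted(depths.values())[-2:]
        assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-10)
        assert two_deepest[0] == pytest.approx(two_deepest[1], abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_patristic_distances_unchanged(self, seed):
        t = sim.simulate_tree(8, seed=seed, rate_sigma=0.3)
        rooted = tr.midpoint_root(t)
        labels = t.tip_labels()
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert tr.patristic_distance(rooted, a, b) == pytest.approx(
                    tr.patristic_distance(t, a, b), abs=1e-10)

    def test_zero_length_tree_warns(self):
        t = tr.parse_newick("((A:0,B:0):0,C:0);")
        with pytest.warns(UserWarning, match="zero"):
            tr.midpoint_root(t)


class TestMash:
    def test_worked_examples(self, quartet_tree):
        assert tr.mash(quartet_tree, tr.CladeSpec("ab", {"A", "B"})).value == 1.0
        assert tr.mash(
            quartet_tree, tr.CladeSpec("all", {"A", "B", "C", "D"})).value == 2.5

    def test_stem_branch_excluded_nonultrametric(self):
        # MaSH of {A,B} is 3.0 while half the max patristic distance is 2.0:
        # on non-ultrametric trees the two quantities differ
        t = tr.parse_newick("((A:1,B:3):1,C:1);")
        clade = tr.CladeSpec("ab", {"A", "B"})
        assert tr.mash(t, clade).value == 3.0
        assert tr.patristic_distance(t, "A", "B") / 2 == 2.0

    def test_non_monophyletic_clade_names_intruders(self, quartet_tree):
        with pytest.raises(tr.TreeError, match=r"\['B'\]|B"):
            tr.mash(quartet_tree, tr.CladeSpec("x", {"A", "C", "D"}))

    def test_singleton_clade_is_zero(self, quartet_tree):
        assert tr.mash(quartet_tree, tr.CladeSpec("a", {"A"})).value == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_half_max_patristic_on_ultrametric(self, seed):
        tree = sim.simulate_tree(12, seed=seed)  # rate_sigma=0: clock-like
        for node in tree.postorder():
            if node.is_tip or node is tree.root:
                continue
            tips = sorted(
                n.label for n in tree.postorder()
                if n.is_tip and _is_descendant(n, node))
            value = tr.mash(tree, tr.CladeSpec("c", tips)).value
            half_max = max(
                tr.patristic_distance(tree, a, b)
                for i, a in enumerate(tips) for b in tips[i + 1:]
            ) / 2
            assert value == pytest.approx(half_max, abs=1e-10)

    def test_monotone_under_nesting(self):
        t = tr.parse_newick("(((A:1,B:2):1,C:4):1,(D:1,E:1):3);")
        inner = tr.mash(t, tr.CladeSpec("ab", {"A", "B"})).value
        outer = tr.mash(t, tr.CladeSpec("abc", {"A", "B", "C"})).value
        whole = tr.mash(t, tr.CladeSpec("all", set("ABCDE"))).value
        assert inner <= outer <= whole


def _is_descendant(node, ancestor):
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


class TestMashTable:
    def test_matches_single_calls_and_sorts(self, quartet_tree):
        other = tr.parse_newick("((A:2,B:2):1,(C:1,D:1):1);")
        clades = [tr.CladeSpec("all", set("ABCD")), tr.CladeSpec("ab", {"A", "B"})]
        table = tr.mash_table({"t16S": quartet_tree, "tGenome": other}, clades)
        assert list(table.index) == ["ab", "all"]  # ascending by first column
        assert table.loc["ab", "t16S"] == 1.0
        assert table.loc["all", "tGenome"] == tr.mash(
            other, clades[0]).value

    def test_missing_tips_marked_unavailable(self, quartet_tree):
        small = tr.parse_newick("(A:1,B:1);")
        table = tr.mash_table(
            {"big": quartet_tree, "small": small},
            [tr.CladeSpec("ab", {"A", "B"}), tr.CladeSpec("cd", {"C", "D"})])
        assert math.isnan(table.loc["cd", "small"])
        assert table.loc["cd", "big"] == 2.0

    def test_empty_clades_rejected(self, quartet_tree):
        with pytest.raises(tr.TreeError):
            tr.mash_table({"t": quartet_tree}, [])

    def test_tsv_uses_tilde_for_unavailable(self, quartet_tree, tmp_path):
        small = tr.parse_newick("(A:1,B:1);")
        table = tr.mash_table(
            {"big": quartet_tree, "small": small},
            [tr.CladeSpec("cd", {"C", "D"})])
        out = tmp_path / "mash.tsv"
        tr.write_mash_table(table, out)
        assert "~" in out.read_text()
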
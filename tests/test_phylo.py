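"""Gene-tree operations: parsing, rooting, collapsing, donor detection."""

import itertools
import random

import pytest

from alienscreen.errors import ConstraintError, InputError, RootingError, TreeError
from alienscreen.phylo import (
    ConfirmStatus,
    collapse_low_support,
    detect_donor_clade,
    make_constraint_tree,
    midpoint_root,
    parse_tree,
)
from alienscreen.taxonomy import LineageLabel

from conftest import random_tree

# sequence-id → taxid map for the small fixture taxonomy in conftest
TMAP = {
    "r1": 1003835, "r2": 1061180, "r3": 1003835,
    "b1": 4371, "b2": 4371, "b3": 436,
    "f1": 162425, "f2": 162425,
}


def leaf_distances(tree):
    """Path lengths between all leaf pairs, measured through the root."""
    def depths(node, acc, out):
        if node.is_leaf:
            out[node.label] = (acc, node)
        for c in node.children:
            depths(c, acc + c.length, out)

    out = {}
    depths(tree.root, 0.0, out)

    def dist(a, b):
        na, nb = out[a][1], out[b][1]
        anc_a = {}
        d, n = 0.0, na
        while n is not None:
            anc_a[id(n)] = d
            d += n.length or 0.0
            n = n.parent
        d, n = 0.0, nb
        while id(n) not in anc_a:
            d += n.length or 0.0
            n = n.parent
        return d + anc_a[id(n)]

    labels = sorted(out)
    return {(a, b): dist(a, b) for a, b in itertools.combinations(labels, 2)}


class TestParse:
    def test_supports_read_from_internal_labels(self):
        t = parse_tree("((A:1,B:1)95:1,C:2);")
        assert sorted(t.leaf_labels()) == ["A", "B", "C"]
        internal = [n for n in t.preorder() if not n.is_leaf and n.parent is not None]
        assert [n.support for n in internal] == [95.0]

    def test_fractional_supports_rescaled(self):
        t = parse_tree("((A:1,B:1)0.95:1,(C:1,D:1)0.5:1);")
        sups = sorted(n.support for n in t.preorder() if n.support is not None)
        assert sups == [50.0, 95.0]

    def test_support_comment_dialect(self):
        t = parse_tree("((A:1,B:1)[&support=87]:1,C:2);")
        sups = [n.support for n in t.preorder() if n.support is not None]
        assert sups == [87.0]

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            parse_tree("((A,B,(A,C));")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_tree("((A:1,B:1):1,(A:1,C:1):1);")

    def test_roundtrip_serialization(self):
        t = parse_tree("((A:1,B:1)95:1,C:2);")
        assert parse_tree(t.as_newick()).as_newick() == t.as_newick()


class TestMidpointRoot:
    def test_caterpillar_diameter_split_evenly(self):
        t = midpoint_root(parse_tree("((((A:4,X:0.5):1,Y:0.5):1,Z:0.5):3,B:1);"))
        d = leaf_distances(t)
        # diameter endpoints A,B at distance 10 → root equidistant at 5
        depth = {}
        def walk(n, acc):
            if n.is_leaf:
                depth[n.label] = acc
            for c in n.children:
                walk(c, acc + c.length)
        walk(t.root, 0.0)
        assert depth["A"] == pytest.approx(5.0)
        assert depth["B"] == pytest.approx(5.0)

    def test_two_leaf_tree(self):
        t = midpoint_root(parse_tree("(A:3,B:1);"))
        d = leaf_distances(t)
        assert d[("A", "B")] == pytest.approx(4.0)
        assert [c.length for c in t.root.children] == pytest.approx([2.0, 2.0])

    def test_missing_branch_lengths_raise(self):
        with pytest.raises(RootingError):
            midpoint_root(parse_tree("((A,B),C);"))

    def test_random_trees_match_bruteforce_midpoint(self):
        """Root eccentricity equals half the brute-force diameter and all
        pairwise leaf distances are preserved."""
        rng = random.Random(2024)
        for _ in range(40):
            t = random_tree(rng, rng.randint(3, 18))
            before = leaf_distances(t)
            rooted = midpoint_root(t)
            after = leaf_distances(rooted)
            for pair, dval in before.items():
                assert after[pair] == pytest.approx(dval, abs=1e-9)
            diameter = max(before.values())
            depth = {}
            def walk(n, acc):
                if n.is_leaf:
                    depth[n.label] = acc
                for c in n.children:
                    walk(c, acc + c.length)
            walk(rooted.root, 0.0)
            assert max(depth.values()) == pytest.approx(diameter / 2, abs=1e-9)

    def test_input_tree_untouched(self):
        t = parse_tree("((A:1,B:5)90:1,C:2);")
        before = t.as_newick()
        midpoint_root(t)
        assert t.as_newick() == before

    def test_support_stays_with_its_bipartition(self):
        # the 77-supported edge separates {A,B} from {C,D} before and after
        t = midpoint_root(parse_tree("((A:1,B:1)77:6,(C:1,D:1)88:1);"))
        for n in t.preorder():
            if n.support == 77.0 or n.support == 88.0:
                side = frozenset(l.label for l in n.leaves())
                assert side in (frozenset("AB"), frozenset("CD"))


class TestCollapse:
    def test_boundary_is_strict(self):
        """Support 94 collapses; exactly 95 is retained."""
        t94 = collapse_low_support(parse_tree("((A:1,B:1)94:1,C:2);"))
        assert len(t94.root.children) == 3  # polytomy
        t95 = collapse_low_support(parse_tree("((A:1,B:1)95:1,C:2);"))
        assert len(t95.root.children) == 2

    def test_all_high_support_unchanged(self):
        nwk = "((A:1,B:1)100:1,(C:1,D:1)100:1);"
        assert collapse_low_support(parse_tree(nwk)).as_newick() == nwk

    def test_absent_support_retained(self):
        t = collapse_low_support(parse_tree("((A:1,B:1):1,C:2);"))
        assert len(t.root.children) == 2

    def test_leafset_preserved_node_count_shrinks_idempotent(self):
        rng = random.Random(99)
        for _ in range(30):
            t = random_tree(rng, rng.randint(3, 15))
            c = collapse_low_support(t)
            assert sorted(c.leaf_labels()) == sorted(t.leaf_labels())
            assert c.n_nodes() <= t.n_nodes()
            assert collapse_low_support(c).as_newick() == c.as_newick()

    def test_root_to_leaf_distances_preserved(self):
        t = parse_tree("(((A:1,B:1)40:2,C:1)60:3,D:1);")
        c = collapse_low_support(t)
        depth = {}
        def walk(n, acc):
            if n.is_leaf:
                depth[n.label] = acc
            for ch in n.children:
                walk(ch, acc + ch.length)
        walk(c.root, 0.0)
        assert depth == {"A": 6.0, "B": 6.0, "C": 4.0, "D": 1.0}


NESTED = "(((r1:0.1,r2:0.1)97:0.2,(b1:0.1,b2:0.1)96:0.2){sup}:1.0,(f1:0.3,f2:0.3)99:1.0);"


class TestDetectDonorClade:
    def detect(self, nwk, db, lin, recipients=("r1", "r2"), threshold=90.0):
        return detect_donor_clade(parse_tree(nwk), set(recipients), db, lin, TMAP,
                                  support_threshold=threshold)

    def test_confirmed_with_donor_lineage(self, db, lin):
        r = self.detect(NESTED.format(sup=98), db, lin)
        assert r.status is ConfirmStatus.CONFIRMED
        assert r.clade_support == 98.0
        assert r.donor_taxid == 4371
        assert r.donor_name == "Acetobacter-like sp."
        assert r.n_bacterial_leaves_in_clade == 2

    def test_mixed_donor_families_take_lca(self, db, lin):
        nwk = "(((r1:0.1,r2:0.1)97:0.2,(b1:0.1,b3:0.1)96:0.2)98:1.0,(f1:0.3,f2:0.3)99:1.0);"
        r = self.detect(nwk, db, lin)
        assert r.status is ConfirmStatus.CONFIRMED
        assert r.donor_taxid == 2  # LCA of the two bacterial families

    def test_low_support(self, db, lin):
        r = self.detect(NESTED.format(sup=85), db, lin)
        assert r.status is ConfirmStatus.LOW_SUPPORT
        assert r.clade_support == 85.0

    def test_threshold_is_strict(self, db, lin):
        assert self.detect(NESTED.format(sup=90), db, lin).status is ConfirmStatus.LOW_SUPPORT
        assert self.detect(NESTED.format(sup=91), db, lin).status is ConfirmStatus.CONFIRMED

    def test_non_bacterial_sister(self, db, lin):
        nwk = "(((r1:0.1,r2:0.1)97:0.2,(f1:0.1,f2:0.1)96:0.2)98:1.0,(b1:0.3,b2:0.3)99:1.0);"
        assert self.detect(nwk, db, lin).status is ConfirmStatus.NON_BACTERIAL

    def test_scattered_recipients(self, db, lin):
        nwk = "((r1:0.1,f1:0.1)97:0.2,(r2:0.1,(b1:0.1,b2:0.1)96:0.1)98:0.2);"
        assert self.detect(nwk, db, lin).status is ConfirmStatus.SCATTERED

    def test_recipients_interleaved_with_bacteria_only(self, db, lin):
        nwk = "(((r1:0.1,b1:0.1)97:0.2,(r2:0.1,b2:0.1)96:0.2)98:1.0,(f1:0.3,f2:0.3)99:1.0);"
        r = self.detect(nwk, db, lin)
        assert r.status is ConfirmStatus.CONFIRMED

    def test_input_errors(self, db, lin):
        with pytest.raises(InputError):
            self.detect(NESTED.format(sup=98), db, lin, recipients=())
        with pytest.raises(InputError):
            self.detect(NESTED.format(sup=98), db, lin, recipients=("r1", "zzz"))

    def test_invariant_under_leaf_order_and_reserialization(self, db, lin):
        a = NESTED.format(sup=98)
        b = "((f2:0.3,f1:0.3)99:1.0,((b2:0.1,b1:0.1)96:0.2,(r2:0.1,r1:0.1)97:0.2)98:1.0);"
        ra = self.detect(a, db, lin)
        rb = self.detect(b, db, lin)
        rc = self.detect(parse_tree(a).as_newick(), db, lin)
        assert ra == rb == rc

    def test_matches_bruteforce_clade_enumeration(self, db, lin):
        """The walk from the recipient MRCA finds the minimal clade that any
        exhaustive scan over all clades would select."""
        rng = random.Random(5)
        labels = list(TMAP)
        for _ in range(60):
            t = random_tree(rng, rng.randint(4, len(labels)))
            relabel = dict(zip(sorted(t.leaf_labels()), rng.sample(labels, len(t.leaves()))))
            for leaf in t.leaves():
                leaf.label = relabel[leaf.label]
            recips = {l for l in t.leaf_labels() if l.startswith("r")}
            others = set(t.leaf_labels()) - recips
            if not recips or not others:
                continue
            got = detect_donor_clade(t, recips, db, lin, TMAP)
            # oracle: minimal clade containing all recipients and ≥1 other leaf
            best = None
            for node in t.preorder():
                ls = {l.label for l in node.leaves()}
                if recips <= ls and ls - recips:
                    if best is None or len(ls) < len(best[1]):
                        best = (node, ls)
            node, ls = best
            all_bact = all(TMAP[l] in (4371, 436) for l in ls - recips)
            if not all_bact:
                assert got.status in (ConfirmStatus.NON_BACTERIAL, ConfirmStatus.SCATTERED)
            elif node.parent is None or node.support is None or node.support <= 90:
                assert got.status is ConfirmStatus.LOW_SUPPORT
            else:
                assert got.status is ConfirmStatus.CONFIRMED
                assert got.n_bacterial_leaves_in_clade == len(ls - recips)


class TestConstraintTree:
    def test_two_plus_two(self):
        leaves = [("a", LineageLabel.RECIPIENT), ("b", LineageLabel.RECIPIENT),
                  ("c", LineageLabel.OUTSIDE), ("d", LineageLabel.OUTSIDE)]
        assert make_constraint_tree(leaves) == "((a,b),c,d);"

    def test_counts(self):
        leaves = [(f"r{i}", LineageLabel.RECIPIENT) for i in range(3)] + [
            (f"b{i}", LineageLabel.OUTSIDE) for i in range(5)]
        t = parse_tree(make_constraint_tree(leaves))
        assert len(t.root.children) == 6  # the recipient clade + 5 loose leaves
        clade = next(c for c in t.root.children if not c.is_leaf)
        assert len(list(clade.leaves())) == 3

    def test_single_constrained_leaf_rejected(self):
        with pytest.raises(ConstraintError):
            make_constraint_tree([("a", LineageLabel.RECIPIENT), ("c", LineageLabel.OUTSIDE)])
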
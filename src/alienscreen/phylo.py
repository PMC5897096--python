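"""Phylogenetic confirmation of alien-index candidates.

A candidate is confirmed when, on its midpoint-rooted gene tree with
poorly supported branches collapsed, the recipient sequences sit inside
a clade whose only other members are bacterial and whose subtending edge
carries bootstrap support strictly greater than 90.  The taxonomic
identity of those bacterial leaves (their lowest common ancestor) is the
inferred donor lineage.

Trees are read from newick (supports as internal node labels, with the
``[&support=x]`` comment dialect tolerated) and manipulated on a plain
rooted node structure so that edge supports provably stay attached to
the same bipartition through rerooting — the step where support values
are classically misplaced.

Support scales are normalized on read: if every numeric support is
≤ 1.0 the values are treated as fractions and rescaled to 0–100.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

from .errors import ConstraintError, InputError, RootingError, TreeError
from .taxonomy import LineageConfig, LineageLabel, TaxonomyDB

log = logging.getLogger(__name__)

_EPS = 1e-12


class Node:
    """One node of a rooted gene tree.

    ``support`` and ``length`` describe the edge subtending the node
    (towards its parent); both are ``None`` on the root.
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.preorder() if n.is_leaf)


@dataclass
class GeneTree:
    """A leaf-labelled tree with branch supports (0–100) and lengths."""

    root: Node

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return list(self.root.leaves())

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def copy(self) -> "GeneTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for child in node.children:
                c.add(clone(child))
            return c

        return GeneTree(clone(self.root))

    def as_newick(self) -> str:
        """Serialize with supports as internal labels; deterministic formatting."""

        def fmt_num(x: float) -> str:
            return f"{x:g}"

        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.support is not None:
                    body += fmt_num(node.support)
                elif node.label:
                    body += node.label
            if node.length is not None:
                body += ":" + fmt_num(node.length)
            return body

        return render(self.root) + ";"


class ConfirmStatus(str, Enum):
    CONFIRMED = "confirmed"
    LOW_SUPPORT = "unconfirmed_low_support"
    NON_BACTERIAL = "unconfirmed_non_bacterial"
    SCATTERED = "unconfirmed_scattered"
    NO_TREE = "no_tree"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ConfirmationResult:
    query_id: str
    status: ConfirmStatus
    clade_support: float | None = None
    donor_taxid: int | None = None
    donor_name: str | None = None
    n_recipient_leaves: int = 0
    n_bacterial_leaves_in_clade: int = 0


# ---------------------------------------------------------------------------
# parsing


_SUPPORT_COMMENT = re.compile(r"\)([0-9.eE+-]*)\[&?support\s*=\s*([0-9.eE+-]+)\]")


def parse_tree(source: str) -> GeneTree:
    """Parse newick text into a :class:`GeneTree`.

    Numeric internal node labels are interpreted as supports; a
    ``[&support=x]`` comment overrides the label.  Duplicate leaf labels
    or malformed newick raise :class:`TreeError`.
    """
    # rewrite the comment dialect into plain internal labels up front
    source = _SUPPORT_COMMENT.sub(r")\2", source)
    try:
        dtree = dendropy.Tree.get(
            data=source,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse failure: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        if dnode.child_nodes():
            support = None
            if label is not None:
                try:
                    support = float(label)
                except ValueError:
                    support = None
            node.support = support
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.support = None
    root.length = None
    tree = GeneTree(root)

    labels = tree.leaf_labels()
    if any(lbl is None or lbl == "" for lbl in labels):
        raise TreeError("tree contains an unlabelled leaf")
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")

    supports = [n.support for n in tree.preorder() if n.support is not None]
    if supports and all(s <= 1.0 for s in supports):
        log.info("supports all ≤ 1.0; interpreting as fractions and rescaling ×100")
        for n in tree.preorder():
            if n.support is not None:
                n.support *= 100.0
    for n in tree.preorder():
        if n.support is not None and not (0.0 <= n.support <= 100.0):
            raise TreeError(f"support {n.support} outside [0, 100]")
    return tree


# ---------------------------------------------------------------------------
# rooting


def _leaf_distances(tree: GeneTree) -> dict[tuple[str, str], float]:
    """All pairwise leaf path lengths (brute force; trees here are small)."""
    adj: dict[Node, list[tuple[Node, float]]] = {}
    for node in tree.preorder():
        for child in node.children:
            if child.length is None:
                raise RootingError(
                    "midpoint rooting requires branch lengths on every edge"
                )
            adj.setdefault(node, []).append((child, child.length))
            adj.setdefault(child, []).append((node, child.length))
    out: dict[tuple[str, str], float] = {}
    leaves = tree.leaves()
    for a in leaves:
        dist = {a: 0.0}
        stack = [a]
        while stack:
            n = stack.pop()
            for nb, w in adj.get(n, []):
                if nb not in dist:
                    dist[nb] = dist[n] + w
                    stack.append(nb)
        for b in leaves:
            out[(a.label, b.label)] = dist[b]
    return out


def _path(a: Node, b: Node) -> list[Node]:
    """Node path from leaf ``a`` to leaf ``b`` through their common ancestor."""
    anc_a = []
    n = a
    while n is not None:
        anc_a.append(n)
        n = n.parent
    index = {id(x): i for i, x in enumerate(anc_a)}
    path_b = []
    n = b
    while id(n) not in index:
        path_b.append(n)
        n = n.parent
    return anc_a[: index[id(n)] + 1] + list(reversed(path_b))


def _reseed(tree: GeneTree, new_root: Node) -> None:
    """Make ``new_root`` the root, reversing parent links along the path.

    Edge lengths and supports stay attached to the physical edge: when an
    edge reverses orientation its annotation moves from the old child to
    the new child (the former parent).
    """
    chain = []
    n = new_root
    while n is not None:
        chain.append(n)
        n = n.parent
    if len(chain) == 1:
        return
    saved = [(c.length, c.support) for c in chain[:-1]]
    for child, parent in zip(chain, chain[1:]):
        parent.children.remove(child)
    for (child, parent), (length, support) in zip(zip(chain, chain[1:]), saved):
        child.children.append(parent)
        parent.parent = child
        parent.length = length
        parent.support = support
    new_root.parent = None
    new_root.length = None
    new_root.support = None
    tree.root = new_root
    _suppress_unifurcations(tree)


def _suppress_unifurcations(tree: GeneTree) -> None:
    for node in list(tree.preorder()):
        if node.parent is not None and len(node.children) == 1:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            if child.support is None:
                child.support = node.support
            i = node.parent.children.index(node)
            node.parent.children[i] = child
            child.parent = node.parent
    while tree.root.parent is None and len(tree.root.children) == 1 and not tree.root.is_leaf:
        only = tree.root.children[0]
        if only.is_leaf:
            break
        only.parent = None
        only.length = None
        only.support = None
        tree.root = only


def midpoint_root(tree: GeneTree) -> GeneTree:
    """Root the tree at the midpoint of its longest leaf-to-leaf path.

    Pairwise leaf path lengths are preserved exactly.  Among equally long
    paths the lexicographically smallest endpoint label pair is chosen; a
    midpoint landing exactly on a node attaches the root at that node.
    Returns a new tree; the input is left untouched.
    """
    tree = tree.copy()
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise RootingError("midpoint rooting needs at least two leaves")
    dists = _leaf_distances(tree)
    pairs = [(la, lb) for (la, lb) in dists if la < lb]
    diameter = max(dists[p] for p in pairs)
    tie_tol = _EPS * max(1.0, diameter)
    best_pair = min(p for p in pairs if dists[p] >= diameter - tie_tol)
    by_label = {n.label: n for n in leaves}
    a, b = by_label[best_pair[0]], by_label[best_pair[1]]
    path = _path(a, b)
    half = diameter / 2.0

    cum = [0.0]
    for prev, nxt in zip(path, path[1:]):
        child = nxt if nxt.parent is prev else prev
        cum.append(cum[-1] + child.length)
    tol = _EPS * max(1.0, diameter)
    for i, c in enumerate(cum):
        if abs(c - half) <= tol:
            _reseed(tree, path[i])
            return tree
        if c > half:
            prev, nxt = path[i - 1], path[i]
            child = nxt if nxt.parent is prev else prev
            parent = prev if child is nxt else nxt
            # portion of the edge between the child-side node and the midpoint
            child_portion = cum[i] - half if child is nxt else half - cum[i - 1]
            edge_len = child.length
            support = child.support
            parent.children.remove(child)
            new_root = Node()
            new_root.add(child)
            child.length = child_portion
            child.support = support
            new_root.length = edge_len - child_portion
            new_root.support = support
            parent.add(new_root)
            _reseed(tree, new_root)
            return tree
    raise AssertionError("midpoint not located; inconsistent branch lengths")


# ---------------------------------------------------------------------------
# collapsing and donor-clade detection


def collapse_low_support(tree: GeneTree, min_support: float = 95.0) -> GeneTree:
    """Contract internal edges with support strictly below ``min_support``.

    Children of a collapsed node reattach to its parent with the
    collapsed edge length added, so root-to-leaf distances are preserved.
    Edges with absent support are retained (absence means unknown, not
    zero — leaf edges and the root never carry bootstrap values).
    Idempotent; the leaf set never changes.  Returns a new tree.
    """
    tree = tree.copy()
    retained_blank = 0
    for node in list(tree.root.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        if node.support is None:
            retained_blank += 1
            continue
        if node.support < min_support:
            parent = node.parent
            i = parent.children.index(node)
            for child in node.children:
                child.parent = parent
                child.length = (child.length or 0.0) + (node.length or 0.0)
            parent.children[i : i + 1] = node.children
    if retained_blank:
        log.debug("%d internal edges without support retained by collapse", retained_blank)
    return tree


def _clade_leaves(node: Node) -> list[Node]:
    return list(node.leaves())


def detect_donor_clade(
    tree: GeneTree,
    recipient_ids: Iterable[str],
    db: TaxonomyDB,
    cfg: LineageConfig,
    taxon_map: Mapping[str, int],
    support_threshold: float = 90.0,
) -> ConfirmationResult:
    """Decide whether recipient sequences nest inside a bacterial clade.

    Walk from the MRCA of the recipient leaves towards the root to the
    first node whose clade contains a non-recipient leaf.  The candidate
    is confirmed iff every such leaf is bacterial (by taxonomic descent
    from the configured Bacteria taxid) and the clade's subtending edge
    has support strictly greater than ``support_threshold``.  The donor
    is the lowest common taxonomic ancestor of the bacterial leaves.
    """
    recipient_ids = set(recipient_ids)
    if not recipient_ids:
        raise InputError("recipient_ids is empty")
    by_label = {n.label: n for n in tree.leaves()}
    missing = recipient_ids - set(by_label)
    if missing:
        raise InputError(f"recipient ids absent from tree: {sorted(missing)}")
    if recipient_ids == set(by_label):
        raise InputError("tree contains no non-recipient leaves")

    # MRCA of recipients
    paths = []
    for rid in recipient_ids:
        chain = []
        n = by_label[rid]
        while n is not None:
            chain.append(n)
            n = n.parent
        paths.append(list(reversed(chain)))
    mrca = None
    for level in zip(*paths):
        if all(x is level[0] for x in level):
            mrca = level[0]
        else:
            break
    assert mrca is not None

    node = mrca
    while all(l.label in recipient_ids for l in node.leaves()):
        node = node.parent  # root always contains a non-recipient leaf

    others = [l for l in node.leaves() if l.label not in recipient_ids]

    def is_bacterial(label: str) -> bool:
        taxid = taxon_map.get(label)
        return taxid is not None and taxid in db and db.is_descendant(taxid, cfg.bacteria_taxid)

    bacterial = [l for l in others if is_bacterial(l.label)]
    n_rec = len(recipient_ids)

    if len(bacterial) != len(others):
        status = ConfirmStatus.SCATTERED if node is mrca else ConfirmStatus.NON_BACTERIAL
        return ConfirmationResult(
            query_id="", status=status, n_recipient_leaves=n_rec,
            n_bacterial_leaves_in_clade=len(bacterial),
        )

    support = node.support if node.parent is not None else None
    if support is None or support <= support_threshold:
        return ConfirmationResult(
            query_id="", status=ConfirmStatus.LOW_SUPPORT, clade_support=support,
            n_recipient_leaves=n_rec, n_bacterial_leaves_in_clade=len(bacterial),
        )
    donor = db.lca([taxon_map[l.label] for l in bacterial])
    return ConfirmationResult(
        query_id="",
        status=ConfirmStatus.CONFIRMED,
        clade_support=support,
        donor_taxid=donor,
        donor_name=db.name(donor) or None,
        n_recipient_leaves=n_rec,
        n_bacterial_leaves_in_clade=len(bacterial),
    )


# ---------------------------------------------------------------------------
# constraint trees


def make_constraint_tree(
    leaves: Sequence[tuple[str, LineageLabel]],
    constrained_label: LineageLabel = LineageLabel.RECIPIENT,
) -> str:
    """Emit a monophyly-constraint newick for topology (AU) testing.

    The leaves carrying ``constrained_label`` form one clade; all other
    leaves attach at the root polytomy.  No branch lengths are written.
    """
    inside = [lbl for lbl, lab in leaves if lab == constrained_label]
    outside = [lbl for lbl, lab in leaves if lab != constrained_label]
    if len(inside) < 2:
        raise ConstraintError(
            f"monophyly constraint needs ≥ 2 leaves labelled {constrained_label}, got {len(inside)}"
        )
    return "((" + ",".join(inside) + ")," + ",".join(outside) + ");" if outside else "(" + ",".join(inside) + ");"
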
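"""Shared fixtures: a small hand-built taxonomy and random-instance builders."""

from __future__ import annotations

import io
import random

import pytest

from alienscreen.hits import Hit, HitTable
from alienscreen.phylo import GeneTree, parse_tree
from alienscreen.taxonomy import LineageConfig, TaxonomyDB, TaxonNode, load_taxonomy

# A miniature tree of life: Bacteria (with two families), Fungi containing
# Saccharomycetales (two yeast species) and a Pezizomycotina-like branch.
SMALL_TAXONOMY_TSV = """taxid\tparent\tname
1\t1\troot
2\t1\tBacteria
435\t2\tAcetobacteraceae
436\t2\tEnterobacteriaceae
4371\t435\tAcetobacter-like sp.
4751\t1\tFungi
147538\t4751\tPezizomycotina
162425\t147538\tAspergillus-like sp.
4892\t4751\tSaccharomycetales
1003835\t4892\tStarmerella bombicola
1061180\t4892\tWickerhamiella domercqiae
"""


@pytest.fixture(scope="session")
def db() -> TaxonomyDB:
    return load_taxonomy(io.StringIO(SMALL_TAXONOMY_TSV), dialect="tsv3")


@pytest.fixture(scope="session")
def lin() -> LineageConfig:
    return LineageConfig()


BACT_TAXID = 4371  # leaf under Bacteria
BACT_FAMILY = 435
OTHER_BACT_FAMILY = 436
FUNGAL_TAXID = 162425  # leaf under Fungi but outside Saccharomycetales
RECIPIENT_TAXID = 1003835  # leaf under Saccharomycetales


def make_table(query="q1", species="ws", self_score=200.0, hits=()):
    """Build a HitTable from (target, taxid, dom_bitscore[, evalue]) tuples."""
    built = []
    for entry in hits:
        target, taxid, dom = entry[:3]
        evalue = entry[3] if len(entry) > 3 else 1e-30
        built.append(Hit(query, target, taxid, dom, dom, evalue))
    return HitTable(query, query_species=species, self_score=self_score, hits=list(built))


def random_tree(rng: random.Random, n_leaves: int, with_supports: bool = True) -> GeneTree:
    """A random binary tree in newick, with random lengths and supports."""
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(lbls: list[str]) -> str:
        if len(lbls) == 1:
            return f"{lbls[0]}:{rng.randint(1, 40) / 10}"
        k = rng.randint(1, len(lbls) - 1)
        left, right = build(lbls[:k]), build(lbls[k:])
        sup = f"{rng.randint(0, 100)}" if with_supports else ""
        return f"({left},{right}){sup}:{rng.randint(1, 40) / 10}"

    k = rng.randint(1, n_leaves - 1)
    nwk = f"({build(labels[:k])},{build(labels[k:])});"
    return parse_tree(nwk)


def random_taxonomy(rng: random.Random, n_nodes: int) -> TaxonomyDB:
    """A random rooted hierarchy with taxids 1..n (1 is the root)."""
    nodes = {1: TaxonNode(1, 1, "no rank", "root")}
    for taxid in range(2, n_nodes + 1):
        parent = rng.randint(1, taxid - 1)
        nodes[taxid] = TaxonNode(taxid, parent, "clade", f"node{taxid}")
    return TaxonomyDB(nodes=nodes, root=1)
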
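"""Collapsing confirmed candidates into ortholog groups.

Each confirmed candidate carries the leaf set of its gene tree.  Two
candidates belong to the same ortholog group when their trees share at
least one recipient candidate sequence — a tree seeded from one species'
query of a xenolog recovers the other member species' sequences among
its top hits, so replicate phylogenies of one transfer overlap.  Groups
are the connected components of that sharing graph; multiple queries
from one species inside a group are paralogs (lineage-specific
duplications), not separate groups.

Retention mirrors the screen's criteria: a group must span at least two
recipient species, and groups whose trees contain a candidate xenolog
from a declared non-recipient species are excluded.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import RosterError
from .taxonomy import TaxonomyDB

log = logging.getLogger(__name__)


def species_from_seq_id(seq_id: str) -> str:
    """Default convention: sequence ids look like ``<species>_g<number>``."""
    return seq_id.rsplit("_g", 1)[0]


@dataclass(frozen=True)
class CandidateRecord:
    query_id: str
    species: str
    confirmed: bool
    tree_leafset: frozenset[str]
    donor_taxid: int | None = None


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, set[str]]  # species → query ids
    donor_taxid: int | None = None

    @property
    def n_species(self) -> int:
        return len(self.members)

    @property
    def n_paralogs_per_species(self) -> dict[str, int]:
        return {sp: len(qs) for sp, qs in self.members.items()}

    def all_queries(self) -> list[str]:
        return sorted(q for qs in self.members.values() for q in qs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _group_id(query_ids: Iterable[str]) -> str:
    digest = hashlib.sha1("\x1f".join(sorted(query_ids)).encode()).hexdigest()
    return f"OG_{digest[:10]}"


def exclude_shared_outside(
    records: Sequence[CandidateRecord],
    outside_species: set[str],
    species_of: Callable[[str], str] = species_from_seq_id,
) -> list[CandidateRecord]:
    """Drop records whose tree contains a leaf from a non-recipient yeast species.

    ``outside_species`` is the declared roster of close relatives outside
    the recipient clade (e.g. a *C. infanticola*-like outgroup); an empty
    roster is the identity.
    """
    if not outside_species:
        return list(records)
    kept = []
    for rec in records:
        shared = {l for l in rec.tree_leafset if species_of(l) in outside_species}
        if shared:
            log.info("record %s excluded: shares leaves %s with non-recipient species",
                     rec.query_id, sorted(shared))
        else:
            kept.append(rec)
    return kept


def collapse_groups(
    records: Sequence[CandidateRecord],
    recipient_species: set[str],
    species_of: Callable[[str], str] = species_from_seq_id,
    min_shared: int = 1,
    db: TaxonomyDB | None = None,
) -> list[OrthologGroup]:
    """Merge replicate phylogenies and paralog trees into ortholog groups.

    Records are nodes; an edge joins two records whose tree leafsets
    share at least ``min_shared`` recipient candidate sequence ids.
    Groups are the connected components, with deterministic ids derived
    from the sorted member query ids; a group's donor is the lowest
    common taxonomic ancestor of its members' donors when ``db`` is
    given, else the donor shared by all members (or None).
    """
    records = list(records)
    for rec in records:
        if rec.species not in recipient_species:
            raise RosterError(
                f"record {rec.query_id} has species {rec.species!r} outside the roster"
            )
    uf = _UnionFind(len(records))
    rec_leafsets = [
        frozenset(l for l in rec.tree_leafset if species_of(l) in recipient_species)
        for rec in records
    ]
    # invert: recipient sequence id → record indices, to avoid all-pairs scans
    by_seq: dict[str, list[int]] = {}
    for i, ls in enumerate(rec_leafsets):
        for seq in ls:
            by_seq.setdefault(seq, []).append(i)
    if min_shared <= 1:
        for idxs in by_seq.values():
            for j in idxs[1:]:
                uf.union(idxs[0], j)
    else:
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                if len(rec_leafsets[i] & rec_leafsets[j]) >= min_shared:
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(records)):
        components.setdefault(uf.find(i), []).append(i)

    groups = []
    for idxs in components.values():
        members: dict[str, set[str]] = {}
        donors = []
        for i in idxs:
            members.setdefault(records[i].species, set()).add(records[i].query_id)
            if records[i].donor_taxid is not None:
                donors.append(records[i].donor_taxid)
        if db is not None and donors:
            donor = db.lca(donors)
        else:
            donor = donors[0] if donors and len(set(donors)) == 1 else None
        groups.append(OrthologGroup(_group_id(q for qs in members.values() for q in qs),
                                    members, donor))
    groups.sort(key=lambda g: g.group_id)
    return groups


def filter_min_species(
    groups: Sequence[OrthologGroup],
    min_species: int = 2,
    recipient_species: set[str] | None = None,
) -> list[OrthologGroup]:
    """Retain groups with members in at least ``min_species`` recipient species.

    Applied to groups rather than raw records so that paralog-rich
    single-species families are correctly dropped.
    """
    if recipient_species is not None:
        for g in groups:
            unknown = set(g.members) - recipient_species
            if unknown:
                raise RosterError(f"group {g.group_id} has unknown species {sorted(unknown)}")
    return [g for g in groups if g.n_species >= min_species]


def summarize_groups(
    groups: Sequence[OrthologGroup], db: TaxonomyDB | None = None
) -> dict:
    """Per-group species/paralog counts and whole-run totals."""
    per_group = []
    for g in groups:
        per_group.append(
            {
                "group_id": g.group_id,
                "n_species": g.n_species,
                "n_members": sum(len(qs) for qs in g.members.values()),
                "paralogs_per_species": dict(sorted(g.n_paralogs_per_species.items())),
                "donor_taxid": g.donor_taxid,
                "donor_name": db.name(g.donor_taxid) if db is not None and g.donor_taxid in db else None,
            }
        )
    return {
        "n_groups": len(groups),
        "n_members_total": sum(pg["n_members"] for pg in per_group),
        "groups": per_group,
    }
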
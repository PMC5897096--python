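"""Homology-hit tables: parsing, normalized bitscores, retention rules.

The raw material of the alien index is, per query protein, the set of
database hits from a phmmer-style search.  Each hit's *normalized
bitscore* (nbs) is the bitscore of its single best-scoring domain divided
by the best bitscore possible for the query — the bitscore of the query
aligned to itself — so nbs lies in [0, 1].

Retention follows the screen's printed rules: hits are sorted by nbs
(descending; ties broken by E-value then target id for reproducibility)
and at most 10,000 are kept, saving no more than five per unique taxid.
Tree sets for downstream phylogenetics take the top 200 retained hits
with full-sequence E-value strictly below 1e-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

from .errors import HitParseError, NormalizationError
from .taxonomy import Source

log = logging.getLogger(__name__)

#: tolerated numeric overshoot of nbs above 1 before a clamp is reported
NBS_TOLERANCE = 1e-9


@dataclass(frozen=True)
class Hit:
    query_id: str
    target_id: str
    taxid: int
    full_bitscore: float
    best_domain_bitscore: float
    evalue: float
    nbs: float | None = None  # filled by normalize()


@dataclass
class HitTable:
    """All hits for one query protein plus the query's self-score."""

    query_id: str
    query_species: str = ""
    self_score: float | None = None
    hits: list[Hit] = field(default_factory=list)
    n_clamped: int = 0  # hits whose nbs exceeded 1 + tolerance and were clamped


@dataclass
class TreeSetSelection:
    """The ordered target ids chosen for gene-tree reconstruction."""

    query_id: str
    selected_target_ids: list[str]
    evalue_cutoff: float = 1e-10
    max_n: int = 200
    min_trimmed_length: int = 150


# ---------------------------------------------------------------------------
# parsing

# column indices (whitespace-split) in HMMER3 tabular layouts
_TBLOUT_COLS = 18  # 18 fixed columns before free-text description
_DOMTBLOUT_COLS = 22


def _floats(parts: list[str], idx: int, lineno: int, what: str) -> float:
    try:
        return float(parts[idx])
    except (ValueError, IndexError):
        raise HitParseError(f"non-numeric or missing {what}: {parts[idx] if idx < len(parts) else '<absent>'!r}", lineno) from None


def _resolve_taxid(target: str, taxon_map: Mapping[str, int] | None, lineno: int) -> int:
    if taxon_map is None:
        raise HitParseError("a taxon_map is required for this dialect", lineno)
    # uncovered targets are carried with taxid -1; the taxonomy policy
    # (drop-with-warning by default) deals with them downstream
    if target not in taxon_map:
        log.warning("target %s not covered by the taxon map", target)
        return -1
    return taxon_map[target]


def _parse_hmmer_tblout(handle: IO[str], taxon_map) -> list[Hit]:
    # tblout: one row per (query, target); column 6 is the full-sequence
    # bitscore and column 9 the best-single-domain bitscore.
    out: list[Hit] = []
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 10:
            raise HitParseError("tblout row has fewer than 10 columns", lineno)
        target, query = parts[0], parts[2]
        evalue = _floats(parts, 4, lineno, "E-value")
        full = _floats(parts, 5, lineno, "bitscore")
        dom = _floats(parts, 8, lineno, "best-domain bitscore")
        out.append(Hit(query, target, _resolve_taxid(target, taxon_map, lineno), full, dom, evalue))
    return out


def _parse_hmmer_domtblout(handle: IO[str], taxon_map) -> list[Hit]:
    # domtblout: one row per domain; the best single domain is the max of
    # the per-domain scores (column 14); full-sequence stats repeat per row.
    best: dict[tuple[str, str], Hit] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 14:
            raise HitParseError("domtblout row has fewer than 14 columns", lineno)
        target, query = parts[0], parts[3]
        evalue = _floats(parts, 6, lineno, "E-value")
        full = _floats(parts, 7, lineno, "bitscore")
        dom = _floats(parts, 13, lineno, "domain bitscore")
        key = (query, target)
        if key not in best:
            order.append(key)
            best[key] = Hit(query, target, _resolve_taxid(target, taxon_map, lineno), full, dom, evalue)
        elif dom > best[key].best_domain_bitscore:
            best[key] = replace(best[key], best_domain_bitscore=dom)
    return [best[k] for k in order]


GENERIC_HEADER = ["query", "target", "taxid", "bitscore", "dom_bitscore", "evalue"]


def _parse_generic_tsv(handle: IO[str], taxon_map) -> list[Hit]:
    header = handle.readline().rstrip("\n").split("\t")
    if header != GENERIC_HEADER:
        raise HitParseError(f"generic_tsv header must be {GENERIC_HEADER}, got {header}", 1)
    out: list[Hit] = []
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise HitParseError("generic_tsv row must have 6 columns", lineno)
        query, target = parts[0], parts[1]
        try:
            taxid = int(parts[2])
        except ValueError:
            raise HitParseError(f"non-integer taxid {parts[2]!r}", lineno) from None
        full = _floats(parts, 3, lineno, "bitscore")
        dom = _floats(parts, 4, lineno, "dom_bitscore")
        evalue = _floats(parts, 5, lineno, "evalue")
        out.append(Hit(query, target, taxid, full, dom, evalue))
    return out


_DIALECTS = {
    "hmmer_tblout": _parse_hmmer_tblout,
    "hmmer_domtblout": _parse_hmmer_domtblout,
    "generic_tsv": _parse_generic_tsv,
}


def parse_hits(
    source: Source,
    dialect: str = "generic_tsv",
    taxon_map: Mapping[str, int] | None = None,
    species: str = "",
) -> list[HitTable]:
    """Parse a hit table file into one :class:`HitTable` per query.

    ``taxon_map`` (target id → taxid) is required for the HMMER dialects;
    the generic TSV carries taxids inline.  Duplicate (query, target)
    rows keep the max-bitscore row with a warning.  Queries appear in
    order of first occurrence.
    """
    if dialect not in _DIALECTS:
        raise HitParseError(f"unknown hit-table dialect {dialect!r}")
    if hasattr(source, "read"):
        hits = _DIALECTS[dialect](source, taxon_map)
    else:
        with open(source, "r", encoding="utf-8") as handle:
            hits = _DIALECTS[dialect](handle, taxon_map)

    tables: dict[str, HitTable] = {}
    seen: dict[tuple[str, str], int] = {}
    for h in hits:
        table = tables.setdefault(h.query_id, HitTable(h.query_id, query_species=species))
        key = (h.query_id, h.target_id)
        if key in seen:
            log.warning("duplicate hit row for %s → %s; keeping max bitscore", *key)
            i = seen[key]
            if h.full_bitscore > table.hits[i].full_bitscore:
                table.hits[i] = h
        else:
            seen[key] = len(table.hits)
            table.hits.append(h)
    return list(tables.values())


def read_self_scores(source: Source) -> dict[str, float]:
    """Read a 2-column self-score sidecar TSV (query_id → bits)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    out: dict[str, float] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise HitParseError("self-score row must have 2 columns", lineno)
        out[parts[0]] = float(parts[1])
    return out


# ---------------------------------------------------------------------------
# normalization and retention


def normalize(table: HitTable, self_score: float | None = None) -> HitTable:
    """Fill every hit's nbs = best_domain_bitscore / self_score.

    The self-score is taken, in order of preference, from the explicit
    argument, the table's stored value, or the query's own self-hit row
    (target id equal to the query id).  Values exceeding 1 by more than
    ``NBS_TOLERANCE`` are clamped to 1.0 with a warning and counted in
    ``table.n_clamped``; smaller overshoots are clamped silently.
    """
    score = self_score if self_score is not None else table.self_score
    if score is None:
        for h in table.hits:
            if h.target_id == table.query_id:
                score = h.full_bitscore
                break
    if score is None or score <= 0:
        raise NormalizationError(
            f"no positive self-score available for query {table.query_id}"
        )
    clamped = 0
    new_hits = []
    for h in table.hits:
        nbs = h.best_domain_bitscore / score
        if nbs > 1.0 + NBS_TOLERANCE:
            log.warning(
                "query %s hit %s: nbs %.6g exceeds 1; clamped", table.query_id, h.target_id, nbs
            )
            clamped += 1
            nbs = 1.0
        elif nbs > 1.0:
            nbs = 1.0
        new_hits.append(replace(h, nbs=nbs))
    return HitTable(table.query_id, table.query_species, score, new_hits, clamped)


def _sort_key(h: Hit):
    return (-(h.nbs if h.nbs is not None else 0.0), h.evalue, h.target_id)


def sort_and_cap(table: HitTable, max_total: int = 10000, max_per_taxon: int = 5) -> HitTable:
    """Sort hits by (nbs desc, E-value asc, target id asc) and cap them.

    A single descending scan keeps a hit only while its taxid has fewer
    than ``max_per_taxon`` kept hits and fewer than ``max_total`` hits are
    kept overall.  Idempotent; empty tables pass through.
    """
    kept: list[Hit] = []
    per_taxon: dict[int, int] = {}
    for h in sorted(table.hits, key=_sort_key):
        if len(kept) >= max_total:
            break
        if per_taxon.get(h.taxid, 0) >= max_per_taxon:
            continue
        per_taxon[h.taxid] = per_taxon.get(h.taxid, 0) + 1
        kept.append(h)
    return HitTable(table.query_id, table.query_species, table.self_score, kept, table.n_clamped)


def select_tree_set(
    table: HitTable,
    evalue_cutoff: float = 1e-10,
    max_n: int = 200,
    min_trimmed_length: int = 150,
) -> TreeSetSelection:
    """Choose the top ``max_n`` retained hits with E-value strictly below the cutoff.

    The table must already be sorted and capped; selection preserves table
    order.  The full-sequence E-value is used.
    """
    selected = [h.target_id for h in table.hits if h.evalue < evalue_cutoff][:max_n]
    return TreeSetSelection(table.query_id, selected, evalue_cutoff, max_n, min_trimmed_length)


def apply_length_filter(
    alignment_lengths: Mapping[str, int], min_len: int = 150
) -> set[str]:
    """Return query ids whose trimmed alignment is at least ``min_len`` residues.

    Lengths strictly below the cutoff are excluded (149 goes, 150 stays).
    """
    for q, length in alignment_lengths.items():
        if length < 0:
            raise ValueError(f"negative trimmed length {length} for query {q}")
    return {q for q, length in alignment_lengths.items() if length >= min_len}


# ---------------------------------------------------------------------------
# tree-set sequence extraction


def extract_tree_set_fasta(
    selection: TreeSetSelection,
    sequences: Mapping[str, str],
    out_path: Union[str, Path],
) -> int:
    """Write the selected full-length proteins to FASTA (60-column wrap).

    ``sequences`` maps target id → amino-acid string (e.g. built with
    Bio.SeqIO from the search database).  Returns the number written;
    missing targets are logged and skipped.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for tid in selection.selected_target_ids:
        if tid not in sequences:
            log.warning("tree-set target %s absent from sequence source", tid)
            continue
        records.append(SeqRecord(Seq(sequences[tid]), id=tid, description=""))
    with open(out_path, "w", encoding="utf-8") as handle:
        seqio_write(records, handle, "fasta")
    return len(records)
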
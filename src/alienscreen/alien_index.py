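"""The bitscore-based alien index (AI).

For one query protein with normalized hits,

    AI = nbsO − nbsG

where nbsO is the normalized bitscore of the best hit to a species
OUTSIDE the group lineage and nbsG the best hit WITHIN the group lineage,
skipping all hits to the recipient lineage (including the query's own
self-hit).  A missing lineage contributes 0, so AI always lies in
[−1, +1]; queries with AI strictly greater than the configured threshold
(0.1 by default) are strong HGT candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .hits import HitTable
from .taxonomy import LineageConfig, LineageLabel, TaxonomyDB, classify

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AIResult:
    query_id: str
    query_species: str
    nbsO: float
    nbsG: float
    ai: float
    is_candidate: bool = False
    best_outside_target: str | None = None
    best_outside_taxid: int | None = None
    # distinguishes ai == 0 because scores balanced from ai == 0 because
    # a lineage had no hits at all
    has_outside_hit: bool = False
    has_group_hit: bool = False


def compute_ai(
    table: HitTable,
    db: TaxonomyDB,
    cfg: LineageConfig,
    on_missing: str = "drop",
) -> AIResult:
    """Compute the alien index for one normalized, sorted, capped table.

    Hits whose taxid cannot be classified are handled per ``on_missing``
    (default: dropped with a warning).  The best-outside hit reported is
    the arg-max under the table's deterministic ordering.
    """
    nbsO = 0.0
    nbsG = 0.0
    best_outside = None
    has_outside = False
    has_group = False
    for h in table.hits:
        label = classify(db, h.taxid, cfg, on_missing=on_missing)
        if label is None or label is LineageLabel.RECIPIENT:
            continue
        nbs = h.nbs if h.nbs is not None else 0.0
        if label is LineageLabel.OUTSIDE:
            has_outside = True
            if nbs > nbsO:
                nbsO = nbs
                best_outside = h
        else:  # GROUP
            has_group = True
            if nbs > nbsG:
                nbsG = nbs
    return AIResult(
        query_id=table.query_id,
        query_species=table.query_species,
        nbsO=nbsO,
        nbsG=nbsG,
        ai=nbsO - nbsG,
        best_outside_target=best_outside.target_id if best_outside else None,
        best_outside_taxid=best_outside.taxid if best_outside else None,
        has_outside_hit=has_outside,
        has_group_hit=has_group,
    )


def call_candidate(result: AIResult, cfg: LineageConfig) -> AIResult:
    """Flag the result as a strong HGT candidate iff ai > threshold, strictly."""
    return replace(result, is_candidate=result.ai > cfg.candidate_threshold)


def screen_proteome(
    tables: Iterable[HitTable],
    db: TaxonomyDB,
    cfg: LineageConfig,
    on_missing: str = "drop",
) -> list[AIResult]:
    """Compute and call the AI for every query of one species, in input order."""
    results = [
        call_candidate(compute_ai(t, db, cfg, on_missing=on_missing), cfg)
        for t in tables
    ]
    n_cand = sum(r.is_candidate for r in results)
    log.info("screened %d queries: %d strong candidates (AI > %g)",
             len(results), n_cand, cfg.candidate_threshold)
    return results
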
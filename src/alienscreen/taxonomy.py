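"""Taxonomy loading and lineage classification.

The screen anchors on two nested taxa: the RECIPIENT lineage into which
transfers are hypothesised (Saccharomycetales, NCBI taxid 4892 by default)
and a larger ancestral GROUP (Fungi, taxid 4751).  Every hit taxon is
classified into exactly one of three labels:

``RECIPIENT``
    descendant of the recipient taxid (including the taxid itself);
``GROUP``
    descendant of the group taxid but not of the recipient taxid;
``OUTSIDE``
    everything else (bacteria, archaea, non-fungal eukaryotes, ...).

Membership is purely topological — rank strings are carried for display
but never consulted.  Two on-disk dialects are supported: the NCBI
``nodes.dmp``/``names.dmp`` dump format and a simplified 3-column TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

from .errors import ConfigError, TaxonomyStructureError, UnknownTaxonError

log = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]


class LineageLabel(str, Enum):
    """Exhaustive, mutually exclusive lineage assignment for a taxid."""

    RECIPIENT = "RECIPIENT"
    GROUP = "GROUP"
    OUTSIDE = "OUTSIDE"

    def __str__(self) -> str:  # keeps TSV output clean
        return self.value


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str = ""
    name: str = ""


@dataclass
class TaxonomyDB:
    """A rooted taxon hierarchy answering ancestor/descendant queries.

    Invariants (validated on construction): every non-root node's parent
    exists, the root is its own parent, and parent links are acyclic.
    """

    nodes: dict[int, TaxonNode]
    root: int

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise TaxonomyStructureError(f"root taxid {self.root} has no node")
        if self.nodes[self.root].parent != self.root:
            raise TaxonomyStructureError(
                f"root taxid {self.root} must be its own parent"
            )
        n = len(self.nodes)
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise TaxonomyStructureError(
                    f"taxid {taxid} names absent parent {node.parent}"
                )
            # cycle check: the walk must hit the root in < n steps
            cur, steps = taxid, 0
            while cur != self.root:
                cur = self.nodes[cur].parent
                steps += 1
                if steps >= n:
                    raise TaxonomyStructureError(
                        f"cycle detected on the parent path of taxid {taxid}"
                    )

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self._node(taxid).name

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None

    # -- queries -----------------------------------------------------------

    def ancestors(self, taxid: int) -> Iterator[int]:
        """Yield ``taxid`` and then every ancestor up to and including the root."""
        cur = self._node(taxid).taxid
        while True:
            yield cur
            parent = self.nodes[cur].parent
            if parent == cur:
                return
            cur = parent

    def is_descendant(self, taxid: int, ancestor: int) -> bool:
        """True iff walking parent links from ``taxid`` reaches ``ancestor``.

        Every taxid is a descendant of itself.
        """
        self._node(ancestor)  # raise on unresolvable ancestor too
        return any(a == ancestor for a in self.ancestors(taxid))

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty collection of taxids."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca() of an empty taxid collection")
        common: list[int] | None = None
        for t in taxids:
            path = list(self.ancestors(t))
            if common is None:
                common = path
            else:
                keep = set(path)
                common = [a for a in common if a in keep]
        assert common, "root is always shared"
        return common[0]


def is_descendant(db: TaxonomyDB, taxid: int, ancestor: int) -> bool:
    """Module-level convenience wrapper for :meth:`TaxonomyDB.is_descendant`."""
    return db.is_descendant(taxid, ancestor)


@dataclass
class LineageConfig:
    """Anchor lineages and the candidate-calling threshold of the screen.

    ``bacteria_taxid`` names the superkingdom used by the confirmation
    stage to decide whether a donor clade is bacterial; lineage membership
    is decided by taxonomic descent, never by name matching.
    """

    recipient_taxid: int = 4892  # Saccharomycetales
    group_taxid: int = 4751  # Fungi
    bacteria_taxid: int = 2  # superkingdom Bacteria
    candidate_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (-1.0 < self.candidate_threshold < 1.0):
            raise ConfigError(
                f"candidate_threshold must lie in (-1, 1), got {self.candidate_threshold}"
            )

    def validate_against(self, db: TaxonomyDB) -> None:
        """Check that the recipient nests inside the group in this taxonomy."""
        if not db.is_descendant(self.recipient_taxid, self.group_taxid):
            raise ConfigError(
                f"recipient taxid {self.recipient_taxid} is not a descendant "
                f"of group taxid {self.group_taxid}"
            )


# ---------------------------------------------------------------------------
# loading


def _open(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _rows_tsv3(handle: IO[str]) -> Iterator[tuple[int, int, str, str]]:
    header = handle.readline()
    if not header.lower().startswith("taxid"):
        raise TaxonomyStructureError(
            "tsv3 taxonomy must start with a 'taxid<TAB>parent<TAB>name' header"
        )
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise TaxonomyStructureError(f"tsv3 row has fewer than 3 columns: {line!r}")
        yield int(parts[0]), int(parts[1]), "", parts[2]


def _rows_ncbi_dmp(handle: IO[str]) -> Iterator[tuple[int, int, str, str]]:
    # nodes.dmp fields are separated by "\t|\t" and rows end in "\t|";
    # fields used: 1 taxid, 2 parent, 3 rank.
    for line in handle:
        line = line.rstrip("\n").rstrip("|").rstrip("\t")
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) < 3:
            raise TaxonomyStructureError(f"nodes.dmp row has fewer than 3 fields: {line!r}")
        yield int(parts[0]), int(parts[1]), parts[2], ""


def load_names_dmp(source: Source) -> dict[int, str]:
    """Read scientific names (class ``scientific name`` only) from names.dmp."""
    handle, close = _open(source)
    names: dict[int, str] = {}
    try:
        for line in handle:
            parts = [p.strip() for p in line.rstrip("\n").rstrip("|").split("|")]
            if len(parts) >= 4 and parts[3] == "scientific name":
                names[int(parts[0])] = parts[1]
    finally:
        if close:
            handle.close()
    return names


def load_taxonomy(
    source: Source,
    dialect: str = "tsv3",
    names: Source | Mapping[int, str] | None = None,
) -> TaxonomyDB:
    """Load a taxonomy from ``tsv3`` or NCBI ``ncbi_dmp`` dialect.

    ``names`` may be a names.dmp path/stream or a prebuilt taxid→name map;
    it is only consulted for the ncbi_dmp dialect (tsv3 carries names
    inline).  Unknown rank strings are tolerated and carried verbatim.
    """
    if dialect == "tsv3":
        rows = _rows_tsv3
    elif dialect == "ncbi_dmp":
        rows = _rows_ncbi_dmp
    else:
        raise ConfigError(f"unknown taxonomy dialect {dialect!r}")

    name_map: Mapping[int, str] = {}
    if names is not None:
        name_map = names if isinstance(names, Mapping) else load_names_dmp(names)

    handle, close = _open(source)
    try:
        nodes: dict[int, TaxonNode] = {}
        root: int | None = None
        for taxid, parent, rank, name in rows(handle):
            if not name:
                name = name_map.get(taxid, "")
            if taxid in nodes:
                raise TaxonomyStructureError(f"duplicate taxid {taxid}")
            nodes[taxid] = TaxonNode(taxid, parent, rank, name)
            if taxid == parent:
                if root is not None and root != taxid:
                    raise TaxonomyStructureError(
                        f"two root rows found: {root} and {taxid}"
                    )
                root = taxid
    finally:
        if close:
            handle.close()
    if root is None:
        raise TaxonomyStructureError("no root row (taxid == parent) found")
    return TaxonomyDB(nodes=nodes, root=root)


# ---------------------------------------------------------------------------
# classification


def classify(
    db: TaxonomyDB,
    taxid: int,
    cfg: LineageConfig,
    on_missing: str = "drop",
) -> LineageLabel | None:
    """Classify ``taxid`` into RECIPIENT / GROUP / OUTSIDE.

    Taxids absent from the taxonomy are handled per ``on_missing``:
    ``"drop"`` (default) logs a warning and returns ``None`` so the caller
    can skip the hit — real taxonomy dumps and hit tables drift out of
    sync; ``"error"`` raises :class:`UnknownTaxonError`.
    """
    if taxid not in db:
        if on_missing == "error":
            raise UnknownTaxonError(taxid)
        log.warning("taxid %s not in taxonomy; hit dropped", taxid)
        return None
    if db.is_descendant(taxid, cfg.recipient_taxid):
        return LineageLabel.RECIPIENT
    if db.is_descendant(taxid, cfg.group_taxid):
        return LineageLabel.GROUP
    return LineageLabel.OUTSIDE
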
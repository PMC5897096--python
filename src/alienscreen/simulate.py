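"""Synthetic taxonomies, hit tables, and gene trees with planted transfers.

The generator emulates the statistical structure the screen assumes
rather than simulating sequences: a hit's bitscore decays exponentially
with the divergence between query and target,

    bitscore(d) = self_score · exp(−λ·d) + Normal(0, noise_sd),  clamped at 0.

Vertical genes place their closest non-recipient homolog inside Fungi
(small divergence, high nbs) and keep all bacterial homologs distant;
planted HGT genes invert that geometry, with the closest homolog in an
Acetobacteraceae-like donor family.  Each planted transfer founds a gene
family shared by every recipient species, whose members recover each
other among their top hits — so replicate gene trees overlap, and the
ortholog-group stage has a known answer (the planted family count).
With ``noise_sd = 0`` the planted labels are perfectly separable at the
default AI threshold.

Everything is a pure function of (seed, config): regenerated outputs are
byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ConfigError
from .hits import Hit, HitTable
from .phylo import GeneTree, parse_tree
from .taxonomy import TaxonNode, TaxonomyDB

# fixed anchor taxids, matching the NCBI ids the screen defaults to
ROOT_TAXID = 1
BACTERIA_TAXID = 2
FUNGI_TAXID = 4751
SACCHAROMYCETALES_TAXID = 4892
_BACT_BASE = 2000
_FUNGI_BASE = 3000
_RECIPIENT_BASE = 4000


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic screen.  The seed is mandatory.

    ``near_depth``/``donor_depth`` are the divergences (substitutions per
    site, loosely) of the closest and the distant non-recipient homologs;
    with the defaults and ``decay_rate = 1`` they yield nbs ≈ 0.90 and
    0.14, i.e. |AI| ≈ 0.77 for every gene when noise is off.
    """

    seed: int
    n_species: int = 6
    n_genes: int = 200
    hgt_fraction: float = 0.1
    self_score_range: tuple[float, float] = (150.0, 800.0)
    decay_rate: float = 1.0
    noise_sd: float = 0.0
    near_depth: float = 0.1
    donor_depth: float = 2.0
    n_bacterial_taxa: int = 5
    n_fungal_taxa: int = 5
    redundancy: int = 7  # hits per taxon; > 5 exercises the per-taxon cap
    support_high: int = 98
    support_low: int = 80
    borderline_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_genes < 1:
            raise ConfigError("n_species and n_genes must be ≥ 1")
        if not (0.0 <= self.hgt_fraction <= 1.0):
            raise ConfigError("hgt_fraction must lie in [0, 1]")
        if self.n_bacterial_taxa < 1 and self.hgt_fraction > 0:
            raise ConfigError("no bacterial taxa: no donor possible with hgt_fraction > 0")
        if self.n_fungal_taxa < 1 or self.redundancy < 1:
            raise ConfigError("n_fungal_taxa and redundancy must be ≥ 1")
        if self.decay_rate <= 0 or self.noise_sd < 0:
            raise ConfigError("decay_rate must be > 0 and noise_sd ≥ 0")

    @property
    def n_hgt_families(self) -> int:
        return round(self.n_genes * self.hgt_fraction)

    def species_names(self) -> list[str]:
        return [f"ws{i + 1}" for i in range(self.n_species)]

    def species_taxid(self, i: int) -> int:
        return _RECIPIENT_BASE + 1 + i

    @property
    def donor_taxid(self) -> int:
        return _BACT_BASE + 1


@dataclass
class TruthRow:
    query_id: str
    species: str
    is_hgt: bool
    donor_taxid: int | None
    family_id: str


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def by_query(self) -> dict[str, TruthRow]:
        return {r.query_id: r for r in self.rows}

    def planted_families(self, min_species: int = 2) -> set[str]:
        """Family ids of planted transfers spanning ≥ ``min_species`` species."""
        span: dict[str, set[str]] = {}
        for r in self.rows:
            if r.is_hgt:
                span.setdefault(r.family_id, set()).add(r.species)
        return {f for f, sps in span.items() if len(sps) >= min_species}


def gen_taxonomy(cfg: SimulationConfig) -> TaxonomyDB:
    """A rooted taxonomy with Bacteria, Fungi, and the recipient order.

    Bacterial families sit under the superkingdom Bacteria; the first one
    is the Acetobacteraceae-like donor.  Recipient species are leaves of
    Saccharomycetales (4892) inside Fungi (4751).  Deterministic — no
    randomness is needed.
    """
    nodes = {
        ROOT_TAXID: TaxonNode(ROOT_TAXID, ROOT_TAXID, "no rank", "root"),
        BACTERIA_TAXID: TaxonNode(BACTERIA_TAXID, ROOT_TAXID, "superkingdom", "Bacteria"),
        FUNGI_TAXID: TaxonNode(FUNGI_TAXID, ROOT_TAXID, "kingdom", "Fungi"),
        SACCHAROMYCETALES_TAXID: TaxonNode(
            SACCHAROMYCETALES_TAXID, FUNGI_TAXID, "order", "Saccharomycetales"
        ),
    }
    for b in range(cfg.n_bacterial_taxa):
        taxid = _BACT_BASE + 1 + b
        name = "Acetobacteraceae_like" if b == 0 else f"BacterialFamily{b + 1}"
        nodes[taxid] = TaxonNode(taxid, BACTERIA_TAXID, "family", name)
    for f in range(cfg.n_fungal_taxa):
        taxid = _FUNGI_BASE + 1 + f
        nodes[taxid] = TaxonNode(taxid, FUNGI_TAXID, "genus", f"OtherFungus{f + 1}")
    for s, name in enumerate(cfg.species_names()):
        taxid = cfg.species_taxid(s)
        nodes[taxid] = TaxonNode(taxid, SACCHAROMYCETALES_TAXID, "species", name)
    return TaxonomyDB(nodes=nodes, root=ROOT_TAXID)


def taxon_map(cfg: SimulationConfig) -> dict[str, int]:
    """target id → taxid for every target the generator can emit."""
    out: dict[str, int] = {}
    for b in range(cfg.n_bacterial_taxa):
        taxid = _BACT_BASE + 1 + b
        for j in range(cfg.redundancy):
            out[f"t{taxid}_{j}"] = taxid
    for f in range(cfg.n_fungal_taxa):
        taxid = _FUNGI_BASE + 1 + f
        for j in range(cfg.redundancy):
            out[f"t{taxid}_{j}"] = taxid
    for s, name in enumerate(cfg.species_names()):
        for g in range(cfg.n_genes):
            out[f"{name}_g{g:03d}"] = cfg.species_taxid(s)
    return out


def _query_id(species: str, gene: int) -> str:
    return f"{species}_g{gene:03d}"


def _family(cfg: SimulationConfig, species: str, gene: int) -> tuple[str, bool]:
    if gene < cfg.n_hgt_families:
        return f"F{gene:03d}", True
    return f"V_{species}_g{gene:03d}", False


def _bitscore(cfg: SimulationConfig, self_score: float, d: float, rng) -> float:
    bits = self_score * math.exp(-cfg.decay_rate * d)
    if cfg.noise_sd > 0:
        bits += rng.normal(0.0, cfg.noise_sd)
    return round(max(bits, 0.0), 1)


def _evalue(bits: float) -> float:
    # a Karlin–Altschul-shaped link: E = m·2^(−bits) for a nominal search space
    return 1e7 * 2.0 ** (-bits)


def gen_hit_tables(
    cfg: SimulationConfig, db: TaxonomyDB | None = None
) -> tuple[list[HitTable], TruthTable]:
    """Hit tables for every (species, gene), plus the planted truth.

    Each table contains the query's self-hit, cross-hits to the other
    recipient members of its family (HGT families only), ``redundancy``
    hits per fungal taxon and per bacterial family, and for HGT genes the
    donor family moved to ``near_depth`` while Fungi recede to
    ``donor_depth``.
    """
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species_names()
    tables: list[HitTable] = []
    truth_rows: list[TruthRow] = []

    for s, sp in enumerate(species):
        sp_taxid = cfg.species_taxid(s)
        for g in range(cfg.n_genes):
            qid = _query_id(sp, g)
            fam, is_hgt = _family(cfg, sp, g)
            self_score = round(float(rng.uniform(*cfg.self_score_range)), 1)
            hits: list[Hit] = []

            def add(target: str, taxid: int, d: float) -> None:
                bits = _bitscore(cfg, self_score, d, rng)
                hits.append(Hit(qid, target, taxid, bits, bits, _evalue(bits)))

            # self-hit: the query aligned to itself
            hits.append(Hit(qid, qid, sp_taxid, self_score, self_score, _evalue(self_score)))
            if is_hgt:
                for o, osp in enumerate(species):
                    if o != s:
                        add(_query_id(osp, g), cfg.species_taxid(o), 0.04)
            for f in range(cfg.n_fungal_taxa):
                taxid = _FUNGI_BASE + 1 + f
                base = cfg.near_depth if not is_hgt else cfg.donor_depth
                for j in range(cfg.redundancy):
                    add(f"t{taxid}_{j}", taxid, base + 0.02 * j + 0.01 * f)
            for b in range(cfg.n_bacterial_taxa):
                taxid = _BACT_BASE + 1 + b
                if is_hgt:
                    base = cfg.near_depth if b == 0 else cfg.near_depth + 0.6
                else:
                    base = cfg.donor_depth
                for j in range(cfg.redundancy):
                    add(f"t{taxid}_{j}", taxid, base + 0.02 * j + 0.01 * b)

            tables.append(HitTable(qid, query_species=sp, self_score=self_score, hits=hits))
            truth_rows.append(
                TruthRow(qid, sp, is_hgt, cfg.donor_taxid if is_hgt else None, fam)
            )
    return tables, TruthTable(truth_rows)


def gen_gene_trees(
    cfg: SimulationConfig, truth: TruthTable, include_vertical: bool = False
) -> dict[str, GeneTree]:
    """One gene tree per planted HGT family (and, on request, per vertical gene).

    HGT trees nest the recipient members inside the donor family's
    leaves; the support on the uniting edge is ``support_high``, or
    ``support_low`` for the first ``borderline_fraction`` of families (to
    exercise the unconfirmed statuses).  Vertical trees nest the single
    recipient among fungal leaves instead.
    """
    species = cfg.species_names()
    donor = cfg.donor_taxid
    donor_leaves = [f"t{donor}_{j}" for j in range(min(cfg.redundancy, 4))]
    other_bact = (
        [f"t{_BACT_BASE + 2}_{j}" for j in range(min(cfg.redundancy, 2))]
        if cfg.n_bacterial_taxa > 1
        else []
    )
    fungal = [
        f"t{_FUNGI_BASE + 1 + f}_0" for f in range(min(cfg.n_fungal_taxa, 3))
    ]
    sH = cfg.support_high

    families: dict[str, list[str]] = {}
    vertical: dict[str, str] = {}
    for row in truth.rows:
        if row.is_hgt:
            families.setdefault(row.family_id, []).append(row.query_id)
        elif include_vertical:
            vertical[row.family_id] = row.query_id

    n_borderline = math.ceil(cfg.borderline_fraction * len(families)) if families else 0
    trees: dict[str, GeneTree] = {}
    for i, fam in enumerate(sorted(families)):
        members = sorted(families[fam])
        sU = cfg.support_low if i < n_borderline else cfg.support_high
        rec = ",".join(f"{m}:0.02" for m in members)
        don = ",".join(f"{d}:0.02" for d in donor_leaves)
        fun = ",".join(f"{f}:0.1" for f in fungal)
        if other_bact:
            ob = ",".join(f"{b}:0.05" for b in other_bact)
            far = f"(({ob}){sH}:0.3,({fun}){sH}:0.6){sH}:0.5"
        else:
            far = f"({fun}){sH}:1.1"
        nwk = f"((({rec}){sH}:0.05,({don}){sH}:0.05){sU}:0.5,{far});"
        trees[fam] = parse_tree(nwk)
    for fam, qid in sorted(vertical.items()):
        fun = ",".join(f"{f}:0.1" for f in fungal)
        bac = ",".join(f"{d}:0.05" for d in donor_leaves)
        nwk = f"(({qid}:0.02,{fun}){sH}:0.5,({bac}){sH}:0.8);"
        trees[fam] = parse_tree(nwk)
    return trees


# ---------------------------------------------------------------------------
# file-level round trip


def write_bundle(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete input bundle: taxonomy, taxon map, hit tables,
    per-query gene trees for the planted families, and the truth table.

    The formats are exactly the ones the pipeline reads, so
    simulate → run is a file-level round trip.  Returns ``outdir``.
    """
    outdir = Path(outdir)
    (outdir / "hits").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)

    db = gen_taxonomy(cfg)
    with open(outdir / "taxonomy.tsv", "w", encoding="utf-8") as fh:
        fh.write("taxid\tparent\tname\n")
        for taxid in sorted(db.nodes):
            n = db.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.parent}\t{n.name}\n")

    tmap = taxon_map(cfg)
    with open(outdir / "taxon_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("target\ttaxid\n")
        for target in sorted(tmap):
            fh.write(f"{target}\t{tmap[target]}\n")

    tables, truth = gen_hit_tables(cfg, db)
    by_species: dict[str, list[HitTable]] = {}
    for t in tables:
        by_species.setdefault(t.query_species, []).append(t)
    for sp, sp_tables in sorted(by_species.items()):
        with open(outdir / "hits" / f"hits_{sp}.tsv", "w", encoding="utf-8") as fh:
            fh.write("query\ttarget\ttaxid\tbitscore\tdom_bitscore\tevalue\n")
            for t in sp_tables:
                for h in t.hits:
                    fh.write(
                        f"{h.query_id}\t{h.target_id}\t{h.taxid}\t"
                        f"{h.full_bitscore:.1f}\t{h.best_domain_bitscore:.1f}\t"
                        f"{h.evalue:.6g}\n"
                    )

    trees = gen_gene_trees(cfg, truth)
    fam_members: dict[str, list[str]] = {}
    for row in truth.rows:
        if row.is_hgt:
            fam_members.setdefault(row.family_id, []).append(row.query_id)
    for fam, tree in sorted(trees.items()):
        nwk = tree.as_newick() + "\n"
        for qid in fam_members.get(fam, []):
            (outdir / "trees" / f"{qid}.nwk").write_text(nwk, encoding="utf-8")

    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("query_id\tspecies\tis_hgt\tdonor_taxid\tfamily_id\n")
        for r in truth.rows:
            donor = r.donor_taxid if r.donor_taxid is not None else ""
            fh.write(f"{r.query_id}\t{r.species}\t{int(r.is_hgt)}\t{donor}\t{r.family_id}\n")

    echo = asdict(cfg)
    echo["self_score_range"] = list(cfg.self_score_range)
    (outdir / "sim_config.json").write_text(
        json.dumps(echo, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return outdir


def read_truth(path: str | Path) -> TruthTable:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            q, sp, is_hgt, donor, fam = line.rstrip("\n").split("\t")
            rows.append(TruthRow(q, sp, bool(int(is_hgt)), int(donor) if donor else None, fam))
    return TruthTable(rows)
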
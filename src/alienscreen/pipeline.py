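"""End-to-end orchestration: screen → confirm → group, plus simulation.

Each stage reads and writes plain text files (TSV reports, JSON
summaries, newick trees) so external tools can slot in between stages.
All outputs are deterministic given inputs and configuration, and every
summary echoes the configuration it was produced under.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable

from . import __version__
from .alien_index import AIResult, screen_proteome
from .errors import ConfigError, InputError
from .groups import (
    CandidateRecord,
    collapse_groups,
    exclude_shared_outside,
    filter_min_species,
    summarize_groups,
)
from .hits import normalize, parse_hits, read_self_scores, sort_and_cap
from .phylo import (
    ConfirmationResult,
    ConfirmStatus,
    collapse_low_support,
    detect_donor_clade,
    midpoint_root,
    parse_tree,
)
from .simulate import SimulationConfig, read_truth, write_bundle
from .taxonomy import LineageConfig, LineageLabel, classify, load_taxonomy

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run (key = value file format)."""

    taxonomy: str = "taxonomy.tsv"
    taxonomy_dialect: str = "tsv3"
    taxon_map: str = "taxon_map.tsv"
    hits_dir: str = "hits"
    trees_dir: str = "trees"
    out_dir: str = "out"
    self_scores: str = ""  # optional sidecar TSV
    truth: str = ""  # optional planted truth for recovery metrics

    recipient_taxid: int = 4892
    group_taxid: int = 4751
    bacteria_taxid: int = 2
    ai_threshold: float = 0.1
    max_total: int = 10000
    max_per_taxon: int = 5
    tree_set_n: int = 200
    evalue_cutoff: float = 1e-10
    min_trimmed_length: int = 150
    collapse_support: float = 95.0
    confirm_support: float = 90.0
    min_species: int = 2
    outside_species: str = ""  # comma-separated roster of non-recipient yeasts
    seed: int = 0  # used by `simulate` only

    # provenance note: the external phmmer searches the screen consumes are
    # expected to have been run with --F1 1e-5 --F2 1e-7 --F3 1e-10
    phmmer_accel = "--F1 1e-5 --F2 1e-7 --F3 1e-10"

    def lineages(self) -> LineageConfig:
        return LineageConfig(
            recipient_taxid=self.recipient_taxid,
            group_taxid=self.group_taxid,
            bacteria_taxid=self.bacteria_taxid,
            candidate_threshold=self.ai_threshold,
        )

    def outside_roster(self) -> set[str]:
        return {s.strip() for s in self.outside_species.split(",") if s.strip()}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
            ftype = fields[key].type
            try:
                if ftype == "int":
                    kwargs[key] = int(value)
                elif ftype == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_taxon_map(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            target, taxid = line.rstrip("\n").split("\t")
            out[target] = int(taxid)
    return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _config_echo(cfg: RunConfig) -> dict:
    echo = asdict(cfg)
    echo["version"] = __version__
    echo["phmmer_accel"] = cfg.phmmer_accel
    return echo


# ---------------------------------------------------------------------------
# stage 1: alien-index screen


def run_screen(cfg: RunConfig) -> dict[str, list[AIResult]]:
    """Screen every species' hit tables; write per-species AI TSVs + summary."""
    hits_dir = Path(cfg.hits_dir)
    files = sorted(hits_dir.glob("hits_*.tsv"))
    if not files:
        raise InputError(f"no hit tables (hits_*.tsv) found in {hits_dir}")
    db = load_taxonomy(cfg.taxonomy, dialect=cfg.taxonomy_dialect)
    lineages = cfg.lineages()
    lineages.validate_against(db)
    self_scores = read_self_scores(cfg.self_scores) if cfg.self_scores else {}

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[AIResult]] = {}
    for path in files:
        species = path.stem[len("hits_"):]
        tables = parse_hits(path, dialect="generic_tsv", species=species)
        prepared = [
            sort_and_cap(
                normalize(t, self_scores.get(t.query_id)),
                max_total=cfg.max_total,
                max_per_taxon=cfg.max_per_taxon,
            )
            for t in tables
        ]
        results[species] = screen_proteome(prepared, db, lineages)
        with open(out_dir / f"ai_{species}.tsv", "w", encoding="utf-8") as fh:
            fh.write("query_id\tnbsO\tnbsG\tai\tis_candidate\tbest_outside_target\tbest_outside_taxid\n")
            for r in results[species]:
                fh.write(
                    f"{r.query_id}\t{r.nbsO:.6f}\t{r.nbsG:.6f}\t{r.ai:.6f}\t"
                    f"{int(r.is_candidate)}\t{r.best_outside_target or ''}\t"
                    f"{r.best_outside_taxid if r.best_outside_taxid is not None else ''}\n"
                )

    summary = {
        "config": _config_echo(cfg),
        "per_species": {
            sp: {
                "n_queries": len(rs),
                "n_candidates": sum(r.is_candidate for r in rs),
            }
            for sp, rs in results.items()
        },
        "n_queries_total": sum(len(rs) for rs in results.values()),
        "n_candidates_total": sum(
            sum(r.is_candidate for r in rs) for rs in results.values()
        ),
    }
    _json_dump(summary, out_dir / "screen_summary.json")
    return results


def _read_ai_reports(out_dir: Path) -> dict[str, list[dict]]:
    reports: dict[str, list[dict]] = {}
    for path in sorted(out_dir.glob("ai_*.tsv")):
        species = path.stem[len("ai_"):]
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
        reports[species] = rows
    if not reports:
        raise InputError(f"no AI reports (ai_*.tsv) found in {out_dir}; run the screen first")
    return reports


# ---------------------------------------------------------------------------
# stage 2: phylogenetic confirmation


def run_confirm(cfg: RunConfig) -> dict[str, ConfirmationResult]:
    """Confirm candidates on their gene trees; write the confirmation report.

    For each candidate the tree ``<trees_dir>/<query_id>.nwk`` is midpoint
    rooted, collapsed at the configured support, and inspected for a
    bacterial donor clade.  A missing tree yields status ``no_tree``.
    """
    out_dir = Path(cfg.out_dir)
    db = load_taxonomy(cfg.taxonomy, dialect=cfg.taxonomy_dialect)
    lineages = cfg.lineages()
    tmap = _read_taxon_map(cfg.taxon_map)
    trees_dir = Path(cfg.trees_dir)
    reports = _read_ai_reports(out_dir)

    results: dict[str, ConfirmationResult] = {}
    leafsets: dict[str, list[str]] = {}
    species_of_query: dict[str, str] = {}
    for species, rows in reports.items():
        for row in rows:
            if row["is_candidate"] != "1":
                continue
            qid = row["query_id"]
            species_of_query[qid] = species
            tree_path = trees_dir / f"{qid}.nwk"
            if not tree_path.exists():
                results[qid] = ConfirmationResult(qid, ConfirmStatus.NO_TREE)
                leafsets[qid] = []
                continue
            tree = parse_tree(tree_path.read_text(encoding="utf-8"))
            tree = midpoint_root(tree)
            tree = collapse_low_support(tree, min_support=cfg.collapse_support)
            recipients = {
                l
                for l in tree.leaf_labels()
                if l in tmap
                and classify(db, tmap[l], lineages) is LineageLabel.RECIPIENT
            }
            res = detect_donor_clade(
                tree, recipients, db, lineages, tmap,
                support_threshold=cfg.confirm_support,
            )
            results[qid] = replace(res, query_id=qid)
            leafsets[qid] = sorted(tree.leaf_labels())

    with open(out_dir / "confirm.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "query_id\tspecies\tstatus\tclade_support\tdonor_taxid\tdonor_name\t"
            "n_recipient_leaves\tn_bacterial_leaves_in_clade\n"
        )
        for qid in sorted(results):
            r = results[qid]
            fh.write(
                f"{qid}\t{species_of_query[qid]}\t{r.status}\t"
                f"{r.clade_support if r.clade_support is not None else ''}\t"
                f"{r.donor_taxid if r.donor_taxid is not None else ''}\t"
                f"{r.donor_name or ''}\t{r.n_recipient_leaves}\t{r.n_bacterial_leaves_in_clade}\n"
            )
    _json_dump(leafsets, out_dir / "confirm_leafsets.json")

    histogram: dict[str, int] = {}
    confirmed_per_species: dict[str, int] = {}
    for qid, r in results.items():
        histogram[str(r.status)] = histogram.get(str(r.status), 0) + 1
        if r.status is ConfirmStatus.CONFIRMED:
            sp = species_of_query[qid]
            confirmed_per_species[sp] = confirmed_per_species.get(sp, 0) + 1
    summary = {
        "config": _config_echo(cfg),
        "n_candidates": len(results),
        "status_histogram": dict(sorted(histogram.items())),
        "confirmed_trees_per_species": dict(sorted(confirmed_per_species.items())),
    }
    _json_dump(summary, out_dir / "confirm_summary.json")
    return results


# ---------------------------------------------------------------------------
# stage 3: ortholog groups


def run_group(cfg: RunConfig):
    """Collapse confirmed candidates into ortholog groups; write reports."""
    out_dir = Path(cfg.out_dir)
    confirm_path = out_dir / "confirm.tsv"
    if not confirm_path.exists():
        raise InputError(f"{confirm_path} not found; run the confirmation stage first")
    db = load_taxonomy(cfg.taxonomy, dialect=cfg.taxonomy_dialect)
    leafsets = json.loads((out_dir / "confirm_leafsets.json").read_text(encoding="utf-8"))
    recipient_species = {
        p.stem[len("ai_"):] for p in out_dir.glob("ai_*.tsv")
    }

    records = []
    with open(confirm_path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            if row["status"] != str(ConfirmStatus.CONFIRMED):
                continue
            records.append(
                CandidateRecord(
                    query_id=row["query_id"],
                    species=row["species"],
                    confirmed=True,
                    tree_leafset=frozenset(leafsets[row["query_id"]]),
                    donor_taxid=int(row["donor_taxid"]) if row["donor_taxid"] else None,
                )
            )
    records = exclude_shared_outside(records, cfg.outside_roster())
    groups = collapse_groups(records, recipient_species, db=db)
    groups = filter_min_species(groups, min_species=cfg.min_species,
                                recipient_species=recipient_species)

    with open(out_dir / "groups.tsv", "w", encoding="utf-8") as fh:
        fh.write("group_id\tspecies\tquery_ids\tn_paralogs\tdonor_taxid\tdonor_name\n")
        for g in groups:
            for sp in sorted(g.members):
                fh.write(
                    f"{g.group_id}\t{sp}\t{','.join(sorted(g.members[sp]))}\t"
                    f"{len(g.members[sp])}\t"
                    f"{g.donor_taxid if g.donor_taxid is not None else ''}\t"
                    f"{db.name(g.donor_taxid) if g.donor_taxid in db else ''}\n"
                )
    report = summarize_groups(groups, db)
    report["config"] = _config_echo(cfg)
    _json_dump(report, out_dir / "groups_summary.json")
    return groups


# ---------------------------------------------------------------------------
# composition


def run_all(cfg: RunConfig) -> dict:
    """Screen, confirm, group; emit recovery metrics when truth is available."""
    screen = run_screen(cfg)
    run_confirm(cfg)
    groups = run_group(cfg)

    out = {
        "n_queries": sum(len(rs) for rs in screen.values()),
        "n_candidates": sum(sum(r.is_candidate for r in rs) for rs in screen.values()),
        "n_groups": len(groups),
    }
    truth_path = Path(cfg.truth) if cfg.truth else None
    if truth_path and truth_path.exists():
        truth = read_truth(truth_path).by_query()
        tp = fp = tn = fn = 0
        for rs in screen.values():
            for r in rs:
                planted = truth[r.query_id].is_hgt
                if r.is_candidate and planted:
                    tp += 1
                elif r.is_candidate:
                    fp += 1
                elif planted:
                    fn += 1
                else:
                    tn += 1
        n_planted = len(read_truth(truth_path).planted_families(cfg.min_species))
        out["recovery"] = {
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "n_planted_families": n_planted,
            "n_recovered_groups": len(groups),
        }
    out["config"] = _config_echo(cfg)
    _json_dump(out, Path(cfg.out_dir) / "run_summary.json")
    return out


def simulate(sim_cfg: SimulationConfig, outdir: str | Path) -> RunConfig:
    """Write a synthetic input bundle and a ready-to-run configuration file."""
    outdir = Path(outdir)
    write_bundle(sim_cfg, outdir)
    run_cfg = RunConfig(
        taxonomy=str(outdir / "taxonomy.tsv"),
        taxon_map=str(outdir / "taxon_map.tsv"),
        hits_dir=str(outdir / "hits"),
        trees_dir=str(outdir / "trees"),
        out_dir=str(outdir / "out"),
        truth=str(outdir / "truth.tsv"),
        seed=sim_cfg.seed,
    )
    run_cfg.to_file(outdir / "run.cfg")
    return run_cfg
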
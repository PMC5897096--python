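# Methods

## Model and assumptions

The screen is a three-stage decision procedure over precomputed
homology evidence; it infers transfer, it does not infer trees or
alignments.

**Stage 1 — alien index.**  For a query with self-score *S* (the
bitscore of the query aligned to itself) every hit's normalized
bitscore is nbs = best-single-domain-bitscore / *S*.  Using the best
*domain* score makes the statistic robust to spurious multi-domain
stacking in the full-sequence score; when only full-sequence scores are
available (HMMER tblout lacks per-domain rows but carries the
best-domain column, which we use; the generic TSV carries both) the
parser degrades gracefully and logs it.  AI = nbsO − nbsG contrasts the
best hit outside the GROUP lineage with the best hit inside it,
skipping the RECIPIENT lineage entirely — including the query's own
self-hit, which is always a recipient hit.  A lineage with no hits
contributes 0, which keeps AI inside [−1, +1] and is reported alongside
explicit `has_outside_hit`/`has_group_hit` flags so AI = 0 from balance
is distinguishable from AI = 0 from absence.

The screen assumes the searched database is taxon-labelled and that the
query is present in it (for the self-hit); a self-score sidecar file
covers runs where it is not.

**Stage 2 — phylogenetic confirmation.**  Gene trees arrive as newick
with supports as internal node labels (fractions are auto-rescaled to
0–100 when every support is ≤ 1).  Trees are midpoint rooted, edges
with support < 95 are collapsed into polytomies, and the walk from the
MRCA of the recipient leaves to the first clade containing any
non-recipient leaf decides the outcome: confirmed only if every such
leaf is bacterial (by taxonomic descent from the superkingdom Bacteria
node, never by name matching) and the clade's subtending edge has
support strictly > 90.  Collapsing first makes the bacterial-purity
condition stricter, since a polytomy pools leaves that weakly supported
edges would otherwise separate.  "Cluster with a bacterial lineage" is
operationalized as this smallest-enclosing-clade rule; a sister-group
reading is a special case of it.  The failure modes are reported
distinctly: `unconfirmed_low_support`, `unconfirmed_non_bacterial`
(recipients monophyletic but beside non-bacteria), and
`unconfirmed_scattered` (the recipient MRCA itself already contains
non-bacterial leaves).

**Stage 3 — ortholog groups.**  Confirmed candidates are nodes of a
graph with an edge wherever two candidates' tree leaf sets share at
least one recipient candidate sequence; connected components are the
ortholog groups.  This operationalizes "replicate phylogenies": a tree
seeded from species A's copy of a xenolog recovers species B's copy
among its top hits, and vice versa, so replicates overlap.  The overlap
threshold (default ≥ 1 shared sequence) is configurable.  Within a
group, several queries from one species are paralogs and are counted,
not split.  Groups must span ≥ 2 recipient species — applied to groups,
not records, so paralog-rich single-species families drop out — and
groups sharing leaves with a declared non-recipient relative are
excluded before grouping.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| recipient / group taxid | 4892 / 4751 | NCBI taxid | Saccharomycetales nested in Fungi |
| AI candidate threshold | 0.1 (strict >) | dimensionless | separates strong candidates from drift in the nbs scale |
| global / per-taxon hit caps | 10,000 / 5 | hits | bounds redundancy from over-sequenced taxa |
| tree-set size / E-value cutoff | 200 / 1e-10 (strict <) | hits | tractable, high-confidence tree sets |
| trimmed-length cutoff | 150 (strict <) excluded | residues | short trimmed alignments carry little signal |
| collapse support | 95 (strict <) collapsed | 0–100 | removes weakly supported resolution before inspection |
| confirmation support | 90 (strict >) | 0–100 | bootstrap level required of the donor clade |
| min recipient species | 2 | species | a transfer retained by one species only is indistinguishable from contamination |

All threshold comparisons are strict exactly as listed; boundary tests
pin each one (AI 0.1 is not a candidate; support 95 is retained;
support 90 is rejected; length 150 is retained).

## Numerical and determinism choices

* Hit ordering is the total order (nbs desc, E-value asc, target id
  asc); the caps are enforced in a single descending scan bounded by
  the global cap.  Output row order is byte-stable across runs.
* nbs values exceeding 1 by more than 1e-9 are clamped to 1 with a
  warning and counted; smaller floating overshoots clamp silently.
* Midpoint rooting: the diameter pair is found exhaustively; ties break
  to the lexicographically smallest endpoint-label pair; a midpoint
  landing exactly on a node (tolerance 1e-12 relative) roots at that
  node.  Rerooting moves each edge's support with the physical edge, so
  bipartition supports survive the root change; pairwise leaf distances
  are preserved to 1e-9.
* Collapsing adds the contracted edge's length to its children,
  preserving root-to-leaf distances; edges with *absent* support are
  retained (absence is unknown, not zero — leaf edges and roots carry
  no bootstrap values).
* Group ids are a SHA-1 digest of the sorted member query ids, so they
  are invariant to record input order.
* Unresolvable taxids drop the affected hit with a logged warning by
  default (taxonomy dumps and hit tables drift out of sync); a strict
  mode raises instead.

## The synthetic generator

The generator emulates the screen's input statistics, not sequences:
bitscore(d) = S·exp(−λ·d) + N(0, σ), clamped at 0, where *d* is the
query–target divergence.  Vertical genes put their nearest non-self
homolog in Fungi at divergence 0.1 and all bacteria at 2.0; planted
transfers invert this, with the donor family (an Acetobacteraceae-like
taxon) at 0.1.  With λ = 1 this yields |AI| ≈ 0.77 for every gene at
σ = 0, so planted labels are perfectly recoverable at the 0.1
threshold; rising σ degrades recovery.  Defaults are 6 recipient
species × 200 genes, 10% planted transfers, self-scores uniform in
150–800 bits, σ = 0, and 7 hits per taxon so the per-taxon cap is
genuinely exercised.  Planted families span all recipient species,
giving the grouping stage a known answer (group count = planted family
count).  A configurable fraction of trees receives low support (80) on
the uniting edge to exercise the unconfirmed statuses.

What the generator does **not** emulate: sequence-level evolution
(no substitution models, no alignments), composition- or length-driven
biases of real bitscores, database sampling bias across taxa,
incomplete-lineage sorting or contamination, and gene trees discordant
with the species tree.  Passing tests therefore demonstrate the
correctness of the decision logic under the assumed geometry, not the
field performance of the screen on real proteomes.

Problem sizes in the test suite (hundreds of random instances per
oracle check, and a 6 × 200-gene end-to-end recovery run) were chosen
as the smallest sizes that exercise every rule including both caps.

## Known limitations

* The per-domain nbs is exact only with domain-level input
  (domtblout or the generic TSV); plain tblout provides HMMER's own
  best-domain column, which is equivalent for phmmer output.
* Whether the "top ≤ 10,000" cap applies before or after the per-taxon
  cap is ambiguous in the field; the single-scan semantics here is one
  consistent reading and is what the oracle tests pin.
* The E-value used by tree-set selection is the full-sequence value.
* Confirmation runs on the collapsed tree; evaluating the 90 rule on
  the uncollapsed tree can accept clades this implementation rejects.
* The AU topology test itself is external: this package only emits the
  monophyly-constraint newick it needs.
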
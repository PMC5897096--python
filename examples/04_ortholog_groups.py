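"""Collapse replicate phylogenies into ortholog groups.

Four confirmed candidate trees from three species describe the same
xenolog (their leaf sets overlap through shared recipient sequences),
including a within-species duplication — they collapse into a single
ortholog group with a paralog count of 2 for species ws1.  A fifth,
single-species record is dropped by the two-species rule.
"""

from alienscreen import (
    CandidateRecord,
    collapse_groups,
    filter_min_species,
    summarize_groups,
)

roster = {"ws1", "ws2", "ws3"}
shared = {"ws1_g007", "ws1_g031", "ws2_g007", "ws3_g007", "acetobacter_1"}
records = [
    CandidateRecord("ws1_g007", "ws1", True, frozenset(shared), 435),
    CandidateRecord("ws1_g031", "ws1", True, frozenset(shared), 435),  # paralog
    CandidateRecord("ws2_g007", "ws2", True, frozenset(shared), 435),
    CandidateRecord("ws3_g007", "ws3", True, frozenset(shared), 435),
    CandidateRecord("ws2_g099", "ws2", True, frozenset({"ws2_g099", "bact_x"}), 436),
]

groups = filter_min_species(collapse_groups(records, roster), min_species=2)
report = summarize_groups(groups)
print(f"records in        : {len(records)}")
print(f"groups out (≥2 sp): {report['n_groups']}")
for g in report["groups"]:
    print(f"  {g['group_id']}: {g['n_species']} species, "
          f"paralogs {g['paralogs_per_species']}, donor taxid {g['donor_taxid']}")
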
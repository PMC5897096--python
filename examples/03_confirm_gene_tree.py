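"""Confirm a candidate on its gene tree and emit a constraint tree.

The tree nests two recipient yeast sequences inside an Acetobacteraceae
clade with support 98 on the uniting edge: after midpoint rooting and
collapsing branches below 95, the donor clade is detected with support
above the 90 threshold, so the candidate is confirmed.  The monophyly
constraint tree is what an external AU-test workflow would consume.
"""

import io

from alienscreen import (
    LineageConfig,
    LineageLabel,
    collapse_low_support,
    detect_donor_clade,
    load_taxonomy,
    make_constraint_tree,
    midpoint_root,
    parse_tree,
)

TAXONOMY = """taxid\tparent\tname
1\t1\troot
2\t1\tBacteria
435\t2\tAcetobacteraceae
4751\t1\tFungi
147538\t4751\tPezizomycotina
4892\t4751\tSaccharomycetales
1003835\t4892\tStarmerella bombicola
1061180\t4892\tWickerhamiella domercqiae
"""
db = load_taxonomy(io.StringIO(TAXONOMY))
lin = LineageConfig()
taxon_map = {"r1": 1003835, "r2": 1061180, "b1": 435, "b2": 435,
             "f1": 147538, "f2": 147538}

newick = "(((r1:0.1,r2:0.1)97:0.2,(b1:0.1,b2:0.1)93:0.2)98:1.0,(f1:0.3,f2:0.3)99:1.0);"
tree = collapse_low_support(midpoint_root(parse_tree(newick)), min_support=95)
result = detect_donor_clade(tree, {"r1", "r2"}, db, lin, taxon_map,
                            support_threshold=90)
print(f"status        : {result.status}")
print(f"clade support : {result.clade_support}")
print(f"donor lineage : {result.donor_name} (taxid {result.donor_taxid})")

leaves = [("r1", LineageLabel.RECIPIENT), ("r2", LineageLabel.RECIPIENT),
          ("b1", LineageLabel.OUTSIDE), ("b2", LineageLabel.OUTSIDE)]
print(f"constraint    : {make_constraint_tree(leaves)}")
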
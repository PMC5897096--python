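"""Compute the alien index for a single query protein.

A query with self-score 200 bits has its best bacterial hit at 150 bits
(nbsO = 0.75) and its best non-recipient fungal hit at 100 bits
(nbsG = 0.50), so AI = 0.25 — above the 0.1 threshold, a strong HGT
candidate.
"""

import io

from alienscreen import (
    Hit,
    HitTable,
    LineageConfig,
    call_candidate,
    compute_ai,
    load_taxonomy,
    normalize,
    sort_and_cap,
)

TAXONOMY = """taxid\tparent\tname
1\t1\troot
2\t1\tBacteria
435\t2\tAcetobacteraceae
4751\t1\tFungi
147538\t4751\tPezizomycotina
4892\t4751\tSaccharomycetales
1003835\t4892\tStarmerella bombicola
"""

db = load_taxonomy(io.StringIO(TAXONOMY), dialect="tsv3")
lin = LineageConfig()  # recipient 4892, group 4751, AI threshold 0.1

table = HitTable(
    query_id="Adh1_like",
    query_species="St_bombicola",
    self_score=200.0,
    hits=[
        Hit("Adh1_like", "acetobacter_adh", 435, 150.0, 150.0, 1e-60),
        Hit("Adh1_like", "pezizomycotina_adh", 147538, 100.0, 100.0, 1e-35),
        Hit("Adh1_like", "Adh1_like", 1003835, 200.0, 200.0, 1e-90),  # self-hit
    ],
)

result = call_candidate(compute_ai(sort_and_cap(normalize(table)), db, lin), lin)
print(f"query          : {result.query_id}")
print(f"nbsO (outside) : {result.nbsO:.2f}   best hit {result.best_outside_target}")
print(f"nbsG (group)   : {result.nbsG:.2f}")
print(f"AI = nbsO-nbsG : {result.ai:.2f}")
print(f"strong candidate (AI > 0.1): {result.is_candidate}")
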
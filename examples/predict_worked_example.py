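"""Rank candidate body fluids for peptidoglycan recognition protein 1.

Loads the packaged worked example — PGRP-1 (UniProt O75594) and its 23
confidence-weighted PPI neighbors — and scores each of the 11 body fluids
by the weighted neighbor vote: the score of fluid j is the sum of the
interaction confidences of neighbors annotated to fluid j. PGRP-1 is truly
detected in plasma/serum, saliva and urine, and those three fluids come out
on top.
"""

import fluidvote as fv

vocab = fv.default_vocabulary()
net, ann = fv.datasets.pgrp1_example(vocab)

scores = fv.score_query(fv.datasets.PGRP1, net, ann, vocab)
pred = fv.rank_fluids(scores, vocab, query=fv.datasets.PGRP1)

print(f"query: {pred.query}  ({net.n_nodes} proteins, {net.n_edges} edges)")
print(f"true fluids: {sorted(ann.labels(pred.query))}")
print("rank  fluid                          score")
for rank, (fluid, score) in enumerate(zip(pred.order, pred.sorted_scores), 1):
    marker = " *" if fluid in ann.labels(pred.query) else ""
    print(f"{rank:>4}  {fv.default_vocabulary().name_of(fluid):<30} {score:.3f}{marker}")
print("(* = a fluid the protein is actually secreted into; the score is the")
print(" confidence-weighted count of neighbors annotated to that fluid)")
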
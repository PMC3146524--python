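"""Jackknife evaluation on a synthetic planted-homophily benchmark.

Generates a 150-protein network in which label-sharing proteins interact
with probability 0.3 (and label-disjoint ones not at all), then leaves each
protein out in turn, predicts its fluids from its neighbors, and summarizes
the ranking quality: order accuracies ACC_j, the average label count N-bar,
the random-guess baseline N-bar/F, k = floor(N-bar)+1, and the top-k
coverage likelihood L_k.
"""

import fluidvote as fv

cfg = fv.SyntheticConfig(n_proteins=150, p_in=0.3, p_out=0.0, seed=7)
bench = fv.generate_benchmark(cfg)
report = fv.evaluate(bench.network, bench.annotations, bench.vocab)

print(f"proteins: {report.n_evaluated}  edges: {bench.network.n_edges}  "
      f"unpredictable: {report.n_unpredictable}")
print(f"average fluids per protein N-bar = {report.avg_labels:.4f} "
      f"(reported as {report.avg_labels_2dp})")
print(f"random-guess baseline = {report.random_baseline_pct:.2f}%")
for j, acc in enumerate(report.order_accuracy, 1):
    print(f"  ACC_{j:<2} = {100 * acc:6.2f}%")
print(f"k = {report.k}  ->  coverage L_{report.k} = {report.coverage:.4f}")
print("(ACC_1 far above the baseline and a high L_k mean the planted")
print(" co-secretion structure is recovered by the neighbor vote)")
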
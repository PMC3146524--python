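"""Generate a synthetic benchmark, write it as TSVs, and read it back.

Shows the homophily dial: with planted structure (label-sharing pairs wired
preferentially) the first-order accuracy is near 1; in the null model (same
edge probability and confidence range for every pair) it falls to the
random-guess rate N-bar/F.
"""

import tempfile
from pathlib import Path

import fluidvote as fv

out = Path(tempfile.mkdtemp()) / "bench"

planted = fv.SyntheticConfig(n_proteins=150, p_in=0.3, p_out=0.0, seed=2)
null = fv.SyntheticConfig(n_proteins=150, p_in=0.1, p_out=0.1,
                          conf_in=(0.15, 1.0), conf_out=(0.15, 1.0), seed=2)

for name, cfg in [("planted", planted), ("null", null)]:
    bench = fv.generate_benchmark(cfg)
    fv.write_network(bench.network, f"{out}.{name}.network.tsv")
    fv.write_annotations(bench.annotations, f"{out}.{name}.labels.tsv")
    # round-trip through the TSV dialects before evaluating
    net = fv.read_network(f"{out}.{name}.network.tsv")
    ann = fv.read_annotations(f"{out}.{name}.labels.tsv")
    rep = fv.evaluate(net, ann, bench.vocab)
    print(f"{name:>8}: {net.n_edges:5d} edges  ACC_1 = {rep.order_accuracy[0]:.3f}  "
          f"baseline = {rep.random_baseline_pct / 100:.3f}  L_{rep.k} = {rep.coverage:.3f}")
print("(planted ACC_1 >> baseline; null ACC_1 ~ baseline: the predictor only")
print(" works insofar as interacting proteins really share body fluids)")
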
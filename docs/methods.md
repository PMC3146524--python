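# Methods

## Model

`fluidvote` scores candidate body fluids for a query protein by a weighted
guilt-by-association vote over its direct PPI neighbors. Writing
$a_{tj}\in\{0,1\}$ for "protein $t$ is secreted into fluid $j$" and
$w(q,t)\in(0,1]$ for the interaction confidence of the pair $(q,t)$ — 0
for non-interacting pairs and for the diagonal, since a protein does not
interact with itself — the score is

$$s_{qj}=\sum_t w(q,t)\,a_{tj},\qquad S=WA .$$

Two signals drive the score upward: more neighbors in fluid $j$, and more
confident interactions with them. Scores are raw confidence sums, not
probabilities: ranking is scale-invariant, and the method makes only
ordinal claims. The prediction for a query is the full permutation of the
fluid vocabulary in descending score order (1st-order fluid = argmax). The
method is strictly one-hop: no propagation beyond direct neighbors.

Assumptions worth stating explicitly:

- **Homophily.** Interacting secreted proteins tend to share body fluids.
  The null-model experiment (below) shows the method collapses to random
  guessing when this fails.
- **Annotated neighborhood.** A query with no annotated neighbor has an
  all-zero score vector; it is flagged `predictable=False` rather than
  being assigned an arbitrary fluid.
- **Static, curated inputs.** Identifier mapping between databases and
  confidence recalibration are out of scope; edge weights are consumed as
  given (internally normalized to the 0–1 scale).

## Evaluation

Every protein in the network is left out in turn and predicted from the
rest (jackknife). Because the confidence-matrix diagonal is zero, a
protein's own annotation cannot leak into its score, so the leave-one-out
prediction coincides with direct prediction; the exclusion is applied
anyway for contract clarity, and no retraining is involved.

- $\mathrm{ACC}_j$ = (#proteins whose $j$-th ranked fluid is a true fluid)
  / $n$. By default $n$ counts *all* network proteins, so unpredictable
  ones can only fail — the denominator is the total network size. The
  `drop_unpredictable` option removes them instead.
- $\bar N$ = mean label count. Since each true fluid occupies exactly one
  rank of a full permutation, $\sum_j \mathrm{ACC}_j = \bar N$ exactly for
  the proteins that receive rankings; `evaluate()` asserts the equivalent
  integer identity (sum of rank hits = sum of label counts over predictable
  proteins) on every run.
- Random baseline = $100\,\bar N/F\,\%$. Reporting convention: $\bar N$ is
  carried at full precision *and* rounded to 2 decimals, and the baseline
  and $k$ are computed from the 2-decimal value — with the packaged census
  this gives 29.36% rather than the 29.35% full precision would produce.
  Both $\bar N$ values appear in the report.
- $k=\lfloor\bar N\rfloor+1$. An alternative reading, the smallest integer
  $\ge\bar N$, coincides with this for non-integer $\bar N$ and differs by
  one when $\bar N$ is an integer; the floor+1 rule is the default and the
  only one applied. $k$ is clamped to $F$.
- $L_k$ = fraction of proteins whose *entire* true-fluid set lies within
  their top-$k$ ranks. Proteins with more labels than $k$ necessarily
  fail; unpredictable proteins fail because their ranking is arbitrary.

**Ties.** Equal scores carry no preferred order. The default tie policy is
deterministic (ascending fluid number), chosen so that identical inputs
always produce identical outputs; a seeded random policy (`tie_policy=
"random"`) is available for the convention that ties should be shuffled.
With the default policy an all-zero score vector ranks fluids 1..F in
vocabulary order, but is flagged unpredictable.

**Numerics.** Plain double-precision accumulation. Per-query scoring sums
neighbors in sorted-id order; batch scoring uses the dense matrix product
$WA$ over the sorted annotated-protein list. The two routes agree entrywise
to < 1e-12 (enforced by tests against an independent loop-based oracle).

## Synthetic benchmarks

`SyntheticConfig` plants the homophily the method assumes: each protein
draws a label-set size from a categorical distribution over $1..F$
(default mass 0.34 on size 1, decaying to 0.005 at size 11, mean ≈ 2.9 —
echoing a secretome in which about a third of proteins occur in a single
fluid and few occur in many), then a uniform fluid subset of that size.
Each unordered pair is wired with probability `p_in` (default 0.3) if the
label sets intersect, `p_out` (default 0.02) otherwise, with edge
confidences uniform in `conf_in` = (0.4, 1.0) or `conf_out` = (0.15, 0.5)
— ranges that straddle the 0.15–0.53 span typical of medium-confidence
interaction scores. One seeded generator drives labels then edges, so a
config is bit-reproducible.

What the generator does *not* emulate: correlated per-fluid marginals (in
the real secretome plasma/serum dominates, covering 418 of 529 proteins;
generated fluids are exchangeable), degree heterogeneity (hubs), and
evidence-channel score structure. Passing tests on these benchmarks
therefore certify the *mechanics* — scoring, ranking, metrics — and the
homophily→accuracy response, not real-data accuracy levels.

Two standard conditions used by the acceptance tests, at $n=150$ over 20
seeds:

- **planted**: `p_in=0.3, p_out=0.0` — first-order accuracy ≥ 0.9 in at
  least 18/20 seeds;
- **null**: `p_in=p_out=0.1` *and equal confidence ranges* (0.15, 1.0) —
  mean first-order accuracy within 0.04 of the $\bar N/F$ baseline. The
  equal ranges matter: with `p_in=p_out` but the default asymmetric
  ranges, label-sharing edges still carry systematically larger weights
  and the vote retains homophily through the confidence channel alone
  (measured ACC₁ ≈ 0.54 vs baseline ≈ 0.26).

Under the null, edges and confidences are independent of labels, neighbor
label sets are exchangeable over fluids, so the top-ranked fluid is
uniform and independent of the query's true set, giving
$E[\mathrm{ACC}_1]=\bar N/F$ for predictable queries — the analytic anchor
for the calibration check.

## File dialects and conventions

- Network TSV: `protein_a  protein_b  confidence`; the unit scale and the
  0–1000 integer scale of raw STRING exports are both accepted
  (`score_scale=auto` infers the latter when any value exceeds 1).
  Duplicate/antiparallel edges merge keeping the maximum confidence
  (conservative: strongest evidence wins); self-loops are dropped with a
  warning, the node retained. Isolated nodes round-trip via `# node:`
  comment lines. Header lines are optional and auto-detected.
- Annotations TSV: `protein  fluids`, the second column a comma/semicolon
  list of type numbers or exact names; repeated protein rows merge by
  union. Identifiers are matched exactly (no isoform stripping).
- Reports are JSON and round-trip losslessly; predictions are 5-column
  TSVs with 6-decimal scores.

## Problem sizes

The test suite and acceptance checks run on the packaged 24-protein worked
example, random instances of up to 50 proteins for oracle-equivalence
checks (100 instances for the conservation identity), and 150-protein
synthetic benchmarks over 20 seeds for the planted/null experiments; the
whole suite completes in a few seconds.

## Known limitations

- One-hop only; a query two steps from any annotated protein is
  unpredictable even in a dense network.
- No score calibration: scores are comparable *within* a query's row, not
  across queries with different degrees.
- The packaged census supports the label-statistics arithmetic
  ($\bar N$, baseline, $k$) but not the jackknife on the original
  529-protein network, whose accuracy curve therefore cannot be reproduced
  here.
- Exact score ties between distinct fluids are resolved by a convention
  (fluid-number order or seeded shuffle), which can matter on very sparse
  neighborhoods.
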
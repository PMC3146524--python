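"""Jackknife evaluation of ranked body-fluid predictions.

Each annotated protein in the network is singled out in turn and predicted
from the remaining annotated proteins (leave-one-out). Because a protein
never interacts with itself, its own annotation cannot leak into its score,
so the jackknife prediction coincides with direct prediction — the exclusion
is applied anyway for contract clarity.

Metrics:

* order accuracy ACC_j — fraction of proteins whose j-th ranked fluid is one
  of their true fluids (each true fluid occupies exactly one rank, so the
  ACC_j sum over all ranks equals the average label count of the proteins
  that received a ranking);
* average label count N-bar — mean number of fluids per protein;
* random baseline — N-bar / F as a percentage, the success rate of guessing
  a fluid uniformly at random;
* k = floor(N-bar) + 1, the number of leading ranks worth inspecting;
* coverage likelihood L_k — fraction of proteins whose complete true-fluid
  set lies within their top-k ranked fluids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .scoring import (
    AnnotationTable,
    InteractionNetwork,
    RankedPrediction,
    rank_fluids,
    score_all,
)
from .vocabulary import FluidVocabulary


@dataclass(frozen=True)
class EvaluationReport:
    """Full jackknife evaluation summary."""

    order_accuracy: tuple[float, ...]
    n_evaluated: int
    n_unpredictable: int
    avg_labels: float          # full precision
    avg_labels_2dp: float      # the conventionally reported 2-decimal value
    random_baseline_pct: float  # 100 * avg_labels_2dp / F
    k: int
    coverage: float
    n_fluids: int
    tie_policy: str = "index"
    drop_unpredictable: bool = False

    def to_dict(self) -> dict:
        return {
            "order_accuracy": list(self.order_accuracy),
            "n_evaluated": self.n_evaluated,
            "n_unpredictable": self.n_unpredictable,
            "avg_labels": self.avg_labels,
            "avg_labels_2dp": self.avg_labels_2dp,
            "random_baseline_pct": self.random_baseline_pct,
            "k": self.k,
            "coverage": self.coverage,
            "n_fluids": self.n_fluids,
            "tie_policy": self.tie_policy,
            "drop_unpredictable": self.drop_unpredictable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            order_accuracy=tuple(d["order_accuracy"]),
            n_evaluated=int(d["n_evaluated"]),
            n_unpredictable=int(d["n_unpredictable"]),
            avg_labels=float(d["avg_labels"]),
            avg_labels_2dp=float(d["avg_labels_2dp"]),
            random_baseline_pct=float(d["random_baseline_pct"]),
            k=int(d["k"]),
            coverage=float(d["coverage"]),
            n_fluids=int(d["n_fluids"]),
            tie_policy=str(d.get("tie_policy", "index")),
            drop_unpredictable=bool(d.get("drop_unpredictable", False)),
        )


@dataclass(frozen=True)
class JackknifeResult:
    """Order accuracies plus the per-protein rankings behind them."""

    order_accuracy: tuple[float, ...]
    hit_counts: tuple[int, ...]  # integer numerators of the accuracies
    predictions: tuple[RankedPrediction, ...] = field(repr=False)
    n_evaluated: int = 0
    n_unpredictable: int = 0


def jackknife_predictions(
    net: InteractionNetwork,
    ann: AnnotationTable,
    vocab: FluidVocabulary,
    tie_policy: str = "index",
    seed: int | None = None,
) -> tuple[RankedPrediction, ...]:
    """Leave-one-out ranked prediction for every protein in the network.

    Every network node must be annotated. Node order is sorted, and with
    ``tie_policy='random'`` a single seeded generator is consumed in that
    order, so identical inputs and seed give identical predictions.
    """
    proteins = net.nodes
    if not proteins:
        raise ValueError("cannot evaluate an empty network")
    missing = [p for p in proteins if p not in ann]
    if missing:
        raise KeyError(
            f"{len(missing)} network protein(s) lack annotations, e.g. {missing[:5]}"
        )
    rng = np.random.default_rng(seed) if tie_policy == "random" else None
    # the diagonal of the confidence matrix is zero, so leaving protein p out
    # of its own scoring is automatic; score all rows in one matrix product
    sm = score_all(proteins, net, ann, vocab)
    return tuple(
        rank_fluids(sm.scores[i], vocab, tie_policy=tie_policy, rng=rng, query=p)
        for i, p in enumerate(proteins)
    )


def jackknife_order_accuracies(
    net: InteractionNetwork,
    ann: AnnotationTable,
    vocab: FluidVocabulary,
    tie_policy: str = "index",
    seed: int | None = None,
    drop_unpredictable: bool = False,
) -> JackknifeResult:
    """ACC_j for j = 1..F over the jackknifed network.

    By default unpredictable proteins (no annotated neighbor) stay in the
    denominator and fail at every order, since the denominator is the total
    number of proteins in the network; ``drop_unpredictable=True`` removes
    them instead.
    """
    preds = jackknife_predictions(net, ann, vocab, tie_policy, seed)
    counted = [p for p in preds if p.predictable] if drop_unpredictable else list(preds)
    if not counted:
        raise ValueError("no proteins left to evaluate")
    n = len(counted)
    hits = [0] * vocab.F
    for pred in counted:
        if not pred.predictable:
            continue  # fails at every order
        true = ann.labels(pred.query)
        for j, fluid in enumerate(pred.order):
            if fluid in true:
                hits[j] += 1
    n_unpredictable = sum(1 for p in preds if not p.predictable)
    # each true fluid occupies exactly one rank of a full permutation
    expected = sum(ann.m(p.query) for p in counted if p.predictable)
    assert sum(hits) == expected, "rank bookkeeping violated label conservation"
    return JackknifeResult(
        order_accuracy=tuple(h / n for h in hits),
        hit_counts=tuple(hits),
        predictions=preds,
        n_evaluated=n,
        n_unpredictable=n_unpredictable,
    )


def average_label_count(ann: AnnotationTable, proteins: Iterable[str]) -> float:
    """Mean number of fluids per protein over the given proteins."""
    proteins = list(proteins)
    if not proteins:
        raise ValueError("cannot average over an empty protein list")
    return sum(ann.m(p) for p in proteins) / len(proteins)


def random_baseline(avg_labels: float, F: int) -> float:
    """Success rate (percent) of a uniform random fluid guess: 100 * N-bar / F.

    Pass the conventionally rounded (2-decimal) average to reproduce reported
    baselines; the result is rounded to 2 decimals as well.
    """
    if F <= 0:
        raise ValueError("fluid count must be positive")
    if not 0 < avg_labels <= F:
        raise ValueError(f"average label count {avg_labels} outside (0, {F}]")
    return round(100.0 * avg_labels / F, 2)


def choose_k(avg_labels: float) -> int:
    """Number of leading ranks to inspect: floor(N-bar) + 1."""
    if avg_labels < 0:
        raise ValueError("average label count cannot be negative")
    return int(math.floor(avg_labels)) + 1


def coverage_likelihood(
    preds: Sequence[RankedPrediction], ann: AnnotationTable, k: int
) -> float:
    """Fraction of proteins whose full true-fluid set lies in their top k ranks.

    Proteins with more true fluids than k necessarily fail; unpredictable
    proteins fail because their ranking carries no information.
    """
    if not preds:
        raise ValueError("no predictions to evaluate")
    F = len(preds[0].order)
    if not 1 <= k <= F:
        raise ValueError(f"k={k} outside 1..{F}")
    covered = sum(
        1
        for p in preds
        if p.predictable and ann.labels(p.query) <= set(p.top(k))
    )
    return covered / len(preds)


def evaluate(
    net: InteractionNetwork,
    ann: AnnotationTable,
    vocab: FluidVocabulary,
    tie_policy: str = "index",
    seed: int | None = None,
    drop_unpredictable: bool = False,
) -> EvaluationReport:
    """Run the full jackknife evaluation and assemble a report.

    Computes the order accuracies, the average label count of the evaluated
    proteins, the random baseline, k, and the top-k coverage likelihood.
    """
    jk = jackknife_order_accuracies(
        net, ann, vocab, tie_policy, seed, drop_unpredictable
    )
    counted = (
        [p for p in jk.predictions if p.predictable]
        if drop_unpredictable
        else list(jk.predictions)
    )
    nbar = average_label_count(ann, [p.query for p in counted])
    nbar2 = round(nbar, 2)
    k = choose_k(nbar2)
    k = min(k, vocab.F)  # N-bar close to F would otherwise exceed the rank count
    coverage = coverage_likelihood(counted, ann, k)
    return EvaluationReport(
        order_accuracy=jk.order_accuracy,
        n_evaluated=jk.n_evaluated,
        n_unpredictable=jk.n_unpredictable,
        avg_labels=nbar,
        avg_labels_2dp=nbar2,
        random_baseline_pct=random_baseline(nbar2, vocab.F),
        k=k,
        coverage=coverage,
        n_fluids=vocab.F,
        tie_policy=tie_policy,
        drop_unpredictable=drop_unpredictable,
    )
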
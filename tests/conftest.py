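"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's scoring/evaluation code paths:
they work from raw (edge list, label dict) primitives with plain Python
loops, so they can certify the vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

import fluidvote as fv


@pytest.fixture(scope="session")
def vocab():
    return fv.default_vocabulary()


@pytest.fixture(scope="session")
def pgrp(vocab):
    """The packaged 24-protein / 23-edge worked-example star network."""
    return fv.datasets.pgrp1_example(vocab)


def oracle_scores(q, edges, labels, fluid_numbers):
    """Per-fluid confidence sums computed by a plain loop over the edge list."""
    s = {f: 0.0 for f in fluid_numbers}
    for a, b, w in edges:
        t = b if a == q else a if b == q else None
        if t is None or t == q or t not in labels:
            continue
        for f in labels[t]:
            s[f] += w
    return np.array([s[f] for f in fluid_numbers])


def oracle_ranking(q, edges, labels, fluid_numbers):
    """Descending-score fluid order with lowest-number tie-break."""
    s = oracle_scores(q, edges, labels, fluid_numbers)
    return [f for _, f in sorted(zip(-s, fluid_numbers))]


def oracle_order_accuracies(edges, labels, fluid_numbers):
    """Leave-one-out order accuracies via the loop-based oracle.

    Unpredictable proteins (all-zero scores) count in the denominator and
    miss at every order, mirroring the evaluator's default convention.
    """
    proteins = sorted(labels)
    F = len(fluid_numbers)
    hits = [0] * F
    for p in proteins:
        s = oracle_scores(p, edges, labels, fluid_numbers)
        if not s.any():
            continue
        order = oracle_ranking(p, edges, labels, fluid_numbers)
        for j, f in enumerate(order):
            if f in labels[p]:
                hits[j] += 1
    return [h / len(proteins) for h in hits]


def random_instance(seed, n=20, F=5, p_edge=0.3):
    """A random weighted labelled graph as raw primitives + package objects."""
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n)]
    fluid_numbers = list(range(1, F + 1))
    labels = {
        p: frozenset(
            rng.choice(fluid_numbers, size=rng.integers(1, F + 1), replace=False).tolist()
        )
        for p in proteins
    }
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((proteins[i], proteins[j], float(rng.uniform(0.05, 1.0))))
    net = fv.InteractionNetwork.from_edges(edges, nodes=proteins)
    ann = fv.AnnotationTable(labels)
    vocab = fv.FluidVocabulary(tuple((f, f"Fluid {f}") for f in fluid_numbers))
    return edges, labels, net, ann, vocab
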
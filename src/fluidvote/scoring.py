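"""Weighted-vote body-fluid scoring over a protein-protein interaction network.

The method rests on a single assumption: interacting secreted proteins tend
to be secreted into the same body fluids. The likelihood score of a query
protein q for fluid j is the sum of the interaction-confidence weights of
q's neighbors that are annotated to fluid j::

    s(q, j) = sum_{t in N(q), j in labels(t)} w(q, t)

i.e. a weighted vote of the one-hop neighborhood. Equivalently, the query x
annotated-protein confidence matrix multiplied by the protein x fluid 0/1
indicator matrix. Scores are raw confidence sums, not probabilities; ranking
fluids by descending score yields the ordered prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

from .vocabulary import FluidVocabulary


class AnnotationTable:
    """Protein -> set of body-fluid type numbers (multi-label annotations).

    Every annotated protein carries a nonempty label set. ``m(p)`` is the
    per-protein label count used by the average-label statistic.
    """

    def __init__(self, labels: Mapping[str, Iterable[int]]):
        table: dict[str, frozenset[int]] = {}
        for protein, fluids in labels.items():
            fset = frozenset(int(f) for f in fluids)
            if not fset:
                raise ValueError(f"protein {protein!r} has an empty fluid set")
            table[str(protein)] = fset
        self._labels = table

    def labels(self, protein: str) -> frozenset[int]:
        return self._labels[protein]

    def m(self, protein: str) -> int:
        """Number of fluids the protein is annotated to."""
        return len(self._labels[protein])

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self._labels))

    def __contains__(self, protein: str) -> bool:
        return protein in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.proteins)

    def items(self) -> Iterator[tuple[str, frozenset[int]]]:
        return ((p, self._labels[p]) for p in self.proteins)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationTable) and self._labels == other._labels


class InteractionNetwork:
    """Undirected, simple, confidence-weighted PPI graph.

    Edge weights are interaction confidences in (0, 1]. Absent pairs have
    implicit confidence 0 and are never stored; self-pairs are forbidden
    (a protein does not interact with itself in the network, so the diagonal
    of the confidence matrix is zero).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        net = cls()
        for node in nodes:
            net.add_node(node)
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    def add_node(self, protein: str) -> None:
        self._g.add_node(str(protein))

    def add_edge(self, a: str, b: str, confidence: float) -> None:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not allowed")
        confidence = float(confidence)
        if not 0.0 < confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside (0, 1] for edge {a}-{b}")
        self._g.add_edge(a, b, confidence=confidence)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def confidence(self, a: str, b: str) -> float:
        """Edge confidence, 0.0 for non-interacting pairs and self-pairs."""
        if a == b or not self._g.has_edge(a, b):
            return 0.0
        return self._g.edges[a, b]["confidence"]

    def neighbors(self, protein: str) -> tuple[str, ...]:
        if protein not in self._g:
            return ()
        return tuple(sorted(self._g.neighbors(protein)))

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, confidence) with a < b, sorted for reproducibility."""
        out = []
        for a, b, data in self._g.edges(data=True):
            a, b = (a, b) if a <= b else (b, a)
            out.append((a, b, data["confidence"]))
        return sorted(out)

    def graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, not a copy)."""
        return self._g


@dataclass(frozen=True)
class ScoreMatrix:
    """Query x fluid nonnegative likelihood scores."""

    queries: tuple[str, ...]
    vocab: FluidVocabulary
    scores: np.ndarray = field(repr=False)  # shape (len(queries), F)

    def row(self, query: str) -> np.ndarray:
        return self.scores[self.queries.index(query)]


@dataclass(frozen=True)
class RankedPrediction:
    """A full ranking of the fluid vocabulary for one query protein.

    ``order`` is a permutation of the fluid type numbers in descending score
    order; ``order[0]`` is the most likely (1st-order) fluid. A query with no
    annotated neighbor has an all-zero score vector and is flagged
    ``predictable=False``; its ranking carries no information.
    """

    query: str
    order: tuple[int, ...]
    sorted_scores: tuple[float, ...]
    predictable: bool

    def top(self, k: int) -> tuple[int, ...]:
        return self.order[:k]


def build_annotation_matrix(
    ann: AnnotationTable, proteins: Iterable[str], vocab: FluidVocabulary
) -> np.ndarray:
    """0/1 indicator matrix A with A[i, j] = 1 iff protein i carries fluid j.

    Rows follow the given protein order; columns follow the vocabulary order.
    Row sums equal the per-protein label counts m(p).
    """
    proteins = list(proteins)
    A = np.zeros((len(proteins), vocab.F), dtype=np.int8)
    for i, p in enumerate(proteins):
        if p not in ann:
            raise KeyError(f"protein {p!r} has no fluid annotation")
        for f in ann.labels(p):
            A[i, vocab.index_of(f)] = 1
    return A

def score_query(
    q: str,
    net: InteractionNetwork,
    ann: AnnotationTable,
    vocab: FluidVocabulary,
    exclude: frozenset[str] | set[str] | None = None,
) -> np.ndarray:
    """Score one query: per-fluid sums of neighbor confidences.

    Neighbors in ``exclude`` (and unannotated neighbors) contribute nothing.
    An isolated or fully excluded query yields the zero vector. Accumulation
    runs in sorted-neighbor order so results are bit-reproducible.
    """
    exclude = exclude or frozenset()
    scores = np.zeros(vocab.F, dtype=np.float64)
    for t in net.neighbors(q):
        if t in exclude or t == q or t not in ann:
            continue
        w = net.confidence(q, t)
        for f in ann.labels(t):
            scores[vocab.index_of(f)] += w
    return scores


def score_all(
    queries: Iterable[str],
    net: InteractionNetwork,
    ann: AnnotationTable,
    vocab: FluidVocabulary,
) -> ScoreMatrix:
    """Score many queries at once as a confidence x indicator matrix product.

    Row i of the result is the score vector of query i: W @ A, where W holds
    the query-to-annotated-protein confidences and A the 0/1 fluid indicators.
    Entrywise identical (to float associativity) to per-query accumulation.
    """
    queries = list(queries)
    if len(set(queries)) != len(queries):
        raise ValueError("duplicate query ids")
    targets = list(ann.proteins)
    target_idx = {t: j for j, t in enumerate(targets)}
    A = build_annotation_matrix(ann, targets, vocab).astype(np.float64)
    W = np.zeros((len(queries), len(targets)), dtype=np.float64)
    for i, q in enumerate(queries):
        for t in net.neighbors(q):
            if t == q or t not in ann:
                continue
            W[i, target_idx[t]] = net.confidence(q, t)
    S = W @ A
    return ScoreMatrix(queries=tuple(queries), vocab=vocab, scores=S)


def top_fluid(scores: np.ndarray, vocab: FluidVocabulary) -> int | None:
    """Fluid number with the maximum score; ``None`` if all scores are zero.

    Ties resolve to the lowest fluid number (the deterministic default
    policy); an all-zero vector is flagged rather than silently mapped to a
    fluid.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (vocab.F,):
        raise ValueError(f"expected score vector of length {vocab.F}")
    if not scores.any():
        return None
    return vocab.numbers[int(np.argmax(scores))]


def rank_fluids(
    scores: np.ndarray,
    vocab: FluidVocabulary,
    tie_policy: str = "index",
    rng: np.random.Generator | None = None,
    query: str = "",
) -> RankedPrediction:
    """Arrange all fluids of a score vector in descending order.

    tie_policy "index" (default) breaks exact ties by ascending fluid number,
    giving a unique, reproducible ranking; "random" shuffles tied groups with
    the supplied generator, matching the convention that equal scores carry
    no preferred order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (vocab.F,):
        raise ValueError(f"expected score vector of length {vocab.F}")
    if np.any(scores < 0):
        raise ValueError("scores must be nonnegative")
    if tie_policy == "index":
        tiebreak = np.arange(vocab.F)
    elif tie_policy == "random":
        if rng is None:
            raise ValueError("tie_policy='random' requires an rng")
        tiebreak = rng.permutation(vocab.F)
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    # lexsort: last key is primary; negate scores for descending order
    perm = np.lexsort((tiebreak, -scores))
    order = tuple(vocab.numbers[int(i)] for i in perm)
    return RankedPrediction(
        query=query,
        order=order,
        sorted_scores=tuple(float(scores[int(i)]) for i in perm),
        predictable=bool(scores.any()),
    )


def count_neighbors_with_any(
    q: str,
    net: InteractionNetwork,
    ann: AnnotationTable,
    fluids: Iterable[int],
) -> int:
    """Number of annotated neighbors of q whose label set meets ``fluids``."""
    fluids = frozenset(int(f) for f in fluids)
    return sum(
        1
        for t in net.neighbors(q)
        if t != q and t in ann and ann.labels(t) & fluids
    )
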
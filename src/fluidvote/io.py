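"""Readers and writers for the package's tab-separated file dialects.

Formats
-------
network
    3-column TSV ``protein_a  protein_b  confidence``. Confidences may be on
    the unit scale (floats in (0, 1], as in curated tables) or the raw
    STRING export scale (integers in (0, 1000]); ``score_scale`` selects the
    dialect, with ``auto`` inferring the 0-1000 scale when any value exceeds
    1. The internal canonical scale is always 0-1. Duplicate or antiparallel
    edges are merged keeping the maximum confidence; self-loops are dropped
    (the node is retained); both are logged as warnings.
annotations
    2-column TSV ``protein  fluids`` where the second column lists fluid
    type numbers or names separated by commas or semicolons. Duplicate
    protein rows are merged by set union.
vocabulary
    2-column TSV ``type_number  name`` (see :mod:`fluidvote.vocabulary`).
predictions
    5-column TSV ``query_id  order  fluid_number  fluid_name  score`` with
    scores at fixed 6-decimal precision, rows grouped by query in ascending
    rank order.
report
    JSON serialization of :class:`~fluidvote.evaluation.EvaluationReport`;
    round-trips losslessly.

Header lines are optional and auto-detected (a non-numeric confidence /
fluid field in the first row is treated as a header).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from .evaluation import EvaluationReport
from .scoring import AnnotationTable, InteractionNetwork, RankedPrediction
from .vocabulary import FluidVocabulary, default_vocabulary, read_fluid_vocab  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

_FLUID_SEP = re.compile(r"[,;]")


def _split_row(line: str) -> list[str]:
    fields = [f.strip() for f in line.rstrip("\n").split("\t")]
    if len(fields) < 2:
        fields = line.split()
    return [f for f in fields if f != ""]


def read_network(
    path: str | Path, score_scale: str = "auto"
) -> InteractionNetwork:
    """Read a weighted PPI edge list from a TSV file.

    ``score_scale``: ``unit`` (confidences already in (0, 1]), ``string1000``
    (divide by 1000, as in raw STRING ``protein.links`` exports), or ``auto``
    (infer ``string1000`` when any confidence exceeds 1).
    """
    if score_scale not in ("unit", "string1000", "auto"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    rows: list[tuple[int, str, str, float]] = []
    isolated: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            # "# node: X" marks an isolated node (edge lists cannot
            # otherwise represent nodes without edges); other comments skip
            stripped = line.lstrip("# \t")
            if stripped.startswith("node:"):
                isolated.append(stripped[len("node:"):].strip())
            continue
        fields = _split_row(line)
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: expected 3 columns "
                f"(protein_a, protein_b, confidence), got {len(fields)}"
            )
        try:
            conf = float(fields[2])
        except ValueError:
            if lineno == 1 and not rows:
                continue  # header line
            raise ValueError(
                f"{path}: line {lineno}: unparseable confidence {fields[2]!r}"
            ) from None
        rows.append((lineno, fields[0], fields[1], conf))

    scale = score_scale
    if scale == "auto":
        scale = "string1000" if any(c > 1.0 for _, _, _, c in rows) else "unit"
    scale_max = 1000.0 if scale == "string1000" else 1.0

    net = InteractionNetwork()
    merged: dict[tuple[str, str], float] = {}
    for lineno, a, b, conf in rows:
        if not 0.0 < conf <= scale_max:
            raise ValueError(
                f"{path}: line {lineno}: confidence {conf} outside (0, {scale_max:g}]"
            )
        conf /= scale_max
        if a == b:
            logger.warning("%s: line %d: dropping self-loop on %r", path, lineno, a)
            net.add_node(a)
            continue
        key = (a, b) if a <= b else (b, a)
        if key in merged:
            logger.warning(
                "%s: line %d: duplicate edge %s-%s, keeping maximum confidence",
                path, lineno, key[0], key[1],
            )
            merged[key] = max(merged[key], conf)
        else:
            merged[key] = conf
    for (a, b), conf in merged.items():
        net.add_edge(a, b, conf)
    for node in isolated:
        net.add_node(node)
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write an edge list TSV (unit-scale confidences, header included).

    Nodes without any edge are preserved as ``# node: <id>`` comment lines
    so the write/read round trip is identity on the node set.
    """
    connected = {n for a, b, _ in net.edges() for n in (a, b)}
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tconfidence\n")
        for node in net.nodes:
            if node not in connected:
                fh.write(f"# node: {node}\n")
        for a, b, conf in net.edges():
            fh.write(f"{a}\t{b}\t{conf:.6f}\n")


def read_annotations(
    path: str | Path, vocab: FluidVocabulary | None = None
) -> AnnotationTable:
    """Read a protein -> fluid-list TSV into an annotation table.

    Fluid tokens may be type numbers or exact fluid names, separated by
    commas or semicolons. Rows repeating a protein are merged by union.
    """
    vocab = vocab or default_vocabulary()
    labels: dict[str, set[int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t") if f.strip()]
        if len(fields) < 2:
            fields = line.split(None, 1)
        if len(fields) < 2:
            raise ValueError(
                f"{path}: line {lineno}: expected (protein, fluid list)"
            )
        protein, fluid_field = fields[0], "\t".join(fields[1:])
        tokens = [t.strip() for t in _FLUID_SEP.split(fluid_field) if t.strip()]
        if not tokens:
            raise ValueError(f"{path}: line {lineno}: empty fluid list for {protein!r}")
        fluids: set[int] = set()
        bad_token: str | None = None
        for token in tokens:
            try:
                fluids.add(vocab.resolve(token))
            except KeyError:
                bad_token = bad_token or token
        if bad_token is not None:
            # a first line where nothing resolves and nothing is numeric is
            # an (optional) header; numeric tokens always mean data
            if (lineno == 1 and not labels and not fluids
                    and not any(t.lstrip("-").isdigit() for t in tokens)):
                continue
            raise ValueError(
                f"{path}: line {lineno}: fluid token {bad_token!r} not in vocabulary"
            )
        labels.setdefault(protein, set()).update(fluids)
    return AnnotationTable(labels)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tfluids\n")
        for protein, fluids in ann.items():
            fh.write(f"{protein}\t{','.join(str(f) for f in sorted(fluids))}\n")


PREDICTION_COLUMNS = ("query_id", "order", "fluid_number", "fluid_name", "score")


def write_predictions(
    preds: Sequence[RankedPrediction],
    vocab: FluidVocabulary,
    path: str | Path,
    top_k: int | None = None,
) -> None:
    """Write ranked predictions as a 5-column TSV, ``top_k`` ranks per query."""
    for pred in preds:
        if sorted(pred.order) != sorted(vocab.numbers):
            raise ValueError(
                f"prediction for {pred.query!r} is not a permutation of the vocabulary"
            )
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for pred in preds:
            limit = len(pred.order) if top_k is None else min(top_k, len(pred.order))
            for rank in range(limit):
                fluid = pred.order[rank]
                fh.write(
                    f"{pred.query}\t{rank + 1}\t{fluid}\t"
                    f"{vocab.name_of(fluid)}\t{pred.sorted_scores[rank]:.6f}\n"
                )


def read_predictions(
    path: str | Path, vocab: FluidVocabulary | None = None
) -> list[RankedPrediction]:
    """Read back a predictions TSV (full-permutation files only)."""
    vocab = vocab or default_vocabulary()
    per_query: dict[str, list[tuple[int, int, float]]] = {}
    order_seen: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if lineno == 1 or not line.strip():
            continue  # header
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}: line {lineno}: expected 5 columns")
        q, rank, fluid, _name, score = fields
        if q not in per_query:
            per_query[q] = []
            order_seen.append(q)
        per_query[q].append((int(rank), int(fluid), float(score)))
    preds = []
    for q in order_seen:
        rows = sorted(per_query[q])
        order = tuple(fluid for _, fluid, _ in rows)
        scores = tuple(score for _, _, score in rows)
        preds.append(
            RankedPrediction(
                query=q, order=order, sorted_scores=scores,
                predictable=any(s > 0 for s in scores),
            )
        )
    return preds


def write_report(report: EvaluationReport, path: str | Path) -> None:
    """Serialize an evaluation report to JSON (lossless round-trip)."""
    if report.n_evaluated <= 0:
        raise ValueError("refusing to write a report over zero proteins")
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> EvaluationReport:
    with open(path) as fh:
        return EvaluationReport.from_dict(json.load(fh))
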
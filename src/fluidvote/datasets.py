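"""Packaged reference data.

Two small fixtures ship with the package:

* the per-fluid census of the 529-protein curated human secretome training
  set (how many of the 529 proteins are detected in each of the 11 fluids;
  the column total is 1708 because most proteins occur in several fluids);
* the worked example around peptidoglycan recognition protein 1 (PGRP-1,
  UniProt O75594): its 23 PPI neighbors with interaction confidences and
  the body-fluid annotations of all 24 proteins. PGRP-1 is detected in
  plasma/serum, saliva and urine, and the weighted neighbor vote recovers
  exactly those three fluids as the top-ranked predictions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_annotations, read_network
from .scoring import AnnotationTable, InteractionNetwork
from .vocabulary import FluidVocabulary, default_vocabulary

#: Number of proteins in the curated secretome training set the census
#: describes. The full 529-node interaction network is not redistributable;
#: only its printed per-fluid census is packaged.
TRAINING_SET_SIZE = 529

#: UniProt accession of peptidoglycan recognition protein 1, the worked example.
PGRP1 = "O75594"


def secretome_census() -> pd.DataFrame:
    """Per-fluid protein counts of the 529-protein training set.

    Columns: ``type_number``, ``name``, ``n_proteins``. The ``n_proteins``
    column sums to 1708, the total number of (protein, fluid) annotations.
    """
    path = resources.files("fluidvote.data") / "secretome_census.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def pgrp1_example(
    vocab: FluidVocabulary | None = None,
) -> tuple[InteractionNetwork, AnnotationTable]:
    """The PGRP-1 (O75594) star network: 24 proteins, 23 weighted edges."""
    vocab = vocab or default_vocabulary()
    data = resources.files("fluidvote.data")
    with resources.as_file(data / "pgrp1_interactions.tsv") as p:
        net = read_network(p, score_scale="unit")
    with resources.as_file(data / "pgrp1_fluids.tsv") as p:
        ann = read_annotations(p, vocab)
    return net, ann
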
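"""End-to-end assembly: representations -> features -> partitioned heads.

Thin composition layer used by the CLI, the examples and the test suite.
Each function takes the in-memory objects the lower modules define; no
function here reinvents a lower-level step.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import evaluation, models, rocket
from .features import (
    FeatureMatrix,
    PooledProvenance,
    flatten_padded,
)
from .io import PeptideRecord
from .models import ClassifierSpec, fit, predict_scores
from .representations import (
    MAX_LEN,
    BlockIndexMap,
    PaddedTensor,
    PLDDTTrack,
    ResidueRepresentation,
    concat_blocks,
    mean_pool,
    pad_to,
)

RepsByAccession = Mapping[str, Mapping[str, ResidueRepresentation | PLDDTTrack]]


def combined_representation(
    blocks: Mapping[str, ResidueRepresentation | PLDDTTrack]
) -> tuple[ResidueRepresentation, BlockIndexMap]:
    """Concatenate one peptide's four blocks into the combined (L, 1152)."""
    return concat_blocks(
        blocks["single"], blocks["pair_reduced"], blocks["msa"], blocks["structure"]
    )


def padded_tensors(
    records: Sequence[PeptideRecord],
    reps: RepsByAccession,
    max_len: int = MAX_LEN,
) -> tuple[list[PaddedTensor], BlockIndexMap]:
    """Combined representations of all records, zero-padded to max_len."""
    tensors = []
    block_map: BlockIndexMap | None = None
    for rec in records:
        combined, block_map = combined_representation(reps[rec.accession])
        tensors.append(pad_to(combined, max_len))
    assert block_map is not None
    return tensors, block_map


def pooled_features(
    records: Sequence[PeptideRecord], reps: RepsByAccession
) -> FeatureMatrix:
    """Mean-pooled combined representation, one 1152-vector per peptide."""
    rows = []
    block_map: BlockIndexMap | None = None
    for rec in records:
        combined, block_map = combined_representation(reps[rec.accession])
        rows.append(mean_pool(combined))
    assert block_map is not None
    return FeatureMatrix(np.vstack(rows), PooledProvenance(block_map))


def flattened_features(
    records: Sequence[PeptideRecord],
    reps: RepsByAccession,
    max_len: int = MAX_LEN,
) -> tuple[FeatureMatrix, list[int]]:
    """Flattened padded tensors (position x channel columns) + true lengths."""
    tensors, block_map = padded_tensors(records, reps, max_len)
    X = flatten_padded([t.values for t in tensors], block_map, max_len)
    return X, [t.true_length for t in tensors]


def rocket_features(
    records: Sequence[PeptideRecord],
    reps: RepsByAccession,
    bank: rocket.KernelBank,
    max_len: int = MAX_LEN,
) -> FeatureMatrix:
    """Random-convolution features of the padded combined representation."""
    tensors, _ = padded_tensors(records, reps, max_len)
    return rocket.transform(tensors, bank)


def head_trainer(
    spec: ClassifierSpec, X: FeatureMatrix | np.ndarray, y: np.ndarray
) -> evaluation.TrainScoreFn:
    """Adapt a classifier head to the evaluation module's train/score protocol."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(y).astype(int)

    def train_and_score(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        model = fit(spec, values[train_idx], y[train_idx])
        return predict_scores(model, values[test_idx])

    return train_and_score


def train_partitioned(
    spec: ClassifierSpec,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    is_knottin: np.ndarray,
) -> models.PartitionedModel:
    """Fit fully independent knottin / non-knottin heads."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(y).astype(int)
    is_knottin = np.asarray(is_knottin, dtype=bool)
    return models.PartitionedModel(
        knottin=fit(spec, values[is_knottin], y[is_knottin]),
        non_knottin=fit(spec, values[~is_knottin], y[~is_knottin]),
    )
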
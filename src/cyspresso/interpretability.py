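"""Shapley-based feature attribution and confidence-track comparisons.

Attribution is applied to forest models trained on flattened per-residue
tensors (position x channel features) only — the random-convolution
transform breaks the direct correspondence between columns and residue
positions, so attributing those features position-wise would be
meaningless and is refused.

Per-sample signed contributions are aggregated two ways: summed absolute
contributions per residue position (normalized for the fact that short
peptides never occupy C-terminal positions) and per representation block.
A separate utility compares mean pLDDT between correctly and incorrectly
predicted peptides with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import MannWhitneyResult, mann_whitney_u
from .features import FeatureMatrix, PositionChannelProvenance
from .models import FittedModel
from .treeshap import forest_shap, sampling_shap


@dataclass
class AttributionSet:
    """Per-sample per-feature signed Shapley contributions.

    Local accuracy: base_value + contributions[s].sum() equals the model's
    positive-class probability for sample s (to 1e-6 in exact mode; the
    Monte-Carlo mode carries sampling error and records its seed/draws).
    """

    contributions: np.ndarray  # (n_samples, n_features)
    base_value: float
    provenance: PositionChannelProvenance
    method: str
    n_draws: int | None = None
    seed: int | None = None


def attribute(
    model: FittedModel,
    X: FeatureMatrix,
    method: str = "exact",
    n_draws: int = 2000,
    seed: int = 0,
) -> AttributionSet:
    """Shapley contributions of a forest model on position-resolved features.

    ``method="exact"`` uses the exact tree-path algorithm; ``"sampling"``
    is a Monte-Carlo permutation estimate (>= 2000 draws recommended) for
    small models.
    """
    if model.spec.head != "random_forest":
        raise ValueError("attribution is only defined for the random forest head")
    if not isinstance(X.provenance, PositionChannelProvenance):
        raise ValueError(
            "attribution requires (position, channel) feature provenance; "
            "transformed (e.g. random-kernel) features are not attributable "
            "to residue positions"
        )
    if model.provenance is not None and model.provenance != X.provenance:
        raise ValueError("feature provenance does not match the training features")
    pos_idx = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    if method == "exact":
        phi, base = forest_shap(model.estimator, X.values, pos_idx)
    elif method == "sampling":
        if n_draws < 1:
            raise ValueError("n_draws must be positive")
        phi, base = sampling_shap(model.estimator, X.values, n_draws, seed, pos_idx)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return AttributionSet(
        contributions=phi,
        base_value=float(base),
        provenance=X.provenance,
        method=method,
        n_draws=n_draws if method == "sampling" else None,
        seed=seed if method == "sampling" else None,
    )


@dataclass
class PositionImportance:
    """Summed |contribution| per residue position, with normalization."""

    raw: np.ndarray          # (max_len,)
    normalized: np.ndarray   # (max_len,), NaN where no sample reaches
    n_eligible: np.ndarray   # (max_len,) samples eligible at each position
    mode: str

    def to_table(self) -> list[dict[str, object]]:
        return [
            {
                "position": p,
                "raw": float(self.raw[p]),
                "normalized": (
                    None if np.isnan(self.normalized[p]) else float(self.normalized[p])
                ),
                "n_eligible": int(self.n_eligible[p]),
            }
            for p in range(self.raw.size)
        ]


def importance_by_position(
    attr: AttributionSet,
    lengths: Sequence[int],
    mode: str = "occupancy",
) -> PositionImportance:
    """Aggregate |contributions| over samples and channels per position.

    ``mode="occupancy"`` (default) divides position p by the number of
    samples whose true length exceeds p — correcting the padding-induced
    undercount at C-terminal positions.  ``mode="exact_length"`` is the
    literal per-length reading: contributions from samples of length l
    are divided by the number of samples of exactly that length before
    summing.  Positions no sample occupies are reported NaN.
    """
    lengths = np.asarray(lengths, dtype=int)
    max_len = attr.provenance.max_len
    if lengths.size != attr.contributions.shape[0]:
        raise ValueError("lengths must give one true length per attributed sample")
    width = attr.provenance.block_map.width
    abs_contrib = np.abs(attr.contributions)
    # row-major flattening: (n_samples, max_len, width) summed over channels
    per_pos = abs_contrib.reshape(-1, max_len, width).sum(axis=2)
    raw = per_pos.sum(axis=0)
    if mode == "occupancy":
        n_eligible = (lengths[:, None] > np.arange(max_len)[None, :]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            normalized = np.where(n_eligible > 0, raw / n_eligible, np.nan)
    elif mode == "exact_length":
        normalized = np.zeros(max_len)
        n_eligible = (lengths[:, None] > np.arange(max_len)[None, :]).sum(axis=0)
        for ell in np.unique(lengths):
            members = lengths == ell
            normalized += per_pos[members].sum(axis=0) / members.sum()
        normalized = np.where(n_eligible > 0, normalized, np.nan)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PositionImportance(
        raw=raw, normalized=normalized, n_eligible=n_eligible, mode=mode
    )


def importance_by_block(attr: AttributionSet) -> dict[str, float]:
    """Summed |contribution| per representation block.

    The block totals partition the overall absolute attribution: they sum
    to ``np.abs(attr.contributions).sum()``.
    """
    block_ids = attr.provenance.block_ids()
    totals = np.abs(attr.contributions).sum(axis=0)
    names = attr.provenance.block_map.block_names
    return {
        name: float(totals[block_ids == b].sum()) for b, name in enumerate(names)
    }


@dataclass
class PlddtComparison:
    """Mean-pLDDT comparison between correctly and incorrectly predicted CDPs."""

    n_correct: int
    n_incorrect: int
    median_correct: float | None
    median_incorrect: float | None
    iqr_correct: tuple[float, float] | None
    iqr_incorrect: tuple[float, float] | None
    test: MannWhitneyResult | None
    skipped: bool


def compare_plddt_by_outcome(
    mean_plddt: Sequence[float],
    predictions: Sequence[int],
    labels: Sequence[int],
) -> PlddtComparison:
    """Split peptides into correct (TP+TN) vs incorrect (FP+FN) predictions
    and compare their mean pLDDT with the Mann-Whitney U test.

    If either group is empty the comparison is reported but the test is
    skipped.
    """
    mean_plddt = np.asarray(mean_plddt, dtype=float)
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    correct = predictions == labels
    a = mean_plddt[correct]
    b = mean_plddt[~correct]

    def summarize(v: np.ndarray):
        if v.size == 0:
            return None, None
        return float(np.median(v)), (float(np.percentile(v, 25)), float(np.percentile(v, 75)))

    med_a, iqr_a = summarize(a)
    med_b, iqr_b = summarize(b)
    if a.size == 0 or b.size == 0:
        return PlddtComparison(a.size, b.size, med_a, med_b, iqr_a, iqr_b, None, True)
    return PlddtComparison(
        n_correct=int(a.size),
        n_incorrect=int(b.size),
        median_correct=med_a,
        median_incorrect=med_b,
        iqr_correct=iqr_a,
        iqr_incorrect=iqr_b,
        test=mann_whitney_u(a, b),
        skipped=False,
    )
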
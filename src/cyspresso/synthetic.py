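"""Synthetic cysteine-dense-peptide datasets with controllable planted signal.

Every pipeline stage is testable without external downloads: this module
fabricates peptide records (variable lengths 30-50, knottin flags,
expression labels), the four per-residue representation blocks at their
real channel widths, and pLDDT-like confidence tracks.

The generator's background is independent standard normal per channel.
For positive-class (expressed) peptides a constant effect of size delta
is added at a chosen set of residue positions and channels of one block,
anchored at the N-terminus by default so trailing-pad conventions do not
shift the planted positions.  Labels can be flipped with a noise
probability after the signal is planted.  Everything is deterministic
under the seed.

Defaults mirror the real dataset's class geometry: 1227 peptides split
876 non-knottin (58.6% expressed) / 351 knottin (47.0% expressed), i.e. a
knottin fraction of 0.286 and an overall positive fraction of 0.55.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io import PeptideRecord
from .representations import (
    BLOCK_WIDTHS,
    COMBINED_ORDER,
    PLDDTTrack,
    ResidueRepresentation,
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 300
    length_range: tuple[int, int] = (30, 50)
    knottin_fraction: float = 351 / 1227
    positive_fraction: float = 0.55
    effect_size: float = 0.0
    signal_positions: tuple[int, ...] = (7, 8, 9)
    signal_block: str = "single"
    signal_channels: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    signal_anchor: str = "n_terminus"
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length range")
        if self.signal_block not in COMBINED_ORDER:
            raise ValueError(f"signal_block must be one of {COMBINED_ORDER}")
        if self.signal_positions and max(self.signal_positions) >= lo:
            raise ValueError(
                "signal_positions must fit inside the shortest peptide "
                f"(min length {lo})"
            )
        width = BLOCK_WIDTHS[self.signal_block]
        if self.signal_channels and max(self.signal_channels) >= width:
            raise ValueError(
                f"signal_channels must lie within block width {width}"
            )
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.signal_anchor not in ("n_terminus", "c_terminus"):
            raise ValueError("signal_anchor must be n_terminus or c_terminus")


@dataclass
class SyntheticDataset:
    """Records plus per-accession representation blocks and labels."""

    records: list[PeptideRecord]
    representations: dict[str, dict[str, ResidueRepresentation | PLDDTTrack]]
    labels: np.ndarray  # observed (possibly noise-flipped) labels
    config: SyntheticConfig

    @property
    def is_knottin(self) -> np.ndarray:
        return np.array([r.is_knottin for r in self.records], dtype=bool)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=int)

    @property
    def mean_plddt(self) -> np.ndarray:
        return np.array(
            [self.representations[r.accession]["plddt"].mean_plddt for r in self.records]
        )

    def container_data(self) -> dict[str, dict[str, np.ndarray]]:
        """Blocks in the array-container dialect (pre-reduced pair)."""
        out: dict[str, dict[str, np.ndarray]] = {}
        for rec in self.records:
            blocks = self.representations[rec.accession]
            out[rec.accession] = {
                "single": blocks["single"].values,
                "pair": blocks["pair_reduced"].values,
                "msa": blocks["msa"].values,
                "structure": blocks["structure"].values,
                "plddt": blocks["plddt"].values,
            }
        return out


def _random_sequence(rng: np.random.Generator, length: int, knottin: bool) -> str:
    seq = rng.choice(AA_ALPHABET, size=length)
    if knottin:
        # cosmetic realism: force six cysteines at distinct positions
        pos = rng.choice(length, size=6, replace=False)
        seq[pos] = "C"
    return "".join(seq)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic dataset under the given study conditions.

    With effect_size 0 the labels are statistically independent of every
    feature (a null dataset); with a positive effect the expressed class
    has ``effect_size`` added at the configured positions/channels of the
    configured block before any label noise is applied.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    n = config.n_samples
    lengths = rng.integers(lo, hi + 1, size=n)
    knottin = rng.random(n) < config.knottin_fraction
    true_labels = rng.random(n) < config.positive_fraction

    records: list[PeptideRecord] = []
    reps: dict[str, dict[str, ResidueRepresentation | PLDDTTrack]] = {}
    flip = rng.random(n) < config.label_noise
    observed = np.where(flip, ~true_labels, true_labels)

    for i in range(n):
        L = int(lengths[i])
        acc = f"SYN{i:05d}"
        records.append(
            PeptideRecord(
                accession=acc,
                sequence=_random_sequence(rng, L, bool(knottin[i])),
                is_knottin=bool(knottin[i]),
                expressed=bool(observed[i]),
            )
        )
        blocks: dict[str, ResidueRepresentation | PLDDTTrack] = {}
        for name in COMBINED_ORDER:
            values = rng.normal(size=(L, BLOCK_WIDTHS[name]))
            if (
                config.effect_size > 0
                and true_labels[i]
                and name == config.signal_block
                and config.signal_positions
                and config.signal_channels
            ):
                pos = np.asarray(config.signal_positions, dtype=int)
                if config.signal_anchor == "c_terminus":
                    pos = L - 1 - pos
                values[np.ix_(pos, np.asarray(config.signal_channels))] += config.effect_size
            blocks[name] = ResidueRepresentation(name, values)
        plddt = np.clip(60.0 + 35.0 * expit(rng.normal(size=L)), 0.0, 100.0)
        blocks["plddt"] = PLDDTTrack(plddt)
        reps[acc] = blocks

    return SyntheticDataset(
        records=records,
        representations=reps,
        labels=observed.astype(int),
        config=config,
    )


def make_paper_shaped_dataset(seed: int = 0) -> list[PeptideRecord]:
    """Records matching the real dataset's class geometry exactly.

    Emits 876 non-knottins (513 expressed) and 351 knottins (165
    expressed) with random sequences — a fixture for fold-balancing and
    metric-shape checks.  Representations are not generated here (the
    geometry, not the features, is the point); use :func:`generate` for
    feature-bearing datasets.
    """
    rng = np.random.default_rng(seed)
    records: list[PeptideRecord] = []
    plan = (
        (False, True, 513),
        (False, False, 876 - 513),
        (True, True, 165),
        (True, False, 351 - 165),
    )
    i = 0
    for knottin, expressed, count in plan:
        for _ in range(count):
            L = int(rng.integers(30, 51))
            records.append(
                PeptideRecord(
                    accession=f"SYN{i:05d}",
                    sequence=_random_sequence(rng, L, knottin),
                    is_knottin=knottin,
                    expressed=expressed,
                )
            )
            i += 1
    return records
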
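"""Per-residue representation blocks and the fixed-size inputs derived from them.

A structure-prediction run emits four per-residue blocks for a peptide of
length L: the abstract "single" representation (L x 384), the residue-pair
representation reduced to per-residue form (L x 128), the MSA representation
(L x 256) and the structure-module representation (L x 384), together with a
per-residue confidence track (pLDDT, values in [0, 100]).  Five model runs
are produced per peptide and the run with the highest mean pLDDT is kept.

Classifiers consume either the mean-pooled vector (one value per channel,
averaged over true residues only) or the full per-residue tensor zero-padded
to a fixed 50 rows with the four blocks concatenated to 1152 channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: channel width of each representation block
BLOCK_WIDTHS: dict[str, int] = {
    "single": 384,
    "pair_reduced": 128,
    "msa": 256,
    "structure": 384,
    "seqvec": 1024,
    "proteinfer": 1100,
}

#: block order of the combined 1152-channel representation
COMBINED_ORDER = ("single", "pair_reduced", "msa", "structure")

#: default padded length (residues)
MAX_LEN = 50


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueRepresentation:
    """One named per-residue representation block: an (L, D) real matrix."""

    block_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ShapeError(f"block {self.block_name!r}: values must be 2-D")
        width = BLOCK_WIDTHS.get(self.block_name)
        if width is not None and values.shape[1] != width:
            raise ShapeError(
                f"block {self.block_name!r}: expected {width} channels, "
                f"got {values.shape[1]}"
            )
        if not np.isfinite(values).all():
            raise ValueError(f"block {self.block_name!r}: non-finite values")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PLDDTTrack:
    """Per-residue structure-prediction confidence in [0, 100]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ShapeError("pLDDT track must be a non-empty vector")
        if values.min() < 0.0 or values.max() > 100.0:
            raise ValueError("pLDDT values must lie in [0, 100]")

    @property
    def mean_plddt(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class ModelRun:
    """One structure-prediction run: its representation blocks + confidence."""

    blocks: Mapping[str, ResidueRepresentation]
    plddt: PLDDTTrack


@dataclass(frozen=True)
class ModelRunSet:
    """The 1..5 candidate runs produced for one peptide."""

    runs: tuple[ModelRun, ...]

    def __post_init__(self) -> None:
        if len(self.runs) == 0:
            raise ValueError("ModelRunSet must hold at least one run")


@dataclass(frozen=True)
class PaddedTensor:
    """A representation zero-padded to a fixed number of rows.

    Rows with index >= true_length are exactly zero; padding is appended at
    the C-terminal end so N-terminal position indices are preserved.
    """

    values: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ShapeError("padded tensor must be 2-D")
        if not (0 < self.true_length <= values.shape[0]):
            raise ValueError("true_length must be in (0, max_len]")
        if self.true_length < values.shape[0] and np.any(values[self.true_length :]):
            raise ValueError("pad rows must be exactly zero")

    @property
    def max_len(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BlockIndexMap:
    """Maps combined-representation channel indices back to (block, offset)."""

    spans: tuple[tuple[str, int, int], ...]  # (name, start, stop)

    def block_of(self, channel: int) -> tuple[str, int]:
        for name, start, stop in self.spans:
            if start <= channel < stop:
                return name, channel - start
        raise IndexError(f"channel {channel} outside combined width")

    @property
    def width(self) -> int:
        return self.spans[-1][2]

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.spans)


def select_best_run(runs: ModelRunSet) -> ModelRun:
    """Return the run with the highest mean pLDDT (ties: lowest run index)."""
    best_idx = 0
    best = runs.runs[0].plddt.mean_plddt
    for i, run in enumerate(runs.runs[1:], start=1):
        m = run.plddt.mean_plddt
        if m > best:
            best, best_idx = m, i
    return runs.runs[best_idx]


def reduce_pair(pair: np.ndarray) -> np.ndarray:
    """Reduce a raw (L, L, C) pair tensor to (L, C) by averaging axis 0.

    out[j, c] = mean_i pair[i, j, c].
    """
    pair = np.asarray(pair, dtype=np.float64)
    if pair.ndim != 3:
        raise ShapeError(f"pair tensor must be 3-D, got ndim={pair.ndim}")
    if pair.shape[0] != pair.shape[1]:
        raise ShapeError(
            f"pair tensor first two dims must match, got {pair.shape[:2]}"
        )
    return pair.mean(axis=0)


def concat_blocks(
    single: ResidueRepresentation,
    pair_reduced: ResidueRepresentation,
    msa: ResidueRepresentation,
    structure: ResidueRepresentation,
) -> tuple[ResidueRepresentation, BlockIndexMap]:
    """Concatenate the four blocks along channels into the combined (L, 1152).

    Channel order: single (0-383), pair_reduced (384-511), msa (512-767),
    structure (768-1151).  The returned :class:`BlockIndexMap` inverts the
    channel layout for interpretability.
    """
    blocks = {
        "single": single,
        "pair_reduced": pair_reduced,
        "msa": msa,
        "structure": structure,
    }
    lengths = {name: b.n_residues for name, b in blocks.items()}
    if len(set(lengths.values())) != 1:
        raise ShapeError(f"blocks disagree on residue count: {lengths}")
    spans = []
    start = 0
    for name in COMBINED_ORDER:
        width = BLOCK_WIDTHS[name]
        if blocks[name].n_channels != width:
            raise ShapeError(
                f"block {name!r} has {blocks[name].n_channels} channels, expected {width}"
            )
        spans.append((name, start, start + width))
        start += width
    combined = np.concatenate([blocks[n].values for n in COMBINED_ORDER], axis=1)
    return ResidueRepresentation("combined", combined), BlockIndexMap(tuple(spans))


def pad_to(rep: ResidueRepresentation | np.ndarray, max_len: int = MAX_LEN) -> PaddedTensor:
    """Zero-pad a representation to ``max_len`` rows (trailing, C-terminal).

    Inputs longer than ``max_len`` are an error — never truncated.
    """
    values = rep.values if isinstance(rep, ResidueRepresentation) else np.asarray(rep, float)
    L = values.shape[0]
    if L > max_len:
        raise ValueError(f"length {L} exceeds max_len {max_len}; refusing to truncate")
    out = np.zeros((max_len, values.shape[1]), dtype=np.float64)
    out[:L] = values
    return PaddedTensor(out, true_length=L)


def mean_pool(rep: ResidueRepresentation | PaddedTensor | np.ndarray) -> np.ndarray:
    """Average each channel over the true residues (pad rows excluded)."""
    if isinstance(rep, PaddedTensor):
        values = rep.values[: rep.true_length]
    elif isinstance(rep, ResidueRepresentation):
        values = rep.values
    else:
        values = np.asarray(rep, dtype=np.float64)
    if values.shape[0] == 0:
        raise ValueError("cannot pool a zero-residue representation")
    return values.mean(axis=0)
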
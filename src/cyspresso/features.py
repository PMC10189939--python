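"""Feature matrices with provenance.

Every classifier input in this package is an ``n_samples x n_features``
real matrix plus a provenance object describing what each column is:
a (block, position, channel) triple for flattened per-residue tensors,
a (block, channel) pair for pooled embeddings, or a (kernel, statistic)
pair for random-convolution features.  Models record the provenance they
were trained on and refuse to score a matrix whose columns mean something
else; the interpretability layer uses it to aggregate attributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .representations import BlockIndexMap


@dataclass(frozen=True)
class PositionChannelProvenance:
    """Columns of a flattened (max_len x width) per-residue tensor.

    Flattening is row-major: feature f = position * width + channel, with
    ``channel`` indexing the combined representation and resolved to a
    named block through ``block_map``.
    """

    block_map: BlockIndexMap
    max_len: int

    @property
    def n_features(self) -> int:
        return self.max_len * self.block_map.width

    def feature_info(self, f: int) -> tuple[str, int, int]:
        """Return (block_name, position, channel_within_block) for column f."""
        width = self.block_map.width
        position, channel = divmod(int(f), width)
        block, offset = self.block_map.block_of(channel)
        return block, position, offset

    def positions(self) -> np.ndarray:
        """Per-column position index, vectorised."""
        return np.arange(self.n_features) // self.block_map.width

    def block_ids(self) -> np.ndarray:
        """Per-column index into ``block_map.block_names``, vectorised."""
        width = self.block_map.width
        channel = np.arange(self.n_features) % width
        out = np.empty(self.n_features, dtype=np.int64)
        for b, (name, start, stop) in enumerate(self.block_map.spans):
            out[(channel >= start) & (channel < stop)] = b
        return out


@dataclass(frozen=True)
class PooledProvenance:
    """Columns of a mean-pooled embedding (one value per channel)."""

    block_map: BlockIndexMap

    @property
    def n_features(self) -> int:
        return self.block_map.width

    def feature_info(self, f: int) -> tuple[str, int]:
        block, offset = self.block_map.block_of(int(f))
        return block, offset


@dataclass(frozen=True)
class RocketProvenance:
    """Columns of a random-convolutional-kernel transform: 2 per kernel."""

    n_kernels: int
    bank_seed: int

    @property
    def n_features(self) -> int:
        return 2 * self.n_kernels

    def feature_info(self, f: int) -> tuple[int, str]:
        kernel, stat = divmod(int(f), 2)
        return kernel, ("ppv", "max")[stat]


Provenance = PositionChannelProvenance | PooledProvenance | RocketProvenance


@dataclass(frozen=True)
class FeatureMatrix:
    """n_samples x n_features matrix with a column provenance map."""

    values: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if values.shape[1] != self.provenance.n_features:
            raise ValueError(
                f"matrix has {values.shape[1]} columns but provenance "
                f"declares {self.provenance.n_features}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values[np.asarray(rows)], self.provenance)


def save_features(
    path, X: FeatureMatrix, accessions: Sequence[str]
) -> None:
    """Persist a feature matrix + provenance + row accessions to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=X.values, track_times=False)
        fh.create_dataset(
            "accessions",
            data=np.array([a.encode() for a in accessions]),
            track_times=False,
        )
        prov = X.provenance
        if isinstance(prov, RocketProvenance):
            fh.attrs["kind"] = "rocket"
            fh.attrs["n_kernels"] = prov.n_kernels
            fh.attrs["bank_seed"] = prov.bank_seed
        else:
            if isinstance(prov, PositionChannelProvenance):
                fh.attrs["kind"] = "position_channel"
                fh.attrs["max_len"] = prov.max_len
                block_map = prov.block_map
            else:
                fh.attrs["kind"] = "pooled"
                block_map = prov.block_map
            fh.attrs["spans"] = "|".join(
                f"{name}:{start}:{stop}" for name, start, stop in block_map.spans
            )


def load_features(path) -> tuple[FeatureMatrix, list[str]]:
    """Inverse of :func:`save_features`."""
    import h5py

    with h5py.File(path, "r") as fh:
        values = np.asarray(fh["values"])
        accessions = [a.decode() for a in fh["accessions"]]
        kind = fh.attrs["kind"]
        if kind == "rocket":
            prov: Provenance = RocketProvenance(
                int(fh.attrs["n_kernels"]), int(fh.attrs["bank_seed"])
            )
        else:
            spans = tuple(
                (p.split(":")[0], int(p.split(":")[1]), int(p.split(":")[2]))
                for p in str(fh.attrs["spans"]).split("|")
            )
            block_map = BlockIndexMap(spans)
            if kind == "position_channel":
                prov = PositionChannelProvenance(block_map, int(fh.attrs["max_len"]))
            else:
                prov = PooledProvenance(block_map)
    return FeatureMatrix(values, prov), accessions


def flatten_padded(tensors: Sequence["np.ndarray"], block_map: BlockIndexMap,
                   max_len: int) -> FeatureMatrix:
    """Flatten a stack of (max_len, width) padded tensors row-major."""
    arr = np.stack([np.asarray(t, dtype=np.float64) for t in tensors])
    n, L, C = arr.shape
    if L != max_len or C != block_map.width:
        raise ValueError(f"expected ({max_len}, {block_map.width}) tensors, got ({L}, {C})")
    return FeatureMatrix(
        arr.reshape(n, L * C), PositionChannelProvenance(block_map, max_len)
    )
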
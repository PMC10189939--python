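"""Random convolutional kernel transform for multichannel residue tensors.

Many random convolution kernels are drawn once (lengths in {7, 9, 11},
normal mean-centred weights, uniform bias in [-1, 1], exponentially
sampled dilation, optional same-padding, and a random channel subset per
kernel) and convolved along the residue axis of each zero-padded
representation.  Each kernel contributes two summary features: the
proportion of positive values (PPV, strictly > 0) and the maximum of the
convolution output — so 10,000 kernels yield 20,000 features per peptide.
The transform is unsupervised and deterministic given the bank's seed; a
frozen bank can be serialized and reloaded bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from numba import njit

from .features import FeatureMatrix, RocketProvenance
from .representations import PaddedTensor

KERNEL_LENGTHS = (7, 9, 11)


@dataclass(frozen=True)
class Kernel:
    """One random convolution kernel.

    weights has shape (len(channel_subset), length) and is mean-centred
    over all entries; bias lies in [-1, 1]; when ``use_padding`` the
    series is zero-extended by ((length-1)*dilation)//2 on both sides.
    """

    length: int
    channel_subset: np.ndarray
    weights: np.ndarray
    bias: float
    dilation: int
    use_padding: bool

    @property
    def padding(self) -> int:
        return ((self.length - 1) * self.dilation) // 2 if self.use_padding else 0


@dataclass(frozen=True)
class KernelBank:
    """A packed bank of random kernels plus the parameters that made it.

    Regeneration with the same (seed, n_kernels, input_length, n_channels,
    channel_mode) is bit-identical.
    """

    n_kernels: int
    input_length: int
    n_channels: int
    seed: int
    channel_mode: str
    lengths: np.ndarray       # (K,) int64
    dilations: np.ndarray     # (K,) int64
    paddings: np.ndarray      # (K,) int64
    biases: np.ndarray        # (K,) float64
    channel_offsets: np.ndarray  # (K+1,) int64 into channel_flat
    channel_flat: np.ndarray     # concatenated sorted channel subsets
    weight_offsets: np.ndarray   # (K+1,) int64 into weight_flat
    weight_flat: np.ndarray      # weights, kernel-major, channel-major, tap-minor

    def kernel(self, k: int) -> Kernel:
        """Materialize kernel k as a standalone object."""
        c0, c1 = self.channel_offsets[k], self.channel_offsets[k + 1]
        chans = self.channel_flat[c0:c1]
        klen = int(self.lengths[k])
        w = self.weight_flat[self.weight_offsets[k] : self.weight_offsets[k + 1]]
        return Kernel(
            length=klen,
            channel_subset=chans.copy(),
            weights=w.reshape(len(chans), klen).copy(),
            bias=float(self.biases[k]),
            dilation=int(self.dilations[k]),
            use_padding=bool(self.paddings[k] > 0),
        )

    def __len__(self) -> int:
        return self.n_kernels


def generate_kernels(
    n_kernels: int,
    input_length: int,
    n_channels: int,
    seed: int,
    channel_mode: str = "subset",
) -> KernelBank:
    """Sample a deterministic bank of random convolution kernels.

    Per kernel: length uniform over {7, 9, 11}; weights standard normal
    then mean-centred over all entries; bias uniform on [-1, 1]; dilation
    2**a with a uniform on [0, log2((input_length-1)/(length-1))] (so the
    dilated span never exceeds the input); padding a fair coin.  With
    ``channel_mode="subset"`` the subset size is drawn uniformly on a log
    scale over [1, n_channels] and that many channels are drawn without
    replacement; ``"all"`` convolves every channel with every kernel.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    if n_kernels < 0:
        raise ValueError("n_kernels must be non-negative")
    if n_kernels > 0 and input_length < max(KERNEL_LENGTHS):
        raise ValueError(
            f"input_length {input_length} shorter than the largest kernel "
            f"({max(KERNEL_LENGTHS)})"
        )
    if channel_mode not in ("subset", "all"):
        raise ValueError(f"unknown channel_mode {channel_mode!r}")

    rng = np.random.default_rng(seed)
    lengths = rng.choice(np.asarray(KERNEL_LENGTHS, dtype=np.int64), size=n_kernels)
    dilations = np.empty(n_kernels, dtype=np.int64)
    paddings = np.empty(n_kernels, dtype=np.int64)
    biases = rng.uniform(-1.0, 1.0, size=n_kernels)

    subsets: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for k in range(n_kernels):
        klen = int(lengths[k])
        max_exp = np.log2((input_length - 1) / (klen - 1))
        dilation = int(2 ** rng.uniform(0.0, max_exp))
        dilations[k] = dilation
        use_padding = rng.integers(0, 2) == 1
        paddings[k] = ((klen - 1) * dilation) // 2 if use_padding else 0
        if channel_mode == "all":
            chans = np.arange(n_channels, dtype=np.int64)
        else:
            size = int(2 ** rng.uniform(0.0, np.log2(n_channels + 1)))
            size = min(max(size, 1), n_channels)
            chans = np.sort(rng.choice(n_channels, size=size, replace=False)).astype(np.int64)
        w = rng.normal(0.0, 1.0, size=(len(chans), klen))
        w -= w.mean()
        subsets.append(chans)
        weights.append(w.ravel())

    channel_offsets = np.zeros(n_kernels + 1, dtype=np.int64)
    weight_offsets = np.zeros(n_kernels + 1, dtype=np.int64)
    for k in range(n_kernels):
        channel_offsets[k + 1] = channel_offsets[k] + len(subsets[k])
        weight_offsets[k + 1] = weight_offsets[k] + weights[k].size
    channel_flat = (
        np.concatenate(subsets) if subsets else np.empty(0, dtype=np.int64)
    )
    weight_flat = np.concatenate(weights) if weights else np.empty(0, dtype=np.float64)

    return KernelBank(
        n_kernels=n_kernels,
        input_length=input_length,
        n_channels=n_channels,
        seed=seed,
        channel_mode=channel_mode,
        lengths=lengths,
        dilations=dilations,
        paddings=paddings,
        biases=biases,
        channel_offsets=channel_offsets,
        channel_flat=channel_flat,
        weight_offsets=weight_offsets,
        weight_flat=weight_flat,
    )


@njit(cache=False)
def _transform_core(
    X, lengths, dilations, paddings, biases, ch_off, ch_flat, w_off, w_flat, out
):  # pragma: no cover - exercised through transform()
    n, L, _ = X.shape
    K = lengths.size
    for s in range(n):
        for k in range(K):
            klen = lengths[k]
            d = dilations[k]
            pad = paddings[k]
            m = ch_off[k + 1] - ch_off[k]
            out_len = L + 2 * pad - (klen - 1) * d
            npos = 0
            mx = -1.7976931348623157e308
            for t in range(out_len):
                acc = biases[k]
                start = t - pad
                for j in range(klen):
                    idx = start + j * d
                    if 0 <= idx < L:
                        wbase = w_off[k] + j
                        for ci in range(m):
                            acc += (
                                w_flat[wbase + ci * klen]
                                * X[s, idx, ch_flat[ch_off[k] + ci]]
                            )
                if acc > 0.0:
                    npos += 1
                if acc > mx:
                    mx = acc
            out[s, 2 * k] = npos / out_len
            out[s, 2 * k + 1] = mx


def _as_array(samples: Sequence[PaddedTensor] | np.ndarray) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        arr = samples
    else:
        arr = np.stack([s.values for s in samples])
    if arr.ndim != 3:
        raise ValueError("samples must form an (n, length, channels) array")
    return np.ascontiguousarray(arr, dtype=np.float64)


def transform(samples: Sequence[PaddedTensor] | np.ndarray, bank: KernelBank) -> FeatureMatrix:
    """Apply every kernel in the bank to every sample.

    Row s is the concatenation of (ppv, max) for each kernel in bank
    order: 2 * n_kernels columns.
    """
    X = _as_array(samples)
    n, L, C = X.shape
    if L != bank.input_length or C != bank.n_channels:
        raise ValueError(
            f"samples have shape ({L}, {C}) but bank expects "
            f"({bank.input_length}, {bank.n_channels})"
        )
    out = np.empty((n, 2 * bank.n_kernels), dtype=np.float64)
    if bank.n_kernels:
        _transform_core(
            X,
            bank.lengths,
            bank.dilations,
            bank.paddings,
            bank.biases,
            bank.channel_offsets,
            bank.channel_flat,
            bank.weight_offsets,
            bank.weight_flat,
            out,
        )
    return FeatureMatrix(out, RocketProvenance(bank.n_kernels, bank.seed))


def apply_kernel(x: PaddedTensor | np.ndarray, kernel: Kernel) -> tuple[float, float]:
    """Convolve one kernel over one sample, returning (ppv, max).

    out[t] = bias + sum_c sum_j weights[c, j] * x[t + j*dilation - pad, c],
    with out-of-range rows treated as zero; ppv counts entries strictly > 0.
    """
    values = x.values if isinstance(x, PaddedTensor) else np.asarray(x, dtype=np.float64)
    L = values.shape[0]
    pad = kernel.padding
    out_len = L + 2 * pad - (kernel.length - 1) * kernel.dilation
    if out_len <= 0:
        raise ValueError("kernel span exceeds input length")
    out = np.full(out_len, kernel.bias, dtype=np.float64)
    for t in range(out_len):
        start = t - pad
        for j in range(kernel.length):
            idx = start + j * kernel.dilation
            if 0 <= idx < L:
                out[t] += float(kernel.weights[:, j] @ values[idx, kernel.channel_subset])
    return float((out > 0).mean()), float(out.max())


def save_kernel_bank(bank: KernelBank, path: str | Path) -> None:
    """Serialize a bank to an HDF5 file (bit-exact round trip)."""
    with h5py.File(path, "w") as fh:
        for name in ("n_kernels", "input_length", "n_channels", "seed"):
            fh.attrs[name] = getattr(bank, name)
        fh.attrs["channel_mode"] = bank.channel_mode
        for name in (
            "lengths",
            "dilations",
            "paddings",
            "biases",
            "channel_offsets",
            "channel_flat",
            "weight_offsets",
            "weight_flat",
        ):
            fh.create_dataset(name, data=getattr(bank, name), track_times=False)


def load_kernel_bank(path: str | Path) -> KernelBank:
    with h5py.File(path, "r") as fh:
        return KernelBank(
            n_kernels=int(fh.attrs["n_kernels"]),
            input_length=int(fh.attrs["input_length"]),
            n_channels=int(fh.attrs["n_channels"]),
            seed=int(fh.attrs["seed"]),
            channel_mode=str(fh.attrs["channel_mode"]),
            lengths=np.asarray(fh["lengths"]),
            dilations=np.asarray(fh["dilations"]),
            paddings=np.asarray(fh["paddings"]),
            biases=np.asarray(fh["biases"]),
            channel_offsets=np.asarray(fh["channel_offsets"]),
            channel_flat=np.asarray(fh["channel_flat"]),
            weight_offsets=np.asarray(fh["weight_offsets"]),
            weight_flat=np.asarray(fh["weight_flat"]),
        )
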
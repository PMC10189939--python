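"""Random convolutional kernel transform: sampling, convolution, oracle."""

import numpy as np
import pytest
from scipy import stats

from cyspresso import rocket
from cyspresso.features import RocketProvenance
from cyspresso.representations import pad_to
from cyspresso.rocket import (
    Kernel,
    apply_kernel,
    generate_kernels,
    load_kernel_bank,
    save_kernel_bank,
    transform,
)


def naive_transform(X, bank):
    """Independent triple-nested-loop reference for the transform."""
    n, L, _ = X.shape
    out = np.empty((n, 2 * bank.n_kernels))
    for s in range(n):
        for k in range(bank.n_kernels):
            ker = bank.kernel(k)
            pad = ker.padding
            conv = []
            for t in range(L + 2 * pad - (ker.length - 1) * ker.dilation):
                acc = ker.bias
                for j in range(ker.length):
                    idx = t - pad + j * ker.dilation
                    if 0 <= idx < L:
                        for ci, c in enumerate(ker.channel_subset):
                            acc += ker.weights[ci, j] * X[s, idx, c]
                conv.append(acc)
            conv = np.array(conv)
            out[s, 2 * k] = np.mean(conv > 0)
            out[s, 2 * k + 1] = conv.max()
    return out


class TestGenerateKernels:
    def test_zero_kernels_gives_empty_bank(self):
        bank = generate_kernels(0, 50, 4, seed=0)
        assert len(bank) == 0
        assert transform(np.zeros((2, 50, 4)), bank).values.shape == (2, 0)

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_kernels(50, 50, 8, seed=5)
        b = generate_kernels(50, 50, 8, seed=5)
        c = generate_kernels(50, 50, 8, seed=6)
        np.testing.assert_array_equal(a.weight_flat, b.weight_flat)
        np.testing.assert_array_equal(a.lengths, b.lengths)
        assert not np.array_equal(a.weight_flat, c.weight_flat)

    def test_length_distribution_uniform_over_7_9_11(self):
        bank = generate_kernels(10_000, 50, 4, seed=1)
        counts = [int(np.sum(bank.lengths == l)) for l in (7, 9, 11)]
        assert sum(counts) == 10_000
        assert stats.chisquare(counts).pvalue > 0.001

    def test_kernel_invariants(self):
        bank = generate_kernels(300, 50, 12, seed=2)
        for k in range(len(bank)):
            ker = bank.kernel(k)
            assert ker.length in (7, 9, 11)
            assert abs(ker.weights.mean()) < 1e-9
            assert -1.0 <= ker.bias <= 1.0
            assert np.all(np.diff(ker.channel_subset) > 0)
            assert 1 <= len(ker.channel_subset) <= 12
            if not ker.use_padding:
                assert (ker.length - 1) * ker.dilation + 1 <= bank.input_length

    def test_invalid_channel_count_rejected(self):
        with pytest.raises(ValueError):
            generate_kernels(10, 50, 0, seed=0)


class TestApplyKernel:
    def two_tap(self, weights, bias=0.0, dilation=1, padding=False):
        return Kernel(
            length=2,
            channel_subset=np.array([0]),
            weights=np.array([weights]),
            bias=bias,
            dilation=dilation,
            use_padding=padding,
        )

    def test_all_zero_input_zero_bias(self):
        bank = generate_kernels(20, 50, 3, seed=3)
        X = np.zeros((50, 3))
        for k in range(len(bank)):
            ker = bank.kernel(k)
            ppv, mx = apply_kernel(X, ker)
            if ker.bias > 0:
                assert (ppv, mx) == (1.0, ker.bias)
            elif ker.bias < 0:
                assert ppv == 0.0 and mx == ker.bias

    def test_bias_only_output(self):
        ker = self.two_tap([1.0, -1.0], bias=1.0)
        assert apply_kernel(np.zeros((5, 1)), ker) == (1.0, 1.0)

    def test_hand_convolution(self):
        # series [1, 0, -1] * centred weights [1, -1] -> outputs [1, 1]
        ker = self.two_tap([1.0, -1.0])
        x = np.array([[1.0], [0.0], [-1.0]])
        ppv, mx = apply_kernel(x, ker)
        assert (ppv, mx) == (1.0, 1.0)


class TestTransform:
    def test_feature_count_is_twice_kernel_count(self):
        bank = generate_kernels(1, 50, 2, seed=4)
        X = np.random.default_rng(0).normal(size=(3, 50, 2))
        F = transform(X, bank)
        assert F.values.shape == (3, 2)
        assert isinstance(F.provenance, RocketProvenance)
        assert F.provenance.feature_info(0) == (0, "ppv")
        assert F.provenance.feature_info(1) == (0, "max")

    def test_matches_naive_loop_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(9)
        for trial in range(12):
            L = int(rng.integers(11, 13))
            C = int(rng.integers(1, 5))
            n = int(rng.integers(1, 4))
            bank = generate_kernels(int(rng.integers(1, 21)), L, C, seed=trial)
            X = rng.normal(size=(n, L, C))
            np.testing.assert_allclose(
                transform(X, bank).values, naive_transform(X, bank), atol=1e-10
            )

    def test_transform_equals_per_sample_apply_kernel(self):
        bank = generate_kernels(15, 20, 3, seed=8)
        X = np.random.default_rng(1).normal(size=(4, 20, 3))
        F = transform(X, bank).values
        for s in range(4):
            for k in range(len(bank)):
                ppv, mx = apply_kernel(X[s], bank.kernel(k))
                assert F[s, 2 * k] == pytest.approx(ppv, abs=1e-12)
                assert F[s, 2 * k + 1] == pytest.approx(mx, abs=1e-12)

    def test_ppv_in_unit_interval_and_scale_invariant_at_zero_bias(self):
        bank = generate_kernels(100, 30, 4, seed=10)
        # force zero bias so the sign pattern is positively homogeneous
        object.__setattr__(bank, "biases", np.zeros_like(bank.biases))
        X = np.random.default_rng(2).normal(size=(5, 30, 4))
        F1 = transform(X, bank).values
        F2 = transform(3.7 * X, bank).values
        ppv1, ppv2 = F1[:, ::2], F2[:, ::2]
        assert ppv1.min() >= 0.0 and ppv1.max() <= 1.0
        np.testing.assert_array_equal(ppv1, ppv2)

    def test_row_order_follows_sample_order(self):
        bank = generate_kernels(10, 20, 2, seed=11)
        X = np.random.default_rng(3).normal(size=(3, 20, 2))
        F = transform(X, bank).values
        F_perm = transform(X[::-1], bank).values
        np.testing.assert_array_equal(F[::-1], F_perm)

    def test_shape_mismatch_rejected(self):
        bank = generate_kernels(5, 50, 4, seed=12)
        with pytest.raises(ValueError, match="bank expects"):
            transform(np.zeros((2, 40, 4)), bank)

    def test_padded_tensor_inputs_accepted(self):
        bank = generate_kernels(5, 50, 2, seed=13)
        tensors = [pad_to(np.random.default_rng(4).normal(size=(30, 2)), 50)]
        assert transform(tensors, bank).values.shape == (1, 10)


def test_bank_round_trip_is_bit_exact(tmp_path):
    bank = generate_kernels(64, 50, 6, seed=14)
    path = tmp_path / "bank.h5"
    save_kernel_bank(bank, path)
    loaded = load_kernel_bank(path)
    for name in ("lengths", "dilations", "paddings", "biases",
                 "channel_offsets", "channel_flat", "weight_offsets", "weight_flat"):
        np.testing.assert_array_equal(getattr(bank, name), getattr(loaded, name))
    X = np.random.default_rng(5).normal(size=(2, 50, 6))
    np.testing.assert_array_equal(transform(X, bank).values, transform(X, loaded).values)
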
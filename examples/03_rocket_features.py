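"""The random convolutional kernel transform.

Thousands of random kernels (length 7/9/11, mean-centred normal weights,
random dilation, bias and channel subset) are convolved along the
residue axis of each padded representation; each kernel is summarized by
the proportion of positive values (ppv) and the maximum, so K kernels
give 2K features per peptide.  The bank is fully determined by its seed
and can be frozen to disk for reproducible pipelines.
"""

import tempfile
from pathlib import Path

import numpy as np

from cyspresso import rocket

rng = np.random.default_rng(0)
X = rng.normal(size=(3, 50, 16))  # 3 peptides, 50 padded residues, 16 channels

bank = rocket.generate_kernels(n_kernels=500, input_length=50, n_channels=16, seed=42)
features = rocket.transform(X, bank)
print("feature matrix:", features.values.shape, "(2 features per kernel)")

ppv = features.values[:, ::2]
print(f"ppv range: [{ppv.min():.3f}, {ppv.max():.3f}] (always within [0, 1])")
print("first kernel:", bank.kernel(0).length, "taps,",
      len(bank.kernel(0).channel_subset), "channels,",
      "dilation", bank.kernel(0).dilation)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "bank.h5"
    rocket.save_kernel_bank(bank, path)
    reloaded = rocket.load_kernel_bank(path)
    identical = np.array_equal(
        rocket.transform(X, reloaded).values, features.values
    )
print("bank round-trip reproduces features exactly:", identical)
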
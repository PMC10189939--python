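"""Shared fixtures: synthetic datasets and expensive fitted models.

Everything is generated programmatically at collection time; there are no
stored data files.  Session scope is used for the large planted-signal
dataset and the forest attribution built on it, which several tests share.
"""

from __future__ import annotations

import numpy as np
import pytest

from cyspresso import interpretability, models, pipeline, synthetic


@pytest.fixture(scope="session")
def ds_small_signal():
    """Small planted-signal dataset for fast mechanics tests."""
    return synthetic.generate(
        synthetic.SyntheticConfig(n_samples=60, effect_size=2.0, seed=7)
    )


@pytest.fixture(scope="session")
def ds_signal300():
    """Planted-signal dataset at study scale: delta=2 at positions {7,8,9},
    8 channels of the single block, n=300."""
    return synthetic.generate(
        synthetic.SyntheticConfig(n_samples=300, effect_size=2.0, seed=11)
    )


@pytest.fixture(scope="session")
def ds_null300():
    """Null dataset (delta=0): labels independent of all features."""
    return synthetic.generate(
        synthetic.SyntheticConfig(n_samples=300, effect_size=0.0, seed=12)
    )


@pytest.fixture(scope="session")
def signal_forest_attribution(ds_signal300):
    """Forest on flattened 50x1152 tensors of the signal dataset, with its
    exact Shapley attributions — shared by the interpretability checks."""
    X, lengths = pipeline.flattened_features(
        ds_signal300.records, ds_signal300.representations
    )
    model = models.fit(
        models.ClassifierSpec("random_forest", seed=0), X, ds_signal300.labels
    )
    attr = interpretability.attribute(model, X)
    return {"X": X, "lengths": lengths, "model": model, "attr": attr}
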
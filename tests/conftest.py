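import numpy as np
import pytest

import myostiff as ms


@pytest.fixture(scope="session")
def parents():
    return ms.make_parent_library(25, seed=11)


@pytest.fixture(scope="session")
def reference_cylinder(parents):
    geom = ms.resize(parents[0], 1.0, 1.0)
    return ms.equivalent_cylinder(geom)


@pytest.fixture(scope="session")
def reference_fibers():
    return ms.fiber_layers(np.deg2rad(60.0), np.deg2rad(-60.0))


@pytest.fixture(scope="session")
def small_corpus(parents):
    """A 240-example corpus with a 40-example test split (fast, shared)."""
    samples = ms.lhs_sample(240, seed=7, n_parents=len(parents))
    ds = ms.build_dataset(parents, samples)
    ms.split(ds, n_test=40, seed=5)
    return ds


@pytest.fixture(scope="session")
def study():
    """The scaled training study shared by the acceptance checks.

    1,200 Latin-hypercube examples over the stated design ranges, 100-example
    test split, 2x512 ReLU network, Adam 1e-4, batch 32, MAE loss,
    best-validation checkpoint over 2,000 epochs; identical hyperparameters
    for the reduced-feature retraining.
    """
    cfg = ms.StudyConfig(
        n_samples=1200, n_test=100,
        surrogate=ms.SurrogateConfig(hidden_layers=2, units=512,
                                     epochs=2000, seed=0))
    return ms.run_training_study(cfg)
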
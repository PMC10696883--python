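import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_fit():
    """A quickly trained classifier on a small planted-motif dataset.

    Shared by tests that need any reasonably discriminative trained model
    (not the full default study conditions, which the acceptance tests
    train separately).
    """
    from crnn_tfbs.crnn import BindingClassifier, ModelConfig
    from crnn_tfbs.negatives import build_balanced_dataset, split_dataset
    from crnn_tfbs.synthdata import SyntheticConfig, simulate_reads

    scfg = SyntheticConfig(n_reads=900, seed=42)
    reads, _ = simulate_reads(scfg)
    dataset = build_balanced_dataset(reads, seed=42)
    train, val, test = split_dataset(dataset, seed=42)
    model = BindingClassifier(ModelConfig(max_epochs=15, patience=4, seed=42))
    fit = model.fit(train, val)
    return {"model": model, "fit": fit, "train": train, "val": val, "test": test}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
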
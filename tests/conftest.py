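import pandas as pd
import pytest

from cppsig.cpp_core import CPPConfig, run_cpp
from cppsig.io import labels_series
from cppsig.synthetic_data import SynthConfig, generate_dataset, generate_scaleset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signature dataset shared across test modules."""
    cfg = SynthConfig(n_pos=30, n_neg=10, n_unlabeled=120, effect_size=1.0, seed=11)
    entries, truth = generate_dataset(cfg)
    return entries, truth, cfg


@pytest.fixture(scope="session")
def small_scaleset():
    return generate_scaleset(n_scales=12, n_subcategories=4, seed=7)


@pytest.fixture(scope="session")
def small_cpp(small_dataset, small_scaleset):
    entries, truth, _ = small_dataset
    test_ids = [e.id for e in entries if e.label.value == "positive"]
    ref_ids = [e.id for e in entries if e.label.value == "unlabeled"]
    res = run_cpp(
        entries, small_scaleset, test_ids, ref_ids, CPPConfig(n_filter=40)
    )
    return res


@pytest.fixture(scope="session")
def small_training(small_dataset, small_cpp):
    """Balanced feature matrix and 0/1 labels for the labeled samples."""
    entries, _, _ = small_dataset
    labels = labels_series(entries)
    keep = labels[labels.isin(["positive", "negative"])]
    X = small_cpp.matrix.loc[keep.index, [f.feature_id for f in small_cpp.features]]
    y = (keep == "positive").astype(int)
    return X, y
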
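import numpy as np
import pytest

from readerbias import DatasetSpec, ImageSpec, generate_dataset
from readerbias.synthetic import manifest_rows


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small on-disk dataset: 20/class train, 5/class val, 10+10 test."""
    root = tmp_path_factory.mktemp("tiny_ds")
    spec = DatasetSpec(
        n_train_per_class=20, n_val_per_class=5, n_test=(10, 10), seed=3
    )
    manifest = generate_dataset(spec, root)
    return spec, manifest, root


@pytest.fixture()
def balanced_labels():
    """An in-memory 500/500 balanced training manifest (no image files)."""
    spec = DatasetSpec(n_train_per_class=500, n_val_per_class=109, n_test=(234, 390))
    return manifest_rows(spec)


@pytest.fixture(scope="session")
def separable_dataset(tmp_path_factory):
    """A nearly noise-free, high-contrast dataset a classifier can overfit."""
    root = tmp_path_factory.mktemp("separable_ds")
    spec = DatasetSpec(
        n_train_per_class=20,
        n_val_per_class=5,
        n_test=(10, 10),
        seed=11,
        image_spec=ImageSpec(noise_sd=0.02, blob_amplitude=0.4),
    )
    manifest = generate_dataset(spec, root)
    return spec, manifest, root
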
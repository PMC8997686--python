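import numpy as np
import pytest

from bcgnet import SynthConfig, build_epoch_dataset, build_filterbank, generate_dataset
from bcgnet.scalogram import epochs_to_array


@pytest.fixture(scope="session")
def study_dataset():
    """Default separable study conditions: 100 subjects, 2 min each, seed 42.

    Returns (records, epoch_dataset, images, labels); shared across the
    end-to-end tests so the scalograms are rendered once per session.
    """
    cfg = SynthConfig(n_hc=50, n_hpt=50, duration=120.0, seed=42)
    records, _ = generate_dataset(cfg)
    ds = build_epoch_dataset(records)
    bank = build_filterbank(fs=cfg.fs, n_samples=len(ds.epochs[0].samples))
    images = epochs_to_array(ds.epochs, bank)
    labels = [e.label for e in ds.epochs]
    return records, ds, images, labels


@pytest.fixture(scope="session")
def small_images(study_dataset):
    """A balanced 40-image slice for quick training smoke tests."""
    _, _, images, labels = study_dataset
    labels = np.array(labels)
    hc = np.flatnonzero(labels == "HC")[:20]
    hpt = np.flatnonzero(labels == "HPT")[:20]
    idx = np.concatenate([hc, hpt])
    return images[idx], [labels[i] for i in idx]
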
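"""Shared fixtures. The expensive trained-model fixtures are session-scoped
and shared between the unit tests and the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from svpnet import classifiers as cls
from svpnet import cropper, localizer, phantom


def small_localizer_config(**overrides) -> localizer.LocalizerConfig:
    base = dict(depth=3, base_filters=4, input_size=128, recurrence_steps=1,
                learning_rate=0.003, batch_size=6, epochs=15,
                optimizer="rmsprop", seed=7)
    base.update(overrides)
    return localizer.LocalizerConfig(**base)


def clips_to_classifier_inputs(labeled_clips, margin=cropper.DEFAULT_MARGIN):
    """Ground-truth-region crops: phantom clips -> (X, y) arrays."""
    x, y = [], []
    for lc in labeled_clips:
        region = cropper.mask_to_region(phantom.ellipse_mask(lc.spec), margin)
        x.append(cropper.crop_clip(lc.clip, region))
        y.append(lc.label)
    return np.stack(x), cls.labels_to_ints(y)


@pytest.fixture(scope="session")
def phantom_images_40():
    images, _ = phantom.make_dataset(40, 0, seed=123)
    return images


@pytest.fixture(scope="session")
def trained_localizer(phantom_images_40):
    """Criterion-scale pilot: 40 images, small config, 15 epochs."""
    config = small_localizer_config()
    model, history = localizer.train_localizer(phantom_images_40, config)
    return model, history


@pytest.fixture(scope="session")
def clip_dataset_80():
    """80 balanced phantom clips, a=0.4, mild noise, cropped to contract."""
    base = phantom.PhantomSpec(pulsation_amplitude=0.4, noise_sd=0.02,
                               duration=1.0)
    _, labeled = phantom.make_dataset(0, 80, base_spec=base, seed=42)
    x, y = clips_to_classifier_inputs(labeled)
    return x, y, labeled


@pytest.fixture(scope="session")
def trained_convlstm(clip_dataset_80):
    """Criterion-scale pilot ConvLSTM: 60 train / 20 held out, 15 epochs."""
    x, y, _ = clip_dataset_80
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    train_idx, test_idx = perm[:60], perm[60:]
    cfg = cls.ClassifierConfig(architecture="convlstm", preset="small",
                               epochs=15, batch_size=10, seed=1)
    model = cls.build_classifier(cfg)
    model, history = cls.train_classifier(model, x[train_idx], y[train_idx], cfg)
    return model, history, train_idx, test_idx


@pytest.fixture(scope="session")
def easy_smoke_dataset():
    """Easier phantoms (a=0.5, low noise) for per-architecture smoke tests."""
    base = phantom.PhantomSpec(pulsation_amplitude=0.5, noise_sd=0.01,
                               duration=1.0)
    _, labeled = phantom.make_dataset(0, 48, base_spec=base, seed=5)
    x, y = clips_to_classifier_inputs(labeled)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    return x, y, perm[:36], perm[36:]
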
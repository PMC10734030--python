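"""Shared fixtures: a small separated synthetic cohort, featurized image
sets, and a pair of trained tinycnn models reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from voicescreen.audio_io import load_manifest
from voicescreen.classifier import TrainConfig, train_backbone
from voicescreen.pipeline import featurize_manifest
from voicescreen.segmentation import WindowingParams
from voicescreen.spectrogram import MelParams
from voicescreen.synthetic_voice import CohortSpec, synth_cohort


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """3 pass + 3 fail participants, 1 repetition per vowel (30 clips)."""
    out = tmp_path_factory.mktemp("cohort")
    synth_cohort(CohortSpec(n_pass=3, n_fail=3, vowels_per_participant=1, seed=11), out)
    return out


@pytest.fixture(scope="session")
def small_manifest(small_cohort_dir):
    return load_manifest(small_cohort_dir / "manifest.csv")


@pytest.fixture(scope="session")
def small_sets(small_manifest):
    """(train, test) image sets: first 4 participants train, last 2 test."""
    pids = small_manifest.participants
    train, _ = featurize_manifest(
        small_manifest, WindowingParams(), MelParams(), "rgb", pids[:4])
    test, _ = featurize_manifest(
        small_manifest, WindowingParams(), MelParams(), "rgb", pids[4:])
    return train, test


@pytest.fixture(scope="session")
def trained_pair(small_sets):
    """Two tinycnn models fitted on the small cohort with different seeds."""
    train_set, _ = small_sets
    models = []
    for seed in (0, 1):
        config = TrainConfig.for_backbone("tinycnn", seed=seed)
        models.append(train_backbone("tinycnn", train_set, config, seed=seed))
    return models


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
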
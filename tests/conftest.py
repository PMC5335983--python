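"""Shared fixtures: the heavy simulation studies run once per session."""

import numpy as np
import pytest

import beatset as bs
from beatset.evaluation import ExperimentConfig, cap_training, contaminated_cluster_study, split_trials
from beatset.features import FeatureTable

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """The 10-trial distorted-cluster robustness study (shared splits)."""
    return contaminated_cluster_study(seed=STUDY_SEED, n_trials=10)


@pytest.fixture(scope="session")
def study_training_table():
    """The capped training half of the study's first trial."""
    spec = bs.default_cluster_spec()
    features = bs.simulate_feature_clusters(spec, [120] * spec.n_classes, seed=STUDY_SEED)
    labels = np.array([str(s) for s in features.labels], dtype=object)
    cfg = ExperimentConfig(n_trials=1, set_size=20, small_class_set_size={}, seed=STUDY_SEED)
    train_idx, _ = split_trials(labels, cfg)[0]
    rng = np.random.default_rng(np.random.SeedSequence([STUDY_SEED, 0, 1]))
    capped = cap_training(train_idx, labels, cfg.cap, rng)
    return FeatureTable(matrix=features.matrix[capped], labels=labels[capped])


@pytest.fixture(scope="session")
def study_model(study_training_table):
    """The ranking metric trained on the study's first-trial training half."""
    return bs.train(study_training_table)


@pytest.fixture(scope="session")
def clean_cluster_features():
    """Distorted (uncontaminated) clusters, small scale."""
    spec = bs.default_cluster_spec()
    return bs.simulate_feature_clusters(spec, [60] * spec.n_classes, seed=11)


@pytest.fixture(scope="session")
def beat_feature_table():
    """Synthetic four-class beats through the default wavelet encoding."""
    beats = bs.simulate_beats(bs.default_beat_specs(), [200] * 4, 235, seed=7)
    return bs.featurize_table(beats, bs.WaveletConfig())
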
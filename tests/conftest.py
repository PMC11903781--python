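import numpy as np
import pytest

from sdstrip import classifier, preprocess, synthetic

# Scaled-down cohort used for end-to-end tests: 8-Hz native rate and 3-h
# recordings keep the suite inside the CI budget while preserving every
# pipeline stage (the 0.5-Hz FIR and 1-Hz decimation behave identically).
COHORT_KW = dict(
    n_subjects=5,
    channels_per_subject=6,
    duration_s=10800.0,
    fs=8.0,
    sd_rate_per_hour=4.0,
    seed=1,
)


@pytest.fixture(scope="session")
def cohort():
    return synthetic.generate_cohort(synthetic.GeneratorSpec(**COHORT_KW))


@pytest.fixture(scope="session")
def preprocessed_cohort(cohort):
    return [(preprocess.preprocess_recording(rec), ann) for rec, ann in cohort]


@pytest.fixture(scope="session")
def training_set(preprocessed_cohort):
    sets = [classifier.build_training_set(rec, ann) for rec, ann in preprocessed_cohort]
    return classifier.concat_training_sets(sets)


@pytest.fixture(scope="session")
def trained_model(training_set):
    cfg = classifier.ModelConfig(random_seed=1)
    ranking = classifier.rank_features(training_set, cfg)
    selected = classifier.select_top_k(ranking, cfg.k_features)
    return classifier.train(training_set, cfg, selected)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
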
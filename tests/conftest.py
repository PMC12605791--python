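import logging

import numpy as np
import pytest

import hsdetect as h

# ratio-cap / clamp warnings are expected all over synthetic cohorts
logging.getLogger("hsdetect.flair").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return h.SyntheticConfig(n_reference=60, n_controls=12, n_left_hs=6,
                             n_right_hs=6, seed=7)


@pytest.fixture(scope="session")
def ref_cohort(small_config):
    return h.make_reference_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def norm_model(ref_cohort):
    return h.fit_normalization(ref_cohort)


@pytest.fixture(scope="session")
def patient_cohort(small_config):
    return h.make_patient_cohort(small_config, seed=13)


@pytest.fixture(scope="session")
def subject_features(patient_cohort, norm_model):
    """Assembled 128-feature vectors for the small patient cohort."""
    subjects, flair_blocks, labels = patient_cohort
    return [
        h.assemble(h.compute_volume_block(s, norm_model), fb,
                   subject_id=s.subject_id, label=lab)
        for s, fb, lab in zip(subjects, flair_blocks, labels)
    ]


@pytest.fixture(scope="session")
def dataset_128(subject_features):
    return h.build_dataset(subject_features, h.SCHEMA_VOL_FLAIR_128)


@pytest.fixture(scope="session")
def phantom_pair(small_config):
    return h.make_image_phantom(small_config, seed=17, hs_side="left")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
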
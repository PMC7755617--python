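"""Shared fixtures: phantom subjects and derived maps, built once per session."""

import numpy as np
import pytest
from hypothesis import settings

import hippoquant as hq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_subject() -> hq.PhantomSubject:
    """Symmetric, lesion-free, noise-free subject: the exact-recovery case."""
    acq = hq.AcquisitionSpec(noise_sigma=0.0, seed=0)
    return hq.make_phantom_subject(
        hq.HippocampusSpec(side="left"), hq.HippocampusSpec(side="right"), acq
    )


@pytest.fixture(scope="session")
def unilateral_subject() -> hq.PhantomSubject:
    """Left atrophy 0.7 with 10% left T2 elevation, 1% noise: the classic
    unilateral disease pattern at the visual-detection threshold."""
    acq = hq.AcquisitionSpec(noise_sigma=10.0, seed=7)
    return hq.make_phantom_subject(
        hq.HippocampusSpec(side="left", atrophy_factor=0.7, t2_elevation=1.10),
        hq.HippocampusSpec(side="right"),
        acq,
    )


def _t2map_for(subject: hq.PhantomSubject) -> hq.T2Map:
    roi = (subject.mask_left.data | subject.mask_right.data).astype(bool)
    return hq.compute_t2_map(subject.echo1, subject.echo2, roi=roi)


@pytest.fixture(scope="session")
def noise_free_t2map(noise_free_subject) -> hq.T2Map:
    return _t2map_for(noise_free_subject)


@pytest.fixture(scope="session")
def unilateral_t2map(unilateral_subject) -> hq.T2Map:
    return _t2map_for(unilateral_subject)


@pytest.fixture(scope="session")
def cohort_model() -> hq.NormativeModel:
    """Normative model from a 20-subject imaged phantom cohort (with profiles)."""
    subjects = hq.make_reference_cohort(20, seed=42, acq=hq.AcquisitionSpec(noise_sigma=10.0))
    cohort = []
    for sub in subjects:
        t2map = _t2map_for(sub)
        metrics = hq.compute_global_metrics(sub.mask_left, sub.mask_right, t2map)
        profiles = {
            m.side: hq.profile(m, t2map, hq.long_axis_frame(m)) for m in (sub.mask_left, sub.mask_right)
        }
        cohort.append((metrics, profiles))
    return hq.build_normative(cohort, min_n=20, seed=42)


@pytest.fixture(scope="session")
def study_data():
    """One simulated paired rater study under the default design."""
    return hq.simulate_rater_study(seed=5)


@pytest.fixture(scope="session")
def study_result(study_data):
    table, gold = study_data
    return hq.analyze_study(table, gold)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
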
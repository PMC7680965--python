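import numpy as np
import pytest

from pdgait.config import PipelineConfig
from pdgait.synthetic_gait import GaitSimParams, simulate_cohort, simulate_record
from pdgait.vgrf_io import SubjectMeta


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free healthy walking record with ground-truth events."""
    return simulate_record(GaitSimParams(n_steps=12, seed=7))


@pytest.fixture(scope="session")
def noisy_record():
    """Healthy record with realistic sensor noise."""
    return simulate_record(GaitSimParams(n_steps=12, noise_sigma=2.0, seed=11))


@pytest.fixture(scope="session")
def pd_record():
    """Moderately affected parkinsonian record (longer strides, flattened)."""
    return simulate_record(
        GaitSimParams(
            n_steps=12, severity=0.7, stance_fraction=0.675, asymmetry=0.35,
            flatten=0.42, gct_cv=0.05, noise_sigma=2.0, seed=13,
        )
    )


@pytest.fixture(scope="session")
def default_meta():
    return SubjectMeta(
        subject_id="sim", group="CONTROL", weight_kg=72.0,
        walking_speed_m_per_s=1.2,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small labelled cohort for pipeline-level tests."""
    base = GaitSimParams(n_steps=18, noise_sigma=2.0)
    records, metas = simulate_cohort(
        8, {2.0: 5, 2.5: 4, 3.0: 3}, base, seed=42
    )
    return records, metas


@pytest.fixture
def config():
    return PipelineConfig(seed=0)


@pytest.fixture(scope="session")
def separable_clusters():
    """Two Gaussian clusters 10 sigma apart: any sane classifier is perfect."""
    rng = np.random.default_rng(0)
    n = 100
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n, 2)),
        rng.normal(10.0, 1.0, size=(n, 2)),
    ])
    y = np.array(["A"] * n + ["B"] * n)
    return X, y
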
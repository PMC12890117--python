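import numpy as np
import pytest

from atflow import AssayGroundTruth, FlowVideoSpec, ParticleImageSpec


@pytest.fixture
def plasma_gt() -> AssayGroundTruth:
    """Default (diluted-plasma) ground truth: slope 0.540, intercept 0.040,
    equivalence at 19 ng/mL."""
    return AssayGroundTruth()


@pytest.fixture
def noiseless_gt() -> AssayGroundTruth:
    return AssayGroundTruth(noise_sd_v=0.0)


@pytest.fixture
def small_video_spec() -> FlowVideoSpec:
    return FlowVideoSpec(n_frames=50, idle_frames=0, channel_length_px=150)


@pytest.fixture
def clean_image_spec() -> ParticleImageSpec:
    """Noise-free micrograph spec: planted totals are recoverable exactly."""
    return ParticleImageSpec(
        background_mean=0.0, background_sd=0.0, n_clusters=4, n_singles=20, seed=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
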
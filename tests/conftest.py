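import numpy as np
import pytest

from mtfse import (
    CohortSpec,
    HRVSegment,
    PipelineConfig,
    build_tfsi,
    extract_features,
    generate_cohort,
    generate_rr,
)
from mtfse.synthetic import SynthConfig


@pytest.fixture(scope="session")
def cohort_features():
    """Feature matrix of the default apnea-like vs normal-like synthetic cohort
    (100 segments per group, seed fixed a priori). Shared across tests because
    generation is the most expensive step of the suite."""
    spec = CohortSpec(n_per_group=100, seed=7)
    return extract_features(generate_cohort(spec))


@pytest.fixture(scope="session")
def lf_segment():
    """One preprocessed segment with a dominant 0.10 Hz (LF) oscillation."""
    return _single_tone_segment(freq=0.10, seed=21)


@pytest.fixture(scope="session")
def lf_tfsi(lf_segment):
    return build_tfsi(lf_segment)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def _single_tone_segment(
    freq: float, seed: int, amp: float = 50.0, noise_sd: float = 2.0
) -> HRVSegment:
    from mtfse import interpolate_resample, remove_artifacts, segment_and_label

    cfg = SynthConfig(
        mean_rr=800.0,
        osc_components=((freq, amp, 0.0),),
        noise_sd=noise_sd,
        seed=seed,
    )
    rr, ann = generate_rr(cfg)
    windows = segment_and_label(remove_artifacts(rr), ann, "C")
    return interpolate_resample(windows[0])


@pytest.fixture
def single_tone_segment():
    """Factory for segments dominated by one oscillator frequency."""
    return _single_tone_segment


@pytest.fixture
def constant_rr_series():
    from mtfse import RRSeries

    return RRSeries.from_intervals(0.0, np.full(500, 800.0), record_id="const")
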
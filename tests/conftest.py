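import numpy as np
import pytest

from fvquant import LineSpec, MeasurementProfile, extract_line_profile
from fvquant.presets import RAT_STAGE_PARAMS
from fvquant.synthetic import StageParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def control_params():
    return RAT_STAGE_PARAMS["Control"]


@pytest.fixture
def flat_params():
    """Degenerate noise-free stage: every pixel equals the stage mean."""
    return StageParams(
        stage_label="Flat", mean_g=100.0, between_sd=0.0, within_sd=0.0,
        axial_slope=0.0, spot_rate=0.0, n_animals=1,
    )


def profile_from_values(values, stage=None, sample_id=None):
    values = np.asarray(values, dtype=float)
    return MeasurementProfile(
        values=values, positions=np.arange(values.size, dtype=float),
        stage_label=stage, sample_id=sample_id,
    )


def midline_profile(image, n=None, **kw):
    h, w = image.shape
    n = n or w
    line = LineSpec(start=(0, h // 2), end=(w - 1, h // 2), n_points=n)
    return extract_line_profile(image, line, **kw)


@pytest.fixture
def make_profile():
    return profile_from_values


@pytest.fixture
def make_midline_profile():
    return midline_profile
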
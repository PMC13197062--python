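import numpy as np
import pytest

from cplp import (Cohort, ImageEncoder, ImageEncoderConfig, SynthConfig,
                  TextHead, TextHeadConfig, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient, 16-dim cohort shared by fast tests."""
    cohort, latents = generate_cohort(
        SynthConfig(n_patients=120, feature_dim=16, seed=42))
    return cohort, latents


@pytest.fixture()
def tiny_encoders():
    """Matched 16-dim image/text heads with a fixed init."""
    rng = np.random.default_rng(7)
    img_cfg = ImageEncoderConfig(model_dim=16, heads=4, feedforward_dim=32,
                                 projection_dim=16)
    txt_cfg = TextHeadConfig(input_dim=16, hidden=(32,), projection_dim=16)
    return ImageEncoder(img_cfg, rng), TextHead(txt_cfg, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
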
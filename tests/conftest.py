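import numpy as np
import pytest

from restransnet.model import ModelConfig, ResTransNet
from restransnet.preprocess import LabeledSample, RoiImage
from restransnet.synthetic import SyntheticCohortSpec, generate_synthetic_cohort


def tiny_config(**overrides) -> ModelConfig:
    """A desk-test model small enough for sub-second steps."""
    kwargs = dict(channels=(2, 4, 8), depth=1, embed_dim=16, n_heads=2, seed=0)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture
def tiny_model() -> ResTransNet:
    return ResTransNet(tiny_config())


@pytest.fixture(scope="session")
def small_cohort():
    """24 patients, one image each, strong class signal, with survival."""
    spec = SyntheticCohortSpec(n_patients=24, images_per_patient=(1, 1),
                               prevalence=0.35, effect_size=3.0, seed=7)
    return generate_synthetic_cohort(spec)


def make_sample(pixels: np.ndarray, patient: str = "P1",
                label: int = 0) -> LabeledSample:
    return LabeledSample(image=RoiImage(pixels=pixels.astype(np.float32)),
                        patient_id=patient, label=label)
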
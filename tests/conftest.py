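import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "masknano",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("masknano")


@pytest.fixture(scope="session")
def survey():
    """Packaged 12-mask survey: (masks, reference frame)."""
    from masknano import load_mask_survey

    return load_mask_survey()


@pytest.fixture(scope="session")
def default_image():
    """One synthetic image at generator defaults, with ground truth."""
    from masknano import SyntheticImageSpec, generate_image

    spec = SyntheticImageSpec(seed=42)
    image, truth = generate_image(spec)
    return spec, image, truth
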
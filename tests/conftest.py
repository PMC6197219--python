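import pytest

from vnc2p.synthetic import (
    SyntheticConfig,
    make_ground_truth,
    make_structural_template,
    render_movie,
)


@pytest.fixture(scope="session")
def clean_config():
    """Deformation-free, noise-free configuration for exact-value tests."""
    return SyntheticConfig(rng_seed=1, deformation_amplitude=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def template(clean_config):
    return make_structural_template(clean_config)


@pytest.fixture(scope="session")
def deformed_recording():
    """Small deformed noisy movie with ground-truth fields (registration tests)."""
    cfg = SyntheticConfig(
        rng_seed=2, deformation_amplitude=3.0, deformation_smoothness=8.0,
        noise_sd=20.0, n_frames=12,
    )
    template = make_structural_template(cfg)
    truth = make_ground_truth(cfg)
    movie = render_movie(template, truth.true_fields, truth, cfg)
    return cfg, template, truth, movie
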
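import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from hotnode import PhantomSpec, degrade_to_native, generate, load_config


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy phantom at the study conditions, generated once per session."""
    spec = PhantomSpec(seed=7)
    ct, spect, truth = generate(spec)
    return spec, ct, spect, truth


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free phantom: deterministic geometry for exact-count assertions."""
    spec = PhantomSpec(seed=3, poisson_noise=False, ct_noise_sd_hu=0.0)
    ct, spect, truth = generate(spec)
    return spec, ct, spect, truth


@pytest.fixture(scope="session")
def detect_result(default_phantom):
    """Full pipeline output on the native-resolution default phantom."""
    from hotnode import run_detect
    spec, ct, spect, truth = default_phantom
    ct_n, spect_n = degrade_to_native(ct, spect)
    cfg = load_config(overrides={
        "classifier": {"landmark_plane_z_mm": truth.landmark_plane_z_mm}})
    return run_detect(ct_n, spect_n, cfg), truth, cfg
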
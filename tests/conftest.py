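import pytest
from hypothesis import HealthCheck, settings

import synergykit as sk

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def control_session():
    """One synthetic control visit (18 trials) with planted k=3 structure."""
    gen = sk.GeneratorConfig(n_synergies=3, noise_sd=0.02, seed=11)
    return sk.synthesize_session(gen, group="control", participant_id="C0")


@pytest.fixture(scope="session")
def sci_session():
    """One synthetic patient visit (36 trials, stim + no_stim) with a
    stimulation artifact on the iliopsoas channels."""
    gen = sk.GeneratorConfig(n_synergies=3, noise_sd=0.05,
                             artifact=sk.ArtifactSpec(rate_hz=30.0), seed=12)
    return sk.synthesize_session(gen, group="SCI", participant_id="S0")


@pytest.fixture(scope="session")
def prep_control(control_session):
    record, _ = control_session
    return sk.preprocess_session(record, sk.PipelineConfig())


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-restart config for tests that only need a rough fit."""
    return sk.PipelineConfig(n_restarts=10, nnmf_tol=1e-5, nnmf_max_iter=400)
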
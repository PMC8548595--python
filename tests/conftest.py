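import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_session():
    """One simulated pair with zero gaze noise, plus its ground truth."""
    from dyadgaze import SimConfig, generate_session

    cfg = SimConfig(gaze_noise_deg=0.0, seed=11)
    recording, truth = generate_session(cfg)
    return cfg, recording, truth


@pytest.fixture(scope="session")
def pipeline_table(noiseless_session):
    """Noiseless session pushed through segmentation + classification."""
    from dyadgaze import RunConfig
    from dyadgaze import io as dio
    from dyadgaze.pipeline import classify_trials, segment_session

    _, recording, truth = noiseless_session
    run = RunConfig()
    meta = dio.trial_metadata(truth)
    seg = segment_session(recording, meta, run)
    table = classify_trials(seg, meta, run)
    return run, seg, table, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
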
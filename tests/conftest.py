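import numpy as np
import pytest

from screenfree_bci.data import EpochSet
from screenfree_bci.preprocessing import (
    bandpass_and_resample,
    extract_epochs,
    reject_artifacts,
)
from screenfree_bci.simulate import SessionConfig, simulate_session


def random_spd(rng: np.random.Generator, n: int = 4) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T + 0.5 * n * np.eye(n)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of
    # which other tests ran before it
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_session() -> tuple[EpochSet, SessionConfig]:
    """A small heterogeneous session, preprocessed, shared across tests.

    8 trials (2 per target object), 250 ms SOA, simulated at 200 Hz to
    keep the suite fast; the decoding pipeline itself runs at 100 Hz as
    always.
    """
    cfg = SessionConfig(
        n_trials=8,
        rate=200.0,
        gains=(1.5, 1.2, 0.7, 0.5),
        latency_shifts_ms=(0.0, 0.0, 10.0, 25.0),
        seed=42,
    )
    rec, sched = simulate_session(cfg)
    ep = reject_artifacts(extract_epochs(bandpass_and_resample(rec), sched))
    return ep, cfg


@pytest.fixture(scope="session")
def small_models(small_session):
    """All three pipeline variants fitted on the small session."""
    from screenfree_bci.decoding import VARIANTS, fit_pipeline

    ep, _ = small_session
    return {v: fit_pipeline(v, ep) for v in VARIANTS}
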
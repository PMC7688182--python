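import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One fully featured synthetic session, shared across tests (read-only)."""
    from classtalk.simulate import SimConfig, generate_session

    return generate_session(SimConfig(session_minutes=10, seed=42), "c01")


@pytest.fixture(scope="session")
def clean_session():
    """Same session conditions but with a perfect ASR (no corruption)."""
    from classtalk.simulate import SimConfig, generate_session

    return generate_session(
        SimConfig(session_minutes=10, seed=42, wer_del=0.0, wer_sub=0.0), "c01"
    )


def random_track(rng, partner="adult", n_max=12, horizon_ms=120_000, dt=250):
    """A random valid interval track on a dt-aligned grid."""
    from classtalk.intervals import IntervalTrack

    n = int(rng.integers(0, n_max + 1))
    edges = np.sort(rng.integers(0, horizon_ms // dt, size=2 * n)) * dt
    ivs = [
        (int(a), int(b)) for a, b in zip(edges[::2], edges[1::2]) if b > a
    ]
    return IntervalTrack.from_intervals(partner, ivs)
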
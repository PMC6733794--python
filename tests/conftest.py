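import numpy as np
import pytest

from slwarn import RawEventTable, SSMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_events():
    return RawEventTable.from_records(
        "p1",
        [
            ("heart_rate", 0.1, 80.0),
            ("heart_rate", 0.3, 90.0),
            ("heart_rate", 1.2, 100.0),
            ("systolic_bp", 0.2, 120.0),
            ("systolic_bp", 2.4, 100.0),
        ],
    )


def random_params(rng, n, e, with_offsets=True) -> SSMParams:
    """Random valid parameter set (covariances built PSD by construction)."""
    Z = rng.normal(size=(n, e))
    A = rng.normal(size=(e, e))
    B = rng.normal(size=(n, n))
    C = rng.normal(size=(e, e))
    return SSMParams(
        Z=Z,
        a=rng.normal(size=n) if with_offsets else np.zeros(n),
        Q=A @ A.T + 0.3 * np.eye(e),
        R=B @ B.T + 0.3 * np.eye(n),
        pi=rng.normal(size=e),
        Lambda=C @ C.T + 0.1 * np.eye(e),
    )
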
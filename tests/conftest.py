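import numpy as np
import pytest

from imuquat.orientation import ImuTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rest_trace(n: int = 50, f: float = 1.0, acc=(0.0, 0.0, 1.0), label=None) -> ImuTrace:
    """A motionless upright trace: gravity along +z, zero rates."""
    return ImuTrace(
        t=np.arange(n) / f,
        acc=np.tile(np.asarray(acc, dtype=float), (n, 1)),
        gyro=np.zeros((n, 3)),
        f=f,
        label=label,
    )


@pytest.fixture
def upright_rest_trace():
    return rest_trace()
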
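import numpy as np
import pytest

from opmclean import SimConfig, simulate_session
from opmclean.simulate import count_peaks


@pytest.fixture(scope="session")
def short_session():
    """A 20-s synthetic session (2 epochs) with both artifact types active.

    Seed chosen so the normal-mode blink train has at least two events in
    each epoch (the typical condition; single-blink epochs are the sparse
    extreme and are exercised by the rate statistics elsewhere).
    """
    for seed in range(30):
        rec, truth = simulate_session(SimConfig(duration=20.0, seed=seed))
        ok = all(
            count_peaks(truth.blink_source[e * 10000 : (e + 1) * 10000]) >= 2
            for e in range(2)
        )
        if ok:
            return rec, truth
    raise RuntimeError("no seed in range produced >=2 blinks in every epoch")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
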
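import numpy as np
import pandas as pd
import pytest

from patchforage.agents import SessionConfig, SessionLog
from patchforage.schedules import Variant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_log(times, patches, rewarded=None, variant=Variant.EXPONENTIAL, kappa=1.0):
    """Build a SessionLog from explicit events for hand-computed examples."""
    times = list(times)
    if rewarded is None:
        rewarded = [True] * len(times)
    cfg = SessionConfig(
        variant=variant,
        kappa=kappa,
        seed=0,
        duration=float(times[-1]) if times else 0.0,
    )
    ev = pd.DataFrame({"t_s": times, "patch": list(patches), "rewarded": rewarded})
    ev["rewarded"] = ev["rewarded"].astype(bool)
    return SessionLog(cfg, ev)


@pytest.fixture
def hand_log():
    """The five-push example: F@1, F@3, M@5, M@6, F@9."""
    return make_log([1.0, 3.0, 5.0, 6.0, 9.0], ["fast", "fast", "med", "med", "fast"])
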
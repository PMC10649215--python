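import numpy as np
import pytest

import parafit as pf


@pytest.fixture(scope="session")
def qt_params() -> pf.DetectorParams:
    return pf.PROFILES["qtdb-250hz"]


@pytest.fixture(scope="session")
def mit_params() -> pf.DetectorParams:
    return pf.PROFILES["mitdb-360hz"]


def make_random_records(n: int, seed: int = 0, duration: float = 20.0):
    """Varied synthetic ECGs (heart rate, noise, wander differ per record)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        sp = pf.SynthParams(
            duration=duration,
            hr_mean=float(rng.uniform(50, 110)),
            hr_sd=float(rng.uniform(0, 6)),
            noise_sd=float(rng.uniform(0, 0.04)),
            baseline_amp=float(rng.uniform(0, 0.15)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(pf.generate(sp))
    return out


@pytest.fixture(scope="session")
def random_ecgs():
    return make_random_records(20, seed=1234)
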
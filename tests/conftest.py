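import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tapsonar import analyze, make_scenario

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 5000.0
C = 343.0
F0 = 40_000.0


@pytest.fixture(scope="session")
def analyzed():
    """Cached (scenario, report-dict) pairs so the recovery tests share runs."""
    cache = {}

    def get(name: str, seed: int, **kw):
        key = (name, seed, tuple(sorted(kw.items())))
        if key not in cache:
            scn = make_scenario(name, seed=seed, **kw)
            cache[key] = (scn, analyze(scn.signal).to_dict())
        return cache[key]

    return get


def tone(freq_hz: float, duration: float = 1.0, fs: float = FS,
         amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.exp(2j * np.pi * freq_hz * t)
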
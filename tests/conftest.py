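import numpy as np
import pytest
from hypothesis import settings

from beeforage import (
    CLOVER,
    OILSEED_RAPE,
    BeeParameters,
    Patch,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bee():
    """Table-default bee parameters (mean flight cost 0.056 J/s)."""
    return BeeParameters.default()


@pytest.fixture(scope="session")
def bee_cal():
    """Calibrated preset (mean flight cost 0.066 J/s)."""
    return BeeParameters.calibrated()


@pytest.fixture(scope="session")
def osr():
    return OILSEED_RAPE


@pytest.fixture(scope="session")
def clover():
    return CLOVER


@pytest.fixture
def make_osr_patch():
    """Factory for large oilseed-rape patches at a given distance."""

    def _make(pid="f0", D=100.0, A=5e4, **kw):
        return Patch(id=pid, rt=OILSEED_RAPE, A=A, D=D, **kw)

    return _make


def random_patch_list(rng, n_max=20):
    """Randomized mixed-resource patch list for fuzz tests."""
    n = rng.integers(1, n_max + 1)
    patches = []
    for k in range(n):
        rt = OILSEED_RAPE if rng.random() < 0.5 else CLOVER
        patches.append(
            Patch(
                id=f"p{k:02d}",
                rt=rt,
                A=float(rng.uniform(50, 2e5)),
                D=float(rng.uniform(12.5, 2500)),
                F=float(rng.uniform(0.05, 1.0) * rt.F0),
                treated=bool(rng.random() < 0.5),
            )
        )
    return patches
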
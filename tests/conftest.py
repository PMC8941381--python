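import numpy as np
import pytest

from fragkern.geometry import RingGeometry


@pytest.fixture(scope="session")
def rings8():
    return RingGeometry.for_side(8)


@pytest.fixture(scope="session")
def rings16():
    return RingGeometry.for_side(16)


@pytest.fixture(scope="session")
def rings32():
    return RingGeometry.for_side(32)


class ScriptedRNG:
    """Deterministic stand-in for a numpy Generator in mutation tests.

    ``uniforms`` feed the per-class mutation-probability draws, ``coins``
    the adjacent-class direction draws, ``magnitudes`` the realized m'
    values.  Shapes are broadcast to whatever the operator requests.
    """

    def __init__(self, uniforms, coins, magnitudes):
        self._uniforms = np.asarray(uniforms, dtype=float)
        self._coins = np.asarray(coins, dtype=float)
        self._magnitudes = np.asarray(magnitudes, dtype=float)
        self._calls = 0

    def random(self, size=None):
        out = self._uniforms if self._calls == 0 else self._coins
        self._calls += 1
        return np.broadcast_to(out, size).copy() if size else float(out)

    def uniform(self, low, high, size=None):
        return np.broadcast_to(self._magnitudes, size).copy()
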
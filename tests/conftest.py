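import pytest

from invfate import ModelParams


@pytest.fixture
def make_params():
    """Benchmark parameter factory: U=0.02, s=0.01, x=0.2, ntot=1e4.

    Dominance h in {0.25, 0.1, 0.05} gives expected captured loads
    Ux/(hs) of {1.6, 4, 8}.
    """

    def _make(h: float = 0.25, U: float = 0.02, x: float = 0.2, N: int = 10_000,
              s: float = 0.01, ntot: int = 10_000) -> ModelParams:
        return ModelParams.from_arm_rate(U=U, s=s, h=h, ntot=ntot, x=x, N=N)

    return _make


@pytest.fixture
def params25(make_params):
    return make_params(h=0.25)


@pytest.fixture
def params05(make_params):
    return make_params(h=0.05)
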
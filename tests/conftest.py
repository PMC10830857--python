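import pytest
from hypothesis import settings

from tomcg import make_custom, make_icg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def icg4():
    return make_icg(L=4, M=0.5, growth=2, split=0.8)


@pytest.fixture(scope="session")
def icg6():
    return make_icg(L=6, M=0.5, growth=2, split=0.8)


@pytest.fixture(scope="session")
def ccg4():
    """Synthetic constant-size centipede game (constant sum M = 1).

    The taker's share grows with the step (0.5, 0.6, 0.7, 0.8) and the
    pass-through mildly favours Player 1; stands in for a constant-sum
    experimental table, which users supply themselves.
    """
    return make_custom(
        schedule=[(0.5, 0.5), (0.4, 0.6), (0.7, 0.3), (0.2, 0.8)],
        pass_through=(0.6, 0.4),
    )
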
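import pytest

from fisherygame import BioeconomicParams, SocialParams, StockState


@pytest.fixture(scope="session")
def econ() -> BioeconomicParams:
    """Laguna shrimp-fishery default economics (P=23, q=0.023, c'=2e-5, f*=18)."""
    return BioeconomicParams()


@pytest.fixture(scope="session")
def stock03() -> StockState:
    """The invasion-experiment stock state: B'=0.3, r=1.0."""
    return StockState(B_prime=0.3, r=1.0)


@pytest.fixture(scope="session")
def good_social() -> SocialParams:
    """High control perception, high risk tolerance (favours cooperation)."""
    return SocialParams.symmetric(alpha=1.0, b=0.3)


@pytest.fixture(scope="session")
def bad_social() -> SocialParams:
    """Low control perception, low risk tolerance (favours cheating)."""
    return SocialParams.symmetric(alpha=0.8, b=0.7)
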
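import numpy as np
import pytest

from shortsprint import SplitTimes, SprintProfile

#: The worked-example clean-start splits (gates 5..40 m, 0.01 s clock).
TABLE1_DISTANCES = np.array([5.0, 10.0, 20.0, 30.0, 40.0])
TABLE1_TIMES = np.array([1.40, 2.13, 3.35, 4.46, 5.54])


@pytest.fixture
def table1_splits() -> SplitTimes:
    return SplitTimes(distances=TABLE1_DISTANCES, times=TABLE1_TIMES)


@pytest.fixture
def triplet_profile() -> SprintProfile:
    """Shared truth of the three demonstration athletes."""
    return SprintProfile(mss=9.5, tau=1.357)


def assert_printed(value: float, printed: float, decimals: int = 2) -> None:
    """Assert agreement at the precision a table prints (half-tick tol)."""
    tol = 0.5 * 10.0 ** (-decimals) * 1.01
    assert abs(value - printed) <= tol, f"{value} != {printed} @ {decimals} dp"
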
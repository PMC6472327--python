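import numpy as np
import pytest

from cvdscreen.cohort import IndividualTrajectory
from cvdscreen.markov import IntensityMatrix, StateSpace, default_policy_intensity


@pytest.fixture(scope="session")
def policy_Q() -> IntensityMatrix:
    return default_policy_intensity()


@pytest.fixture(scope="session")
def policy_space() -> StateSpace:
    return StateSpace.policy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_trajectory(path, absorption="none", absorption_time=None, t_max=20.0, id=0):
    """Hand-built trajectory for screening fixtures."""
    return IndividualTrajectory(
        id=id, path=list(path), absorption=absorption,
        absorption_time=absorption_time, t_max=t_max,
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory


def brute_force_concordance(risks, durations, events) -> float:
    """Exhaustive pairwise Harrell's C: ties in risk count 0.5.

    A pair is comparable when the shorter time ends in an event; assumes
    distinct survival times (the fixtures guarantee it).
    """
    risks = np.asarray(risks, float)
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    assert len(np.unique(durations)) == len(durations)
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (i, j) if durations[i] < durations[j] else (j, i)
            if not events[a]:
                continue
            den += 1
            if risks[a] > risks[b]:
                num += 1.0
            elif risks[a] == risks[b]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def euler_transition_matrix(Qm: np.ndarray, t: float, step: float = 1e-3) -> np.ndarray:
    """Discretised-path oracle: P(t) ~ (I + Q h)^(t/h) by repeated squaring."""
    k = int(round(t / step))
    A = np.eye(Qm.shape[0]) + Qm * (t / k)
    return np.linalg.matrix_power(A, k)
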
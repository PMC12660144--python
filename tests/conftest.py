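import numpy as np
import pytest

from teamscape import PayoffGrid, ProblemInstance, SkillGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(
    payoffs: np.ndarray, skills: np.ndarray | None = None, s: int | None = None
) -> ProblemInstance:
    """Build a ProblemInstance from raw arrays (skills default to all-zero)."""
    payoffs = np.asarray(payoffs, dtype=float)
    if skills is None:
        skills = np.zeros(payoffs.shape, dtype=np.int64)
    skills = np.asarray(skills)
    if s is None:
        s = int(skills.max()) + 1
    return ProblemInstance(
        payoffs=PayoffGrid(values=payoffs),
        skills=SkillGrid(labels=skills, s=s),
    )


def random_instance(
    rng: np.random.Generator, height: int = 10, width: int = 10, s: int = 3
) -> ProblemInstance:
    payoffs = rng.random((height, width))
    skills = rng.integers(0, s, size=(height, width))
    return make_instance(payoffs, skills, s=s)
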
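import numpy as np
import pytest

from mixgrn import SyntheticSpec, generate_problem


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem():
    """A seeded n=60, p=15, s=40 synthetic instance (problem, truth, gold)."""
    spec = SyntheticSpec(n=60, p=15, s=40, seed=7)
    problem, truth, gold = generate_problem(spec)
    problem.standardized = True  # generator output is already scale-free
    return problem, truth, gold


def random_spd(rng, s, cond=10.0):
    """Random SPD matrix with bounded condition number."""
    Q, _ = np.linalg.qr(rng.standard_normal((s, s)))
    lam = rng.uniform(1.0, cond, s)
    return (Q * lam[None, :]) @ Q.T


def random_psd(rng, s, rank=None):
    """Random PSD matrix (possibly rank-deficient)."""
    rank = rank or s
    A = rng.standard_normal((s, rank))
    return A @ A.T / rank
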
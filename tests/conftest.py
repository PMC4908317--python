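import numpy as np
import pytest

from prmpred import build_pwm
from prmpred.synthetic import FixtureSpec


@pytest.fixture
def toy_pwm():
    """4 peptides over a 3-letter alphabet, pseudocount 1 (hand-checkable)."""
    return build_pwm(
        ["AB", "AB", "AC", "BC"],
        "uniform",
        pseudocount=1.0,
        alphabet="ABC",
        id="toy",
    )


@pytest.fixture
def default_spec():
    return FixtureSpec(seed=11)


def random_toy_pwm(rng, n=None, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """A random small PWM (n <= 4) for enumeration cross-checks."""
    if n is None:
        n = int(rng.integers(1, 5))
    k = int(rng.integers(3, 9))
    peptides = [
        "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
        for _ in range(k)
    ]
    return build_pwm(peptides, "uniform", pseudocount=float(rng.uniform(0, 1)))


def enumerate_score_distribution(pwm, granularity):
    """Independent oracle: exact tail probabilities by brute force over all
    m^n windows, using the same score rounding as the DP."""
    m, n = pwm.m, pwm.n
    key = np.floor(pwm.weights / granularity + 0.5).astype(np.int64)
    total = np.zeros(1, dtype=np.int64)
    prob = np.ones(1)
    for j in range(n):
        total = (total[:, None] + key[:, j][None, :]).ravel()
        prob = (prob[:, None] * pwm.background[None, :]).ravel()
    order = np.argsort(total)
    total, prob = total[order], prob[order]
    uniq, idx = np.unique(total, return_index=True)
    sums = np.add.reduceat(prob, idx)
    tail = np.cumsum(sums[::-1])[::-1]
    return uniq * granularity, sums, tail
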
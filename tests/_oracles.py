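"""Independent brute-force oracles used to cross-check the implementation.

Everything here is computed from first principles (explicit expansion,
double loops, Monte-Carlo draws) without calling the code paths under test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def random_table(rng: np.random.Generator, max_categories: int = 6,
                 max_n: int = 50, min_n: int = 1) -> np.ndarray:
    """A random C x C count matrix, C in 2..max_categories, n in min_n..max_n."""
    C = int(rng.integers(2, max_categories + 1))
    probs = rng.dirichlet(np.ones(C * C))
    n = int(rng.integers(min_n, max_n + 1))
    return rng.multinomial(n, probs).reshape(C, C)


def rp_double_sum(counts: np.ndarray) -> float:
    """RP by the explicit double loop over both marginals."""
    n = counts.sum()
    p1 = counts.sum(axis=1) / n
    p2 = counts.sum(axis=0) / n
    C = counts.shape[0]
    total = 0.0
    for i in range(C):
        for j in range(C):
            total += p1[i] * p2[j] * ((j > i) - (j < i))
    return total


def rv_expansion_sort(counts: np.ndarray) -> float:
    """RV by expanding to individual subjects and mid-ranking explicitly."""
    C = counts.shape[0]
    subjects = [
        (i, j) for i in range(C) for j in range(C) for _ in range(counts[i, j])
    ]
    n = len(subjects)
    key1 = np.array([i * C + j for i, j in subjects])
    key2 = np.array([j * C + i for i, j in subjects])
    r1 = rankdata(key1, method="average")
    r2 = rankdata(key2, method="average")
    return float(6.0 / n**3 * np.sum((r1 - r2) ** 2))


def rc_monte_carlo(counts: np.ndarray, kappa: float = 4.0,
                   draws: int = 10**6, seed: int = 0) -> float:
    """RC by Monte-Carlo triple draws from the two marginals.

    ``c21`` is estimated as the relative frequency of ``x1 < y < x2`` for
    independent occasion-1 draws ``x1, x2`` and an occasion-2 draw ``y``;
    ``c12`` symmetrically.
    """
    rng = np.random.default_rng(seed)
    n = counts.sum()
    cum1 = np.cumsum(counts.sum(axis=1) / n)
    cum2 = np.cumsum(counts.sum(axis=0) / n)

    def draw(cum: np.ndarray) -> np.ndarray:
        return np.searchsorted(cum, rng.random(draws), side="right")

    x1, x2, y = draw(cum1), draw(cum1), draw(cum2)
    c21 = np.mean((x1 < y) & (y < x2))
    u1, u2, v = draw(cum2), draw(cum2), draw(cum1)
    c12 = np.mean((u1 < v) & (v < u2))
    return float(kappa * (c21 - c12))


def bootstrap_rp_se(counts: np.ndarray, replicates: int = 10**4,
                    seed: int = 0) -> float:
    """Bootstrap SE of RP by multinomial resampling of the table."""
    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    C = counts.shape[0]
    p = counts.ravel() / n
    boot = rng.multinomial(n, p, size=replicates).reshape(replicates, C, C)
    p1 = boot.sum(axis=2) / n
    p2 = boot.sum(axis=1) / n
    F1 = np.concatenate([np.zeros((replicates, 1)), np.cumsum(p1, axis=1)], axis=1)
    rp = np.sum(p2 * F1[:, :-1], axis=1) - np.sum(p2 * (1.0 - F1[:, 1:]), axis=1)
    return float(rp.std(ddof=1))
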
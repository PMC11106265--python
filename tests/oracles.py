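"""Independent brute-force oracles used only by the test suite.

These re-derive quantities from first principles (explicit enumeration of
sample sequences, Monte-Carlo simulation) without touching the library's
own computation paths.
"""

from itertools import product

import numpy as np
from scipy.stats import norm


def ordered_probit_pmf_oracle(n: float, c: float, s_max: int) -> np.ndarray:
    """Probit-binned count pmf over {1..s_max} via direct CDF differences."""
    probs = []
    for s in range(1, s_max + 1):
        probs.append(norm.cdf((s + 0.5 - n) / c) - norm.cdf((s - 0.5 - n) / c))
    probs = np.array(probs)
    return probs / probs.sum()


def sampling_accept_oracle(
    p1: float,
    r1: float,
    r2: float,
    rs: float,
    n_center: float,
    alpha_gain: float,
    alpha_loss: float,
    q1: float,
    c: float = 2.0,
    s_max: int = 7,
) -> float:
    """Acceptance probability by exhaustive enumeration of sample sequences.

    Every sequence of S draws in {O1, O2}^S is enumerated explicitly; its
    probability is the product of per-draw proposal probabilities and its
    utility-difference estimate is the importance-weighted mean over draws.
    """

    def v(x):
        return x**alpha_gain if x >= 0 else -(abs(x) ** alpha_loss)

    dv = {1: v(r1) - v(rs), 2: v(r2) - v(rs)}
    w = {1: p1 / q1 if q1 > 0 else 0.0, 2: (1 - p1) / (1 - q1) if q1 < 1 else 0.0}
    qd = {1: q1, 2: 1 - q1}
    pmf_s = ordered_probit_pmf_oracle(n_center, c, s_max)
    total = 0.0
    for s_count, p_s in zip(range(1, s_max + 1), pmf_s):
        for seq in product((1, 2), repeat=s_count):
            p_seq = 1.0
            num = 0.0
            den = 0.0
            mag = 0.0
            for draw in seq:
                p_seq *= qd[draw]
                num += w[draw] * dv[draw]
                den += w[draw]
                mag += abs(w[draw] * dv[draw])
            # exact ties (balanced opposing contributions) at relative tolerance
            if abs(num) <= 1e-9 * mag:
                p_acc = 0.5
            else:
                p_acc = 1.0 if num * den > 0 else 0.0
            total += p_s * p_seq * p_acc
    return total


def sampling_accept_monte_carlo(
    p1, r1, r2, rs, n_center, alpha_gain, alpha_loss, q1,
    c=2.0, s_max=7, n_episodes=1_000_000, seed=0,
):
    """Monte-Carlo simulation of sampling episodes; returns (mean, se)."""

    def v(x):
        return np.where(x >= 0, np.abs(x) ** alpha_gain, -np.abs(x) ** alpha_loss)

    rng = np.random.default_rng(seed)
    pmf_s = ordered_probit_pmf_oracle(n_center, c, s_max)
    s_draws = rng.choice(np.arange(1, s_max + 1), p=pmf_s, size=n_episodes)
    n1 = rng.binomial(s_draws, q1)
    w1 = p1 / q1
    w2 = (1 - p1) / (1 - q1)
    dv1 = float(v(np.array(r1)) - v(np.array(rs)))
    dv2 = float(v(np.array(r2)) - v(np.array(rs)))
    num = n1 * w1 * dv1 + (s_draws - n1) * w2 * dv2
    mag = n1 * abs(w1 * dv1) + (s_draws - n1) * abs(w2 * dv2)
    tie = np.abs(num) <= 1e-9 * mag
    acc = np.where(tie, 0.5, np.where(num > 0, 1.0, 0.0))
    return float(acc.mean()), float(acc.std(ddof=1) / np.sqrt(n_episodes))
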
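"""Independent closed-form / brute-force oracles used by the tests.

Everything here is derived from first principles of birth-death Markov
chains or exhaustive enumeration, deliberately sharing no code with the
package's simulation path.
"""

from __future__ import annotations

import itertools

import numpy as np


def boltzmann_stationary(ddg: np.ndarray, rt: float) -> np.ndarray:
    """Exact stationary law of the reflecting chain: pi(m) ~ exp(-G(m)/RT)."""
    g = np.concatenate([[0.0], np.cumsum(np.asarray(ddg, dtype=float))])
    w = np.exp(-(g - g.min()) / rt)
    return w / w.sum()


def mfpt_below(v_f: np.ndarray, v_r: np.ndarray, start: int, m_star: int) -> float:
    """Mean first-passage time from ``start`` to any state < m_star on a
    birth-death chain reflecting at N (standard ladder-sum formula).

    ``v_f[i]`` is the rate i -> i+1 (i = 0..N-1); ``v_r[i]`` the rate
    i+1 -> i.  Uses pi-ratios built directly from the rates.
    """
    n = len(v_f)
    # pi up to a constant: pi[m+1]/pi[m] = v_f[m]/v_r[m]
    pi = np.ones(n + 1)
    for m in range(n):
        pi[m + 1] = pi[m] * v_f[m] / v_r[m]
    total = 0.0
    for k in range(m_star, start + 1):
        total += pi[k : n + 1].sum() / (pi[k] * v_r[k - 1])
    return total


def absorb_before_hit_probability(
    v_f: np.ndarray, v_r: np.ndarray, m0: int, stop_m: int
) -> float:
    """P(hit 0 before stop_m) for the chain absorbed at both ends, by a
    first-step-analysis linear solve over the interior states."""
    interior = list(range(1, stop_m))
    idx = {m: i for i, m in enumerate(interior)}
    a = np.zeros((len(interior), len(interior)))
    b = np.zeros(len(interior))
    for m in interior:
        i = idx[m]
        tot = v_f[m] + v_r[m - 1]
        a[i, i] = 1.0
        p_up = v_f[m] / tot
        p_dn = v_r[m - 1] / tot
        if m - 1 == 0:
            b[i] += p_dn
        else:
            a[i, idx[m - 1]] -= p_dn
        if m + 1 < stop_m:
            a[i, idx[m + 1]] -= p_up
    u = np.linalg.solve(a, b)
    if m0 == 0:
        return 1.0
    if m0 >= stop_m:
        return 0.0
    return float(u[idx[m0]])


def permutation_p_exhaustive(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for the Pearson r by full enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def r(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_obs = abs(r(x, y))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        hits += abs(r(x, y[list(perm)])) >= r_obs - 1e-12
        total += 1
    return hits / total
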
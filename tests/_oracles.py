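"""Independent brute-force oracles for the association indices and ensembles.

Everything here is written as plain loops over the definitions, deliberately
ignoring the vectorized implementations it is used to check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def checker_oracle(B: np.ndarray) -> int:
    S = B.shape[0]
    count = 0
    for i in range(S):
        for j in range(i + 1, S):
            shared = sum(1 for t in range(B.shape[1]) if B[i, t] and B[j, t])
            if shared == 0:
                count += 1
    return count


def c_score_oracle(B: np.ndarray) -> float:
    S, T = B.shape
    total = 0.0
    n_pairs = 0
    for i in range(S):
        for j in range(i + 1, S):
            shared = sum(1 for t in range(T) if B[i, t] and B[j, t])
            ri = sum(B[i, t] for t in range(T))
            rj = sum(B[j, t] for t in range(T))
            total += (ri - shared) * (rj - shared)
            n_pairs += 1
    return total / n_pairs


def v_ratio_oracle(B: np.ndarray) -> float:
    S, T = B.shape

    def pop_var(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    col_sums = [sum(B[i, t] for i in range(S)) for t in range(T)]
    row_vars = [pop_var([B[i, t] for t in range(T)]) for i in range(S)]
    return pop_var(col_sums) / sum(row_vars)


def ca_aa_oracle(n: np.ndarray) -> tuple[float, float]:
    S, T = n.shape
    ca = aa = 0
    for i in range(S):
        for j in range(i + 1, S):
            for k in range(T):
                for l in range(k + 1, T):
                    di = n[i, k] - n[i, l]
                    dj = n[j, k] - n[j, l]
                    if di * dj < 0:
                        ca += 1
                    elif di * dj > 0:
                        aa += 1
    denom = (S * (S - 1) / 2) * (T * (T - 1) / 2)
    return ca / denom, aa / denom


def ma_oracle(n: np.ndarray) -> float:
    S, T = n.shape
    col = [sum(n[i, k] for i in range(S)) for k in range(T)]
    p = [[n[i, k] / col[k] for k in range(T)] for i in range(S)]
    num = 0.0
    sq = 0.0
    for i in range(S):
        s = sum(p[i])
        s2 = sum(x * x for x in p[i])
        num += s * s - s2
        sq += s2
    return num / ((T - 1) * sq)


def enumerate_fixed_marginal(row_sums, col_sums) -> list[bytes]:
    """All binary matrices with the given marginals, as byte keys."""
    S, T = len(row_sums), len(col_sums)
    states = []
    for bits in itertools.product((0, 1), repeat=S * T):
        M = np.array(bits, dtype=np.int8).reshape(S, T)
        if list(M.sum(axis=1)) == list(row_sums) and list(M.sum(axis=0)) == list(col_sums):
            states.append(M.tobytes())
    return states


def it_exact_distribution(row_totals, col_totals) -> dict[bytes, Fraction]:
    """Exact final-table distribution of the sequential IT fill.

    Recursion over placements: each step picks an available cell (row and
    column both unsaturated) with probability proportional to the observed
    totals R_i * C_j, renormalized over the available set.
    """
    R = list(row_totals)
    C = list(col_totals)
    S, T = len(R), len(C)
    out: dict[bytes, Fraction] = {}

    def recurse(table, rrem, crem, prob):
        if sum(rrem) == 0:
            key = np.array(table, dtype=np.int64).tobytes()
            out[key] = out.get(key, Fraction(0)) + prob
            return
        avail = [
            (i, j)
            for i in range(S)
            for j in range(T)
            if rrem[i] > 0 and crem[j] > 0
        ]
        z = sum(R[i] * C[j] for i, j in avail)
        for i, j in avail:
            p = Fraction(R[i] * C[j], z)
            table[i][j] += 1
            rrem[i] -= 1
            crem[j] -= 1
            recurse(table, rrem, crem, prob * p)
            table[i][j] -= 1
            rrem[i] += 1
            crem[j] += 1

    recurse([[0] * T for _ in range(S)], R[:], C[:], Fraction(1))
    return out
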
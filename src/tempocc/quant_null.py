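"""Abundance-based association indices and quantitative null models.

Quantitative analogues of the presence/absence machinery operate on
integer count matrices (individuals per species x year cell):

* ``CA_ST`` -- standardized count of 2x2 species-by-year sub-matrices whose
  abundance differences oppose each other (abundance checkerboards); high
  values mean negative covariation (segregation).
* ``AA_ST`` -- standardized count of concordant 2x2 sub-matrices; high
  values mean positive covariation (aggregation).
* ``MA`` -- the n-community extension of the Morisita--Horn similarity over
  year samples; 1 = identical relative composition every year, 0 = fully
  dissimilar.  Low MA suggests competition-driven (compensatory) dynamics.

Two individual-based randomizations provide the null ensembles: ``IT``
places individuals one at a time with cell probability proportional to
row x column totals until every marginal total is reached, and ``IA``
places all N individuals independently with those probabilities,
constraining only the grand total.  Tests are one-tailed per direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .binary_null import NullModelResult, empirical_p
from .matrix_io import AbundanceMatrix

__all__ = [
    "QUANT_INDICES",
    "CountMatrix",
    "scale_to_counts",
    "ca_aa_scores",
    "ma_index",
    "it_randomize",
    "ia_randomize",
    "run_quant_null",
    "quant_null_suite",
]

QUANT_INDICES = ("CA_ST", "AA_ST", "MA")

#: Tail semantics: which tail of the null distribution means segregation /
#: aggregation for each index.
QUANT_TAILS = {
    "CA_ST": {"segregation": "high", "aggregation": "low"},
    "AA_ST": {"segregation": "low", "aggregation": "high"},
    "MA": {"segregation": "low", "aggregation": "high"},
}


@dataclass
class CountMatrix:
    """Non-negative integer species x year matrix of individuals."""

    species_ids: list[str]
    year_labels: list[int]
    values: np.ndarray
    scale_factor: float = 1.0
    plot_size_ha: float = 10.0
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if np.any(v < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(v, np.round(v)):
            raise ValueError("counts must be integers")
        self.values = np.round(v).astype(np.int64)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]


def scale_to_counts(matrix: AbundanceMatrix, scale_factor: float = 250.0) -> CountMatrix:
    """Convert a density matrix to integer counts: ``round(density * factor)``.

    The default factor of 250 maps the smallest tracing constant
    (0.004 p/10 ha) to exactly one individual.  Any positive density that
    would round to zero raises, with advice to enlarge the factor.
    """
    if not scale_factor > 0:
        raise ValueError("scale_factor must be positive")
    v = matrix.values
    counts = np.round(v * scale_factor)
    lost = (v > 0) & (counts == 0)
    if lost.any():
        i, j = np.argwhere(lost)[0]
        raise ValueError(
            f"density {v[i, j]} at ({matrix.species_ids[i]}, "
            f"year {matrix.year_labels[j]}) rounds to 0 individuals; "
            f"increase scale_factor (currently {scale_factor})"
        )
    return CountMatrix(
        species_ids=list(matrix.species_ids),
        year_labels=list(matrix.year_labels),
        values=counts,
        scale_factor=scale_factor,
        plot_size_ha=matrix.plot_size_ha,
        dataset_id=matrix.dataset_id,
    )


def _values(matrix) -> np.ndarray:
    v = matrix.values if hasattr(matrix, "values") else matrix
    return np.asarray(v)


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def _ca_aa_from_signs(pos: np.ndarray, neg: np.ndarray, n_pairs: float):
    ca = (pos * neg).sum(axis=(-2, -1)) / 2
    aa = (pos * (pos - 1) / 2 + neg * (neg - 1) / 2).sum(axis=(-2, -1)) / 2
    return ca / n_pairs, aa / n_pairs


def ca_aa_scores(matrix) -> tuple[float, float]:
    """Standardized abundance checkerboard (CA_ST) and aggregation (AA_ST).

    Over all ``C(S,2) * C(T,2)`` 2x2 sub-matrices with differences
    ``d_i = n_ik - n_il`` and ``d_j = n_jk - n_jl``: a checkerboard has
    ``d_i d_j < 0``, an aggregation ``d_i d_j > 0``; ties (either difference
    zero) count toward neither.  Both counts are divided by the total number
    of sub-matrices, so ``CA_ST + AA_ST <= 1``.
    """
    n = _values(matrix).astype(np.int64)
    S, T = n.shape
    if S < 2 or T < 2:
        raise ValueError("need at least 2 species and 2 years")
    d = n[:, :, None] - n[:, None, :]  # (S, T, T)
    pos = (d > 0).sum(axis=0).astype(np.int64)  # (T, T), zero on diagonal pairs
    neg = (d < 0).sum(axis=0).astype(np.int64)
    n_pairs = (S * (S - 1) / 2) * (T * (T - 1) / 2)
    ca, aa = _ca_aa_from_signs(pos, neg, n_pairs)
    return float(ca), float(aa)


def _ca_aa_batch(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K, S, T = stack.shape
    n_pairs = (S * (S - 1) / 2) * (T * (T - 1) / 2)
    # chunk over replicates: the (k, S, T, T) difference tensor is the
    # memory hot spot for large matrices
    chunk = max(1, int(2e8 / (S * T * T * 8)))
    cas, aas = [], []
    for start in range(0, K, chunk):
        part = stack[start : start + chunk]
        d = part[:, :, :, None] - part[:, :, None, :]
        pos = (d > 0).sum(axis=1).astype(np.int64)
        neg = (d < 0).sum(axis=1).astype(np.int64)
        ca, aa = _ca_aa_from_signs(pos, neg, n_pairs)
        cas.append(ca)
        aas.append(aa)
    return np.concatenate(cas), np.concatenate(aas)


def ma_index(matrix) -> float:
    """Multi-community Morisita--Horn similarity across year samples.

    With ``p_ik`` the relative abundance of species ``i`` in year ``k``::

        MA = sum_i [ (sum_k p_ik)^2 - sum_k p_ik^2 ]
             / [ (T - 1) * sum_i sum_k p_ik^2 ]

    Reduces to the classical two-community Morisita--Horn index at T = 2.
    Every column total must be positive.
    """
    n = _values(matrix).astype(float)
    if n.shape[1] < 2:
        raise ValueError("need at least 2 year samples")
    col = n.sum(axis=0)
    if np.any(col == 0):
        raise ValueError("zero column total: relative abundances undefined")
    p = n / col
    T = n.shape[1]
    num = (p.sum(axis=1) ** 2 - (p**2).sum(axis=1)).sum()
    den = (T - 1) * (p**2).sum()
    return float(num / den)


def _ma_batch(stack: np.ndarray) -> np.ndarray:
    f = stack.astype(float)
    col = f.sum(axis=1, keepdims=True)
    col[col == 0] = np.nan  # zero columns can occur under IA; MA undefined -> nan
    p = f / col
    T = stack.shape[2]
    num = (p.sum(axis=2) ** 2 - (p**2).sum(axis=2)).sum(axis=1)
    den = (T - 1) * (p**2).sum(axis=(1, 2))
    return num / den


# ---------------------------------------------------------------------------
# randomization algorithms
# ---------------------------------------------------------------------------

@njit(cache=True)
def _it_fill_kernel(R, C, n_rep, seed, out):  # pragma: no cover
    np.random.seed(seed)
    S = R.shape[0]
    T = C.shape[0]
    for rep in range(n_rep):
        rrem = R.copy()
        crem = C.copy()
        # active lists of unsaturated rows / columns with their weights
        rows = np.arange(S)
        cols = np.arange(T)
        n_rows = S
        n_cols = T
        rw_sum = 0.0
        for i in range(S):
            rw_sum += R[i]
        cw_sum = 0.0
        for j in range(T):
            cw_sum += C[j]
        N = int(rw_sum)
        for _ in range(N):
            # sample a row proportional to its original total
            u = np.random.random() * rw_sum
            acc = 0.0
            ri = n_rows - 1
            for a in range(n_rows):
                acc += R[rows[a]]
                if u < acc:
                    ri = a
                    break
            u = np.random.random() * cw_sum
            acc = 0.0
            ci = n_cols - 1
            for a in range(n_cols):
                acc += C[cols[a]]
                if u < acc:
                    ci = a
                    break
            i = rows[ri]
            j = cols[ci]
            out[rep, i, j] += 1
            rrem[i] -= 1
            crem[j] -= 1
            if rrem[i] == 0:
                rw_sum -= R[i]
                rows[ri] = rows[n_rows - 1]
                rows[n_rows - 1] = i
                n_rows -= 1
            if crem[j] == 0:
                cw_sum -= C[j]
                cols[ci] = cols[n_cols - 1]
                cols[n_cols - 1] = j
                n_cols -= 1


def it_batch(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n`` IT randomizations as an ``(n, S, T)`` int64 stack."""
    R = np.asarray(row_totals, dtype=np.int64)
    C = np.asarray(col_totals, dtype=np.int64)
    if R.sum() != C.sum():
        raise ValueError("row and column totals must sum to the same N")
    out = np.zeros((n, len(R), len(C)), dtype=np.int64)
    seed = int(rng.integers(0, 2**31 - 1))
    _it_fill_kernel(R, C, n, seed, out)
    return out


def it_randomize(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> np.ndarray:
    """One IT randomization: individuals placed one at a time.

    Each placement chooses a cell with probability proportional to
    ``R_i * C_j`` among cells whose row and column are not yet saturated.
    Because that availability set is always the product of the unsaturated
    rows and columns, a dead-end cannot occur when the totals balance, so
    the ``max_restarts`` budget (kept for contract compatibility) is never
    consumed.  Output marginals equal the inputs exactly.
    """
    if max_restarts < 1:
        raise ValueError("max_restarts must be >= 1")
    return it_batch(row_totals, col_totals, 1, rng)[0]


def ia_batch(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n`` IA randomizations: N individuals dropped independently."""
    R = np.asarray(row_totals, dtype=np.int64)
    C = np.asarray(col_totals, dtype=np.int64)
    N = int(R.sum())
    if N <= 0:
        raise ValueError("grand total must be positive")
    p = np.outer(R, C).astype(float)
    p = (p / p.sum()).ravel()
    draws = rng.multinomial(N, p, size=n)
    return draws.reshape(n, len(R), len(C)).astype(np.int64)


def ia_randomize(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """One IA randomization (only the grand total is constrained)."""
    return ia_batch(row_totals, col_totals, 1, rng)[0]


# ---------------------------------------------------------------------------
# hypothesis testing
# ---------------------------------------------------------------------------

def _classify_one_tailed(index: str, p_low: float, p_high: float, alpha: float) -> str:
    tails = QUANT_TAILS[index]
    p_seg = p_high if tails["segregation"] == "high" else p_low
    p_agg = p_high if tails["aggregation"] == "high" else p_low
    # p_low + p_high >= 1 + 1/(n+1), so both tails cannot be significant
    assert not (p_seg < alpha and p_agg < alpha)
    if p_seg < alpha:
        return "segregation"
    if p_agg < alpha:
        return "aggregation"
    return "random"


def _null_stack(values: np.ndarray, algorithm: str, n_sim: int, rng) -> np.ndarray:
    R = values.sum(axis=1)
    C = values.sum(axis=0)
    if algorithm == "IT":
        return it_batch(R, C, n_sim, rng)
    if algorithm == "IA":
        return ia_batch(R, C, n_sim, rng)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _observed_and_nulls(values: np.ndarray, stack: np.ndarray):
    ca, aa = ca_aa_scores(values)
    ca_null, aa_null = _ca_aa_batch(stack)
    ma = ma_index(values)
    ma_null = _ma_batch(stack)
    return {"CA_ST": (ca, ca_null), "AA_ST": (aa, aa_null), "MA": (ma, ma_null)}


def run_quant_null(
    matrix,
    index: str,
    algorithm: str,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> NullModelResult:
    """One-tailed empirical test of a quantitative index under IT or IA.

    Both tail probabilities are reported (add-one convention); the outcome
    is segregation if the segregation-side tail is below ``alpha``,
    aggregation if the aggregation-side tail is, else random.
    """
    if index not in QUANT_INDICES:
        raise ValueError(f"unknown quantitative index {index!r}")
    rng = np.random.default_rng() if rng is None else rng
    values = _values(matrix).astype(np.int64)
    stack = _null_stack(values, algorithm, n_sim, rng)
    if index == "MA":
        observed, null_values = ma_index(values), _ma_batch(stack)
    else:
        ca, aa = ca_aa_scores(values)
        ca_null, aa_null = _ca_aa_batch(stack)
        observed, null_values = (ca, ca_null) if index == "CA_ST" else (aa, aa_null)
    finite = null_values[np.isfinite(null_values)]
    p_low, p_high = empirical_p(observed, finite)
    return NullModelResult(
        observed=float(observed),
        null_values=null_values,
        p_low=p_low,
        p_high=p_high,
        p_two=None,
        alpha=alpha,
        outcome=_classify_one_tailed(index, p_low, p_high, alpha),
        algorithm=algorithm,
        index=index,
        dataset=getattr(matrix, "dataset_id", ""),
        n_sim=n_sim,
    )


def quant_null_suite(
    matrix,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], NullModelResult]:
    """All six (algorithm, index) combinations, sharing null stacks."""
    rng = np.random.default_rng() if rng is None else rng
    values = _values(matrix).astype(np.int64)
    out: dict[tuple[str, str], NullModelResult] = {}
    for algorithm in ("IT", "IA"):
        stack = _null_stack(values, algorithm, n_sim, rng)
        for index, (obs, nulls) in _observed_and_nulls(values, stack).items():
            finite = nulls[np.isfinite(nulls)]
            p_low, p_high = empirical_p(obs, finite)
            out[(algorithm, index)] = NullModelResult(
                observed=float(obs),
                null_values=nulls,
                p_low=p_low,
                p_high=p_high,
                p_two=None,
                alpha=alpha,
                outcome=_classify_one_tailed(index, p_low, p_high, alpha),
                algorithm=algorithm,
                index=index,
                dataset=getattr(matrix, "dataset_id", ""),
                n_sim=n_sim,
            )
    return out
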
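"""Presence/absence association indices and binary null models.

Three community-wide indices operate on a species x year presence/absence
matrix:

* ``CHECKER`` -- the number of species pairs that never co-occur in any year
  (perfect checkerboards).
* ``C_SCORE`` -- the mean number of checkerboard units per species pair,
  ``CU_ij = (r_i - S_ij) (r_j - S_ij)`` with ``r`` the row totals and
  ``S_ij`` the number of shared years.
* ``V_RATIO`` -- the variance ratio: variance of the yearly species totals
  over the sum of the per-species occurrence variances.  1 under
  independence; values below 1 indicate negative covariance.

Observed values are compared against a randomized ensemble produced by one of
two algorithms: ``SIM2`` (row sums fixed, columns equiprobable) or ``SIM9``
(both marginals fixed, sampled by a sequential-swap Markov chain).  High
CHECKER / C-score signals segregation; low V-ratio signals segregation.
Tests are two-tailed with empirical Monte-Carlo p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from numba import njit

from .matrix_io import BinaryMatrix

__all__ = [
    "BINARY_INDICES",
    "NullModelResult",
    "checker",
    "c_score",
    "v_ratio",
    "sim2_randomize",
    "sim2_batch",
    "sim9_randomize",
    "sim9_batch",
    "run_binary_null",
    "binary_null_suite",
]

BINARY_INDICES = ("CHECKER", "C_SCORE", "V_RATIO")

#: Which tail of the null distribution signals segregation, per index.
SEGREGATION_TAIL = {"CHECKER": "high", "C_SCORE": "high", "V_RATIO": "low"}


@dataclass
class NullModelResult:
    """Observed index, its null distribution, and the classified outcome."""

    observed: float
    null_values: np.ndarray
    p_low: float
    p_high: float
    p_two: float | None
    alpha: float
    outcome: Literal["aggregation", "segregation", "random"]
    algorithm: str = ""
    index: str = ""
    dataset: str = ""
    level: str = "assemblage"
    guild: str | None = None
    n_sim: int = field(default=0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.n_sim == 0:
            self.n_sim = len(self.null_values)


def _values(matrix) -> np.ndarray:
    v = matrix.values if hasattr(matrix, "values") else matrix
    return np.asarray(v)


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def checker(matrix) -> int:
    """Number of species pairs with no year of joint presence."""
    B = _values(matrix).astype(np.int64)
    if B.shape[0] < 2:
        raise ValueError("need at least 2 species")
    shared = B @ B.T
    iu = np.triu_indices(B.shape[0], k=1)
    return int((shared[iu] == 0).sum())


def c_score(matrix) -> float:
    """Mean checkerboard units per species pair."""
    B = _values(matrix).astype(np.int64)
    S = B.shape[0]
    if S < 2:
        raise ValueError("need at least 2 species")
    shared = B @ B.T
    r = B.sum(axis=1)
    cu = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(S, k=1)
    return float(cu[iu].mean())


def v_ratio(matrix) -> float:
    """Variance of yearly species totals over summed per-species variances.

    Population variances (divide by T).  Raises if every row is constant.
    """
    B = _values(matrix).astype(float)
    row_var = B.var(axis=1)
    denom = row_var.sum()
    if denom == 0:
        raise ValueError("v_ratio undefined: all species rows are constant")
    return float(B.sum(axis=0).var() / denom)


def _checker_batch(stack: np.ndarray) -> np.ndarray:
    shared = np.einsum("kst,kut->ksu", stack, stack, dtype=np.int64)
    iu = np.triu_indices(stack.shape[1], k=1)
    return (shared[:, iu[0], iu[1]] == 0).sum(axis=1).astype(float)


def _c_score_batch(stack: np.ndarray) -> np.ndarray:
    shared = np.einsum("kst,kut->ksu", stack, stack, dtype=np.int64)
    r = stack.sum(axis=2, dtype=np.int64)
    cu = (r[:, :, None] - shared) * (r[:, None, :] - shared)
    iu = np.triu_indices(stack.shape[1], k=1)
    return cu[:, iu[0], iu[1]].mean(axis=1)


def _v_ratio_batch(stack: np.ndarray) -> np.ndarray:
    f = stack.astype(float)
    denom = f.var(axis=2).sum(axis=1)
    num = f.sum(axis=1).var(axis=1)
    return num / denom


_BATCH = {
    "CHECKER": _checker_batch,
    "C_SCORE": _c_score_batch,
    "V_RATIO": _v_ratio_batch,
}

_SCALAR = {"CHECKER": checker, "C_SCORE": c_score, "V_RATIO": v_ratio}


# ---------------------------------------------------------------------------
# SIM2: row sums fixed, columns equiprobable
# ---------------------------------------------------------------------------

def sim2_batch(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent SIM2 randomizations as an ``(n, S, T)`` int8 stack.

    Each row's presences are placed in ``r_i`` distinct columns drawn
    uniformly, independently across rows and replicates.
    """
    B = np.asarray(values)
    S, T = B.shape
    r = B.sum(axis=1).astype(np.int64)
    u = rng.random((n, S, T))
    order = np.argsort(u, axis=2)
    ranks = np.empty_like(order)
    idx = np.arange(T)
    np.put_along_axis(ranks, order, np.broadcast_to(idx, (n, S, T)), axis=2)
    return (ranks < r[None, :, None]).astype(np.int8)


def sim2_randomize(matrix, rng: np.random.Generator):
    """One SIM2 randomization, same container type as the input."""
    out = sim2_batch(_values(matrix), 1, rng)[0]
    if isinstance(matrix, BinaryMatrix):
        return BinaryMatrix(
            species_ids=list(matrix.species_ids),
            year_labels=list(matrix.year_labels),
            values=out,
            plot_size_ha=matrix.plot_size_ha,
            dataset_id=matrix.dataset_id,
        )
    return out


# ---------------------------------------------------------------------------
# SIM9: both marginals fixed (sequential swap chain)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sim9_kernel(M, n_samples, burn_in, cadence, seed, out):  # pragma: no cover
    np.random.seed(seed)
    S, T = M.shape
    for _ in range(burn_in):
        i = np.random.randint(S)
        j = np.random.randint(S - 1)
        if j >= i:
            j += 1
        k = np.random.randint(T)
        l = np.random.randint(T - 1)
        if l >= k:
            l += 1
        a, b, c, d = M[i, k], M[i, l], M[j, k], M[j, l]
        if a != b and c != d and a != c:
            M[i, k], M[i, l], M[j, k], M[j, l] = b, a, d, c
    for s in range(n_samples):
        for _ in range(cadence):
            i = np.random.randint(S)
            j = np.random.randint(S - 1)
            if j >= i:
                j += 1
            k = np.random.randint(T)
            l = np.random.randint(T - 1)
            if l >= k:
                l += 1
            a, b, c, d = M[i, k], M[i, l], M[j, k], M[j, l]
            if a != b and c != d and a != c:
                M[i, k], M[i, l], M[j, k], M[j, l] = b, a, d, c
        out[s] = M


def _has_checkerboard(B: np.ndarray) -> bool:
    S = B.shape[0]
    Bb = B.astype(bool)
    for i in range(S):
        for j in range(i + 1, S):
            if (Bb[i] & ~Bb[j]).any() and (~Bb[i] & Bb[j]).any():
                return True
    return False


def sim9_batch(
    values: np.ndarray,
    n: int,
    rng: np.random.Generator,
    burn_in: int = 30_000,
    swaps_per_sample: int | None = None,
) -> np.ndarray:
    """``n`` SIM9 samples from one sequential-swap chain, ``(n, S, T)`` int8.

    The chain proposes a uniformly random (row-pair, column-pair) 2x2
    sub-matrix each step and swaps it only when it is a checkerboard,
    counting every *attempt* toward the cadence.  Because the proposal is
    symmetric and non-checkerboard draws are no-ops, the stationary
    distribution is exactly uniform over the fixed-marginal ensemble
    (trial-swap property).  One sample is emitted every
    ``swaps_per_sample`` attempts (default ``10 * max(S, T) + 1``) after
    ``burn_in`` attempts.
    """
    B = np.asarray(values).astype(np.int8)
    S, T = B.shape
    if S < 2 or T < 2:
        raise ValueError("SIM9 needs at least a 2x2 matrix")
    if swaps_per_sample is None:
        # odd cadence avoids parity locking on tiny two-state ensembles
        # where every proposal is an accepted swap
        swaps_per_sample = 10 * max(S, T) + 1
    if not _has_checkerboard(B):
        warnings.warn(
            "matrix has no swappable checkerboard sub-matrix: SIM9 chain is "
            "frozen and every sample equals the input",
            stacklevel=2,
        )
        return np.repeat(B[None, :, :], n, axis=0)
    out = np.empty((n, S, T), dtype=np.int8)
    seed = int(rng.integers(0, 2**31 - 1))
    _sim9_kernel(B.copy(), n, burn_in, swaps_per_sample, seed, out)
    return out


def sim9_randomize(
    matrix,
    rng: np.random.Generator,
    burn_in: int = 30_000,
    swaps_per_sample: int | None = None,
) -> Iterator[np.ndarray]:
    """Stream of SIM9 samples (generator over ``(S, T)`` arrays)."""
    values = _values(matrix)
    while True:
        yield from sim9_batch(values, 256, rng, burn_in, swaps_per_sample)


# ---------------------------------------------------------------------------
# hypothesis testing
# ---------------------------------------------------------------------------

def empirical_p(observed: float, null_values: np.ndarray) -> tuple[float, float]:
    """Add-one Monte-Carlo tail probabilities (ties count as extreme)."""
    null_values = np.asarray(null_values)
    n = len(null_values)
    p_high = (1 + (null_values >= observed).sum()) / (n + 1)
    p_low = (1 + (null_values <= observed).sum()) / (n + 1)
    return float(p_low), float(p_high)


def _classify_two_tailed(
    index: str, p_low: float, p_high: float, p_two: float, alpha: float
) -> str:
    if p_two >= alpha:
        return "random"
    seg_tail = SEGREGATION_TAIL[index]
    extreme_high = p_high < p_low
    if (seg_tail == "high") == extreme_high:
        return "segregation"
    return "aggregation"


def run_binary_null(
    matrix,
    index: str,
    algorithm: str,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    burn_in: int = 30_000,
    swaps_per_sample: int | None = None,
) -> NullModelResult:
    """Two-tailed empirical test of one index under SIM2 or SIM9.

    ``p_high = (1 + #{null >= obs}) / (n_sim + 1)``, analogously for
    ``p_low``; ``p_two = min(1, 2 min(p_low, p_high))``.  The outcome is
    classified from the significant tail using the index's direction
    semantics (high CHECKER / C-score and low V-ratio mean segregation).
    """
    if index not in BINARY_INDICES:
        raise ValueError(f"unknown binary index {index!r}")
    if algorithm not in ("SIM2", "SIM9"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if index == "V_RATIO" and algorithm == "SIM9":
        raise ValueError(
            "SIM9 is not applicable to the V-ratio: fixed row and column sums "
            "do not randomize the marginal variances"
        )
    rng = np.random.default_rng() if rng is None else rng
    values = _values(matrix)
    observed = float(_SCALAR[index](values))
    if algorithm == "SIM2":
        stack = sim2_batch(values, n_sim, rng)
    else:
        stack = sim9_batch(values, n_sim, rng, burn_in, swaps_per_sample)
    null_values = _BATCH[index](stack)
    p_low, p_high = empirical_p(observed, null_values)
    p_two = min(1.0, 2 * min(p_low, p_high))
    outcome = _classify_two_tailed(index, p_low, p_high, p_two, alpha)
    return NullModelResult(
        observed=observed,
        null_values=null_values,
        p_low=p_low,
        p_high=p_high,
        p_two=p_two,
        alpha=alpha,
        outcome=outcome,
        algorithm=algorithm,
        index=index,
        dataset=getattr(matrix, "dataset_id", ""),
    )


def binary_null_suite(
    matrix,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    burn_in: int = 30_000,
    swaps_per_sample: int | None = None,
) -> dict[tuple[str, str], NullModelResult]:
    """All five valid (algorithm, index) combinations on one matrix.

    The null stack for each algorithm is generated once and shared across
    its indices, so the five tests cost two randomization runs.
    """
    rng = np.random.default_rng() if rng is None else rng
    values = _values(matrix)
    out: dict[tuple[str, str], NullModelResult] = {}
    for algorithm, indices in (
        ("SIM2", ("CHECKER", "C_SCORE", "V_RATIO")),
        ("SIM9", ("CHECKER", "C_SCORE")),
    ):
        if algorithm == "SIM2":
            stack = sim2_batch(values, n_sim, rng)
        else:
            stack = sim9_batch(values, n_sim, rng, burn_in, swaps_per_sample)
        for index in indices:
            observed = float(_SCALAR[index](values))
            null_values = _BATCH[index](stack)
            p_low, p_high = empirical_p(observed, null_values)
            p_two = min(1.0, 2 * min(p_low, p_high))
            out[(algorithm, index)] = NullModelResult(
                observed=observed,
                null_values=null_values,
                p_low=p_low,
                p_high=p_high,
                p_two=p_two,
                alpha=alpha,
                outcome=_classify_two_tailed(index, p_low, p_high, p_two, alpha),
                algorithm=algorithm,
                index=index,
                dataset=getattr(matrix, "dataset_id", ""),
            )
    return out
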
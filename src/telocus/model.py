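"""Pooled Bayesian mixture model for multimapped-read reassignment, fitted
by expectation-maximization.

Fragments are generated by features (column 0 = NO_FEATURE) with per-pool
abundance pi and, for ambiguously aligned fragments, reassignment proportions
theta.  The probability of fragment i in pool P is

    Pr(f_i) = sum_j pi_Pj * theta_Pj^y_i * q_ij

Pools share parameters across cells: one per cell (individual), one for the
whole sample (pseudobulk), or one per provided label (celltype).  Updates use
symmetric Dirichlet pseudocounts (pi_prior, theta_prior) added to every
component; the default theta prior of 200000 pins theta near uniform so that
reassignment is driven by pi.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .ingest import WeightMatrix

logger = logging.getLogger(__name__)

PSEUDOBULK_POOL = "pseudobulk"

__all__ = [
    "PoolAssignment",
    "ModelParams",
    "FittedModel",
    "assign_pools",
    "fragment_probability",
    "e_step",
    "m_step",
    "complete_data_log_likelihood",
    "fit_em",
    "model_selection",
]


@dataclass
class PoolAssignment:
    """Mapping of cells to parameter-sharing pools."""

    mode: str
    pool_ids: list[str]
    cell_to_pool: dict[str, str]

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "pseudobulk", "celltype"):
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        missing = sorted(set(self.cell_to_pool.values()) - set(self.pool_ids))
        if missing:
            raise ValueError(f"cells assigned to unlisted pools: {missing}")

    @property
    def D(self) -> int:
        return len(self.pool_ids)

    def pool_index(self) -> dict[str, int]:
        return {p: d for d, p in enumerate(self.pool_ids)}

    def row_pools(self, barcodes: Sequence[str]) -> np.ndarray:
        """Pool index for each row barcode."""
        idx = self.pool_index()
        try:
            return np.array([idx[self.cell_to_pool[b]] for b in barcodes], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"barcode {exc.args[0]!r} has no pool assignment") from exc


def assign_pools(
    barcodes: Iterable[str],
    mode: str,
    labels: Mapping[str, str] | None = None,
) -> PoolAssignment:
    """Build a PoolAssignment for the given cells.

    celltype mode requires a label for every barcode; missing barcodes are an
    error (listed), never silently pooled.
    """
    cells = list(dict.fromkeys(barcodes))
    if mode == "individual":
        return PoolAssignment(mode, list(cells), {c: c for c in cells})
    if mode == "pseudobulk":
        return PoolAssignment(mode, [PSEUDOBULK_POOL], {c: PSEUDOBULK_POOL for c in cells})
    if mode == "celltype":
        if labels is None:
            raise ValueError("celltype pooling requires a cell -> label mapping")
        missing = [c for c in cells if c not in labels]
        if missing:
            raise ValueError(f"no celltype label for barcodes: {missing}")
        cell_to_pool = {c: labels[c] for c in cells}
        pool_ids = list(dict.fromkeys(cell_to_pool[c] for c in cells))
        return PoolAssignment(mode, pool_ids, cell_to_pool)
    raise ValueError(f"unknown pooling mode {mode!r}")


@dataclass
class ModelParams:
    """Per-pool abundance (pi) and reassignment (theta) parameters.

    ``pi`` and ``theta`` are (D, K+1) arrays, rows summing to 1.
    """

    pool_ids: list[str]
    pi: np.ndarray
    theta: np.ndarray
    empty_pools: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        D = len(self.pool_ids)
        if self.pi.shape[0] != D or self.theta.shape != self.pi.shape:
            raise ValueError("parameter array shapes inconsistent with pool count")
        for name, arr in (("pi", self.pi), ("theta", self.theta)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")

    @classmethod
    def uniform(cls, pool_ids: list[str], n_features: int) -> "ModelParams":
        D = len(pool_ids)
        u = np.full((D, n_features), 1.0 / n_features)
        return cls(pool_ids=pool_ids, pi=u.copy(), theta=u.copy())


def fragment_probability(
    pi: np.ndarray, theta: np.ndarray, q: Mapping[int, float], y: int
) -> float:
    """Pr(f_i) = sum over nonzero j of pi_j * theta_j^y * q_ij."""
    if not q:
        raise ValueError("fragment has an all-zero weight row")
    total = 0.0
    for j, qj in q.items():
        total += pi[j] * (theta[j] if y else 1.0) * qj
    return total


def _unnormalized(
    params: ModelParams, matrix: WeightMatrix, row_pool: np.ndarray
) -> sp.csr_matrix:
    """u_ij = pi_Pj * theta_Pj^y_i * q_ij with the sparsity pattern of q."""
    W = matrix.weights
    rows_of_data = np.repeat(
        np.arange(W.shape[0], dtype=np.int64), np.diff(W.indptr)
    )
    pools_of_data = row_pool[rows_of_data]
    cols = W.indices
    factor = params.pi[pools_of_data, cols]
    amb = matrix.ambiguous[rows_of_data].astype(bool)
    factor = factor * np.where(amb, params.theta[pools_of_data, cols], 1.0)
    U = W.copy()
    U.data = W.data * factor
    return U


def e_step(
    params: ModelParams, matrix: WeightMatrix, pools: PoolAssignment
) -> sp.csr_matrix:
    """Posterior membership weights x, row-normalized over the fragment's
    nonzero columns.  A row whose every term vanishes under the current
    parameters is renormalized over q alone (warning logged)."""
    row_pool = pools.row_pools(matrix.barcodes)
    U = _unnormalized(params, matrix, row_pool)
    row_sums = np.asarray(U.sum(axis=1)).ravel()
    dead = row_sums == 0
    if np.any(dead):
        logger.warning(
            "%d fragment rows have zero probability under current parameters; "
            "renormalizing over alignment weights alone",
            int(dead.sum()),
        )
        W = matrix.weights
        for i in np.flatnonzero(dead):
            U.data[U.indptr[i] : U.indptr[i + 1]] = W.data[W.indptr[i] : W.indptr[i + 1]]
        row_sums = np.asarray(U.sum(axis=1)).ravel()
    rows_of_data = np.repeat(np.arange(U.shape[0], dtype=np.int64), np.diff(U.indptr))
    U.data = U.data / row_sums[rows_of_data]
    return U


def _pool_indicator(row_pool: np.ndarray, D: int) -> sp.csr_matrix:
    n = len(row_pool)
    return sp.csr_matrix(
        (np.ones(n), (row_pool, np.arange(n))), shape=(D, n)
    )


def m_step(
    posterior: sp.csr_matrix,
    matrix: WeightMatrix,
    pools: PoolAssignment,
    pi_prior: float = 0.0,
    theta_prior: float = 200000.0,
) -> ModelParams:
    """MAP parameter update with symmetric pseudocounts:

        pi_Pj    = (sum_i x_Pij + a_pi)    / (N_P + (K+1) a_pi)
        theta_Pj = (sum_i y_i x_Pij + a_th) / (sum_i y_i + (K+1) a_th)

    An empty pool gets uniform parameters and is flagged.
    """
    row_pool = pools.row_pools(matrix.barcodes)
    D = pools.D
    k1 = matrix.n_features
    S = _pool_indicator(row_pool, D)

    pi_num = np.asarray((S @ posterior).todense())  # (D, K+1) column sums per pool
    n_per_pool = np.asarray(S.sum(axis=1)).ravel()

    y = matrix.ambiguous.astype(float)
    Xy = posterior.copy()
    rows_of_data = np.repeat(
        np.arange(posterior.shape[0], dtype=np.int64), np.diff(posterior.indptr)
    )
    Xy.data = posterior.data * y[rows_of_data]
    th_num = np.asarray((S @ Xy).todense())
    y_per_pool = np.asarray(S @ y).ravel()

    pi = pi_num + pi_prior
    pi_den = n_per_pool + k1 * pi_prior
    theta = th_num + theta_prior
    th_den = y_per_pool + k1 * theta_prior

    empty: list[str] = []
    for d in range(D):
        if n_per_pool[d] == 0:
            pi[d] = 1.0
            pi_den[d] = k1
            empty.append(pools.pool_ids[d])
        elif pi_den[d] == 0:  # pi_prior == 0 cannot reach here with fragments
            pi[d] = 1.0
            pi_den[d] = k1
        if th_den[d] == 0:  # no ambiguous fragments and zero prior
            theta[d] = 1.0
            th_den[d] = k1
    pi = pi / pi_den[:, None]
    theta = theta / th_den[:, None]
    return ModelParams(
        pool_ids=list(pools.pool_ids), pi=pi, theta=theta, empty_pools=empty
    )


def complete_data_log_likelihood(
    params: ModelParams,
    posterior: sp.csr_matrix,
    matrix: WeightMatrix,
    pools: PoolAssignment,
) -> float:
    """lnL = sum over x_Pij > 0 of x_Pij * ln(pi_Pj * theta_Pj^y_i * q_ij)."""
    row_pool = pools.row_pools(matrix.barcodes)
    U = _unnormalized(params, matrix, row_pool)
    x = posterior.data
    u = U.data
    active = x > 0
    if np.any(u[active] == 0):
        warnings.warn("zero model probability where posterior mass is positive; lnL = -inf")
        return float("-inf")
    return float(np.sum(x[active] * np.log(u[active])))


def observed_data_log_likelihood(
    params: ModelParams, matrix: WeightMatrix, pools: PoolAssignment
) -> float:
    """sum_i ln sum_j pi_Pj * theta_Pj^y_i * q_ij.

    This is the EM objective evaluated at the exact posterior (the evidence
    lower bound is tight there), so it is non-decreasing across iterations;
    the complete-data lnL evaluated at successive iterates is not, which is
    why the per-iteration trace records this quantity instead.
    """
    row_pool = pools.row_pools(matrix.barcodes)
    U = _unnormalized(params, matrix, row_pool)
    row_sums = np.asarray(U.sum(axis=1)).ravel()
    if np.any(row_sums == 0):
        warnings.warn("fragment rows with zero probability; lnL = -inf")
        return float("-inf")
    return float(np.sum(np.log(row_sums)))


def _count_parameters(matrix: WeightMatrix, pools: PoolAssignment) -> int:
    """k = sum over pools of 2 x (features with >=1 aligned fragment in pool)."""
    row_pool = pools.row_pools(matrix.barcodes)
    S = _pool_indicator(row_pool, pools.D)
    occupancy = np.asarray((S @ (matrix.weights != 0)).todense())
    return int(2 * np.count_nonzero(occupancy, axis=1).sum())


@dataclass
class FittedModel:
    params: ModelParams
    posterior: sp.csr_matrix
    pools: PoolAssignment
    lnL: float
    iterations: int
    converged: bool
    k: int
    n: int
    lnL_trace: list[float]

    @property
    def BIC(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.lnL

    @property
    def AIC(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL

    def fit_report(self, out_stream: IO[str], matrix: WeightMatrix) -> None:
        row_pool = self.pools.row_pools(matrix.barcodes)
        S = _pool_indicator(row_pool, self.pools.D)
        occupancy = np.asarray((S @ (matrix.weights != 0)).todense())
        n_per_pool = np.asarray(S.sum(axis=1)).ravel().astype(int)
        out_stream.write(
            "pool\tfragments\tobserved_features\titerations\tconverged\tlnL\tk\tn\tBIC\tAIC\n"
        )
        for d, pid in enumerate(self.pools.pool_ids):
            out_stream.write(
                f"{pid}\t{n_per_pool[d]}\t{int(np.count_nonzero(occupancy[d]))}\t"
                f"{self.iterations}\t{self.converged}\t{self.lnL:.6f}\t{self.k}\t"
                f"{self.n}\t{self.BIC:.6f}\t{self.AIC:.6f}\n"
            )

    def dump_posterior(self, out_stream: IO[str], matrix: WeightMatrix) -> None:
        """Sparse triplet TSV: fragment read name, feature id, x."""
        X = self.posterior.tocoo()
        out_stream.write("fragment\tfeature\tx\n")
        for i, j, v in zip(X.row, X.col, X.data):
            out_stream.write(f"{matrix.read_names[i]}\t{matrix.feature_ids[j]}\t{v:.10g}\n")


def fit_em(
    matrix: WeightMatrix,
    pools: PoolAssignment,
    pi_prior: float = 0.0,
    theta_prior: float = 200000.0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> FittedModel:
    """Alternate E and M steps from uniform initialization until the largest
    absolute change over all pi and theta entries drops below ``tol`` or
    ``max_iter`` is reached."""
    if matrix.n_fragments == 0:
        raise ValueError("cannot fit model on an empty weight matrix")
    params = ModelParams.uniform(list(pools.pool_ids), matrix.n_features)
    trace: list[float] = [observed_data_log_likelihood(params, matrix, pools)]
    converged = False
    iterations = 0
    posterior = e_step(params, matrix, pools)
    for it in range(1, max_iter + 1):
        iterations = it
        new_params = m_step(posterior, matrix, pools, pi_prior, theta_prior)
        delta = max(
            float(np.max(np.abs(new_params.pi - params.pi))),
            float(np.max(np.abs(new_params.theta - params.theta))),
        )
        params = new_params
        posterior = e_step(params, matrix, pools)
        trace.append(observed_data_log_likelihood(params, matrix, pools))
        if delta < tol:
            converged = True
            break
    lnL = complete_data_log_likelihood(params, posterior, matrix, pools)
    return FittedModel(
        params=params,
        posterior=posterior,
        pools=pools,
        lnL=lnL,
        iterations=iterations,
        converged=converged,
        k=_count_parameters(matrix, pools),
        n=matrix.n_fragments,
        lnL_trace=trace,
    )


def model_selection(fitted: FittedModel) -> tuple[float, float]:
    """(BIC, AIC) = (k ln n - 2 lnL, 2k - 2 lnL)."""
    if fitted.n == 0:
        raise ValueError("model has zero observations")
    return fitted.BIC, fitted.AIC
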
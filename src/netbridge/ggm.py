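"""Gaussian graphical model estimation with EBIC model selection.

The estimator follows the regularize-then-refit recipe: a graphical-lasso
path proposes candidate edge supports, the support minimizing the extended
BIC after an *unregularized* constrained maximum-likelihood refit is taken
as the starting point, and a greedy stepwise search over single-edge
additions/removals refines it to a local EBIC minimum.  Edge stability is
assessed by nonparametric subject bootstrap.

The constrained MLE enforces the Dempster conditions: the fitted
covariance equals the sample covariance on the diagonal and on support
edges while the precision matrix is zero off support.  It is computed with
the classic neighbourhood-regression iteration (Hastie/Tibshirani/Friedman
Algorithm 17.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

__all__ = [
    "GGMError",
    "GGMFit",
    "BootstrapNetwork",
    "fit_ggm_support",
    "ebic",
    "glasso_path",
    "ebic_best_support",
    "stepwise_select",
    "estimate_network",
    "bootstrap_network",
]


class GGMError(RuntimeError):
    pass


@dataclass
class GGMFit:
    nodes: list[str]
    support: np.ndarray           # boolean adjacency, zero diagonal
    precision: np.ndarray
    partial_corr: np.ndarray
    covariance: np.ndarray        # fitted model covariance
    loglik: float
    n: int
    n_iter: int
    max_residual: float

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.support.sum() // 2)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        out = {}
        for i, j in zip(*np.triu_indices(self.p, k=1)):
            if self.support[i, j]:
                out[(self.nodes[i], self.nodes[j])] = float(self.partial_corr[i, j])
        return out


@dataclass
class BootstrapNetwork:
    nodes: list[str]
    median: np.ndarray      # (p, p) per-edge bootstrap median weight
    lower: np.ndarray       # 2.5th percentile
    upper: np.ndarray       # 97.5th percentile
    significant: np.ndarray  # bool, interval excludes zero
    point_fit: GGMFit
    n_replicates: int
    n_failed: int
    seed: int


def _as_support(support, p: int) -> np.ndarray:
    a = np.asarray(support, dtype=bool)
    if a.shape != (p, p) or (a != a.T).any() or a.diagonal().any():
        raise ValueError("support must be a symmetric boolean adjacency "
                         "matrix with empty diagonal")
    return a


def fit_ggm_support(corr: np.ndarray, support, n: int,
                    nodes: list[str] | None = None, tol: float = 1e-8,
                    max_iter: int = 10000) -> GGMFit:
    """Constrained Gaussian MLE for a fixed edge support.

    Parameters
    ----------
    corr : sample covariance/correlation matrix (positive definite).
    support : symmetric boolean adjacency over the nodes.
    n : sample size behind ``corr`` (enters the log-likelihood and EBIC).
    """
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    A = _as_support(support, p)
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise GGMError("input matrix is not positive definite")
    nodes = list(nodes) if nodes is not None else [f"v{i}" for i in range(p)]

    W = S.copy()
    rest_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            rest = rest_cache[j]
            nb = rest[A[rest, j]]
            w_new = np.zeros(p - 1)
            if nb.size:
                beta = np.linalg.solve(W[np.ix_(nb, nb)], S[nb, j])
                w_new = W[np.ix_(rest, nb)] @ beta
            delta = max(delta, np.abs(W[rest, j] - w_new).max(initial=0.0))
            W[rest, j] = w_new
            W[j, rest] = w_new
        if delta < tol:
            break
    else:
        resid = _dempster_residual(W, S, A)
        raise GGMError(
            f"constrained MLE did not converge in {max_iter} iterations "
            f"(residual {resid:.3e})")

    K = np.zeros((p, p))
    for j in range(p):
        rest = rest_cache[j]
        nb = rest[A[rest, j]]
        if nb.size:
            beta = np.linalg.solve(W[np.ix_(nb, nb)], S[nb, j])
            k_jj = 1.0 / (S[j, j] - W[nb, j] @ beta)
            K[j, j] = k_jj
            K[nb, j] = -beta * k_jj
        else:
            K[j, j] = 1.0 / S[j, j]
    K = (K + K.T) / 2.0
    K[~A & ~np.eye(p, dtype=bool)] = 0.0

    d = np.sqrt(np.diag(K))
    pc = -K / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = np.clip(pc, -1.0, 1.0)

    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GGMError("fitted precision is not positive definite")
    loglik = 0.5 * n * (logdet - np.trace(S @ K) - p * np.log(2 * np.pi))
    resid = _dempster_residual(W, S, A)
    return GGMFit(nodes=nodes, support=A, precision=K, partial_corr=pc,
                  covariance=W, loglik=float(loglik), n=n, n_iter=it + 1,
                  max_residual=float(resid))


def _dempster_residual(W: np.ndarray, S: np.ndarray, A: np.ndarray) -> float:
    """Max deviation of the fitted covariance from S on diagonal+support."""
    mask = A | np.eye(len(S), dtype=bool)
    return float(np.abs((W - S)[mask]).max(initial=0.0))


def ebic(fit: GGMFit, gamma: float = 0.5) -> float:
    """Extended BIC: ``-2 L + E log n + 4 E gamma log p``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    E = fit.n_edges
    return (-2.0 * fit.loglik + E * np.log(fit.n)
            + 4.0 * E * gamma * np.log(fit.p))


def glasso_path(corr: np.ndarray, n_lambdas: int = 100, ratio: float = 0.01
                ) -> list[np.ndarray]:
    """Distinct edge supports along a log-spaced graphical-lasso path.

    The path runs from ``lambda_max`` (the largest absolute off-diagonal
    entry, giving the empty graph) down to ``ratio * lambda_max``.
    Non-converging path points are skipped with a warning.
    """
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    lam_max = np.abs(S[off]).max()
    if lam_max == 0:
        return [np.zeros((p, p), dtype=bool)]
    lams = np.geomspace(lam_max, ratio * lam_max, n_lambdas)
    supports: list[np.ndarray] = [np.zeros((p, p), dtype=bool)]
    failures = []
    for lam in lams:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except Exception as exc:  # noqa: BLE001 - per-lambda diagnostics
            failures.append((float(lam), str(exc)))
            continue
        A = (np.abs(prec) > 1e-8) & off
        A = A | A.T
        if not any(np.array_equal(A, s) for s in supports):
            supports.append(A)
    if failures:
        warnings.warn(f"glasso failed at {len(failures)} path points "
                      f"(first: lambda={failures[0][0]:.3g}: {failures[0][1]})",
                      RuntimeWarning, stacklevel=2)
    return supports


def ebic_best_support(corr: np.ndarray, n: int, supports: list[np.ndarray],
                      gamma: float = 0.5,
                      nodes: list[str] | None = None) -> GGMFit:
    """Unregularized refit of each candidate support; returns the EBIC-best."""
    best_fit, best_val = None, np.inf
    for A in supports:
        try:
            fit = fit_ggm_support(corr, A, n, nodes=nodes)
        except GGMError:
            continue
        val = ebic(fit, gamma)
        if val < best_val - 1e-12:
            best_fit, best_val = fit, val
    if best_fit is None:
        raise GGMError("no candidate support could be fitted")
    return best_fit


def stepwise_select(corr: np.ndarray, n: int, start_support,
                    gamma: float = 0.5,
                    nodes: list[str] | None = None) -> GGMFit:
    """Greedy single-edge addition/removal search to a local EBIC minimum.

    At each step every single-edge toggle is refit without regularization;
    the move with the largest EBIC decrease is accepted (ties broken by
    lexicographic edge order).
    """
    S = np.asarray(corr, dtype=float)
    p = S.shape[0]
    A = _as_support(start_support, p).copy()
    current = fit_ggm_support(S, A, n, nodes=nodes)
    current_val = ebic(current, gamma)
    pairs = list(combinations(range(p), 2))
    while True:
        best_move, best_fit, best_val = None, None, current_val
        for (i, j) in pairs:
            A[i, j] = A[j, i] = not A[i, j]
            try:
                fit = fit_ggm_support(S, A, n, nodes=nodes)
                val = ebic(fit, gamma)
            except GGMError:
                val = np.inf
                fit = None
            A[i, j] = A[j, i] = not A[i, j]
            if val < best_val - 1e-10:
                best_move, best_fit, best_val = (i, j), fit, val
        if best_move is None:
            return current
        i, j = best_move
        A[i, j] = A[j, i] = not A[i, j]
        current, current_val = best_fit, best_val


def estimate_network(data: pd.DataFrame, gamma: float = 0.5,
                     n_lambdas: int = 100) -> GGMFit:
    """Full GGM pipeline on a subjects x nodes table.

    Complete-case Pearson correlation -> glasso path -> EBIC-best
    unregularized refit -> stepwise refinement.
    """
    df = data.dropna()
    n, p = df.shape
    if n < p + 2:
        raise GGMError(f"need at least p+2 complete rows ({n} < {p + 2})")
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    nodes = list(df.columns)
    supports = glasso_path(corr, n_lambdas=n_lambdas)
    start = ebic_best_support(corr, n, supports, gamma, nodes=nodes)
    return stepwise_select(corr, n, start.support, gamma, nodes=nodes)


def bootstrap_network(data: pd.DataFrame, B: int = 1000, gamma: float = 0.5,
                      seed: int = 0, n_lambdas: int = 100) -> BootstrapNetwork:
    """Nonparametric subject bootstrap of the full GGM pipeline.

    Per replicate the entire estimation (glasso path + EBIC + stepwise) is
    re-run on a resample; absent edges contribute weight 0.  An edge is
    flagged significant when its 2.5-97.5 percentile interval excludes
    zero.  Replicates whose fit fails are dropped; more than 10% failures
    reject the run.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    df = data.dropna()
    n, p = df.shape
    if n < p + 2:
        raise GGMError(f"need at least p+2 complete rows ({n} < {p + 2})")
    point = estimate_network(df, gamma, n_lambdas=n_lambdas)
    rng = np.random.default_rng(seed)
    weights = np.zeros((B, p, p))
    failed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            fit = estimate_network(df.iloc[idx], gamma, n_lambdas=n_lambdas)
        except GGMError:
            failed += 1
            weights[b] = np.nan
            continue
        weights[b] = fit.partial_corr * fit.support
    if failed > 0.1 * B:
        raise GGMError(f"{failed}/{B} bootstrap replicates failed")
    ok = ~np.isnan(weights[:, 0, 0])
    w = weights[ok]
    med = np.median(w, axis=0)
    lo = np.percentile(w, 2.5, axis=0)
    hi = np.percentile(w, 97.5, axis=0)
    sig = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    return BootstrapNetwork(nodes=list(df.columns), median=med, lower=lo,
                            upper=hi, significant=sig, point_fit=point,
                            n_replicates=int(ok.sum()), n_failed=failed,
                            seed=seed)


def network_edge_list(boot: BootstrapNetwork) -> pd.DataFrame:
    """CSV-ready edge list (node_a, node_b, weight, median, lo, hi, significant)."""
    rows = []
    p = len(boot.nodes)
    fit = boot.point_fit
    for i, j in zip(*np.triu_indices(p, k=1)):
        rows.append({
            "node_a": boot.nodes[i], "node_b": boot.nodes[j],
            "weight": float(fit.partial_corr[i, j] * fit.support[i, j]),
            "median": float(boot.median[i, j]),
            "lo": float(boot.lower[i, j]), "hi": float(boot.upper[i, j]),
            "significant": bool(boot.significant[i, j]),
        })
    return pd.DataFrame(rows)
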
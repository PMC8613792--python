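"""Metric multidimensional scaling by stress majorization (SMACOF).

The ordination embeds an n x n Euclidean dissimilarity matrix into two
dimensions by iteratively minimizing raw Kruskal stress with the Guttman
transform. Each restart's stress trace is monotone non-increasing (a
property of majorization) and is kept on the result for verification.
Goodness of fit is summarized two ways:

* ``stress1`` — Kruskal's stress-1, sqrt(sum (d - delta)^2 / sum delta^2);
* ``sstress`` — the ALSCAL-style S-Stress on squared distances,
  sqrt(sum (d^2 - delta^2)^2 / sum delta^4);

and ``r2``, the squared Pearson correlation between input dissimilarities
and configuration distances over all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateConfigurationError, InputError


@dataclass
class MDSSolution:
    coordinates: np.ndarray  # (n, 2)
    stress1: float
    sstress: float
    r2: float
    raw_stress: float
    converged: bool
    n_iter: int
    stress_trace: np.ndarray  # raw stress per iteration of the winning restart


def check_dissimilarities(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError(f"dissimilarity matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InputError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise InputError("dissimilarity matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise InputError("dissimilarities must be nonnegative")
    return np.clip(D, 0.0, None)


def classical_scaling(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson's classical scaling: eigendecompose the double-centered
    squared-dissimilarity matrix and keep the leading axes."""
    D = check_dissimilarities(D)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(w_top)
    if X.shape[1] < n_components:
        X = np.hstack([X, np.zeros((n, n_components - X.shape[1]))])
    return X


def _guttman_step(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    dist = squareform(pdist(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist > 0, D / dist, 0.0)
    B = -ratio
    np.fill_diagonal(B, 0.0)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def _raw_stress(X: np.ndarray, D: np.ndarray) -> float:
    d = pdist(X)
    delta = squareform(D, checks=False)
    return float(((d - delta) ** 2).sum())


def _fit_measures(X: np.ndarray, D: np.ndarray) -> tuple[float, float, float]:
    d = pdist(X)
    delta = squareform(D, checks=False)
    denom1 = float((delta**2).sum())
    denom2 = float((delta**4).sum())
    if denom1 == 0.0:
        raise DegenerateConfigurationError("all dissimilarities are zero")
    stress1 = float(np.sqrt(((d - delta) ** 2).sum() / denom1))
    sstress = float(np.sqrt(((d**2 - delta**2) ** 2).sum() / denom2))
    if np.std(d) == 0.0 or np.std(delta) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(d, delta)[0, 1] ** 2)
    return stress1, sstress, r2


def smacof(
    D: np.ndarray,
    n_components: int = 2,
    n_restarts: int = 4,
    max_iter: int = 1000,
    tol: float = 1e-9,
    seed: int = 0,
    row_keys: np.ndarray | None = None,
) -> MDSSolution:
    """Best-of-restarts SMACOF.

    One restart starts from the classical-scaling solution; the remaining
    ``n_restarts - 1`` start from seeded random configurations drawn from a
    counter-based stream, so the whole fit is reproducible from a single
    integer. When ``row_keys`` (one integer per row, e.g. a label hash) is
    given, each row's random start depends only on ``(seed, restart,
    row_key)``, which makes the fit equivariant under row permutations.
    Convergence is a relative raw-stress change below ``tol``; the winner
    across restarts is the configuration with the lowest raw stress.
    """
    D = check_dissimilarities(D)
    n = D.shape[0]
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    if n == 1:
        return MDSSolution(np.zeros((1, n_components)), 0.0, 0.0, 0.0, 0.0, True, 0, np.zeros(1))
    if not squareform(D, checks=False).any():
        raise DegenerateConfigurationError("all rows coincide: every dissimilarity is zero")

    if row_keys is not None and len(row_keys) != n:
        raise InputError("row_keys length must match the matrix size")
    scale = float(squareform(D, checks=False).max())
    base_seed = seed & 0x7FFFFFFF
    inits = [classical_scaling(D, n_components)]
    for k in range(1, n_restarts):
        if row_keys is None:
            rng = np.random.default_rng([base_seed, k])
            inits.append(rng.normal(scale=scale, size=(n, n_components)))
        else:
            rows = [
                np.random.default_rng([base_seed, k, int(key) & 0x7FFFFFFF]).normal(
                    scale=scale, size=n_components
                )
                for key in row_keys
            ]
            inits.append(np.vstack(rows))

    best: MDSSolution | None = None
    for X0 in inits:
        X = X0.copy()
        trace = [_raw_stress(X, D)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            X = _guttman_step(X, D)
            s = _raw_stress(X, D)
            trace.append(s)
            prev = trace[-2]
            if prev > 0 and (prev - s) / prev < tol:
                converged = True
                break
            if s == 0.0:
                converged = True
                break
        stress1, sstress, r2 = _fit_measures(X, D)
        sol = MDSSolution(X, stress1, sstress, r2, trace[-1], converged, it, np.asarray(trace))
        if best is None or sol.raw_stress < best.raw_stress:
            best = sol
    return best
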
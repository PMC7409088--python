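"""Conditional-independence network extraction from ordinal item data.

Pipeline per respondent role:

1. Spearman correlation matrix R from pairwise-complete observations
   (such a matrix need not be positive semidefinite);
2. ridge-penalized precision estimate with target T: with
   A = R - lambda*T, the penalized-likelihood stationarity condition
   ``Omega^{-1} - R - lambda (Omega - T) = 0`` has the closed-form
   solution ``Omega(lambda) = { A/2 + [A^2/4 + lambda I]^{1/2} }^{-1}``,
   evaluated in the eigenbasis of A; the estimate is symmetric positive
   definite for any symmetric R and lambda > 0;
3. penalty selection by conditioning: the spectral condition number
   kappa(lambda) of Omega(lambda) approximates the digits of numerical
   accuracy lost as log10(kappa); the smallest grid lambda whose loss
   does not exceed ``max_digits`` (default 2) is chosen, i.e. the least
   shrinkage compatible with a numerically well-behaved estimate;
4. partial correlations rho_ij = -omega_ij / sqrt(omega_ii omega_jj);
5. edge support by local false discovery rate: the off-diagonal partial
   correlations are modeled as the two-component mixture
   ``f(r) = eta0 f0(r; k) + (1 - eta0) / 2`` on (-1, 1), where
   ``f0(r; k) = (1 - r^2)^{(k-3)/2} / B(1/2, (k-1)/2)`` is the null
   density of a sample correlation at k effective degrees of freedom
   (estimated, since ridge shrinkage invalidates the nominal n - p - 1)
   and the alternative is uniform.  The posterior probability that an
   edge is present, ``(1 - eta0) (1/2) / f(r)``, must reach the
   retention threshold (default 0.75, inclusive) for the edge to be
   kept, with its signed partial correlation as weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .dataset_io import ResponseMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    r: pd.DataFrame
    pairwise_n: pd.DataFrame

    @property
    def items(self) -> list[str]:
        return list(self.r.columns)


def spearman_pairwise(
    m: ResponseMatrix, min_pairs: int = 3, impute_undefined: bool = True
) -> CorrelationMatrix:
    """Pairwise-complete Spearman matrix with pairwise-n bookkeeping.

    Entries with fewer than ``min_pairs`` complete pairs are undefined;
    by default they are imputed as 0 with a warning so that estimation
    can proceed on heavily missing items.
    """
    if len(m.items) < 2:
        raise ValueError("need at least 2 items")
    all_missing = [c for c in m.items if m.data[c].isna().all()]
    if all_missing:
        raise ValueError(f"items with no observations: {all_missing}")
    corr = m.data.corr(method="spearman", min_periods=min_pairs)
    notna = m.data.notna().astype(float)
    n_pair = pd.DataFrame(
        (notna.T.to_numpy() @ notna.to_numpy()).astype(int),
        index=m.items,
        columns=m.items,
    )
    np.fill_diagonal(corr.values, 1.0)
    n_undef = int(np.isnan(corr.to_numpy()).sum())
    if n_undef:
        if not impute_undefined:
            raise ValueError(f"{n_undef} undefined pairwise correlations")
        logger.warning(
            "imputing %d undefined pairwise correlations as 0", n_undef // 2
        )
        corr = corr.fillna(0.0)
    return CorrelationMatrix(r=corr, pairwise_n=n_pair)


@dataclass(frozen=True)
class RidgeEstimate:
    omega: np.ndarray
    lam: float
    target: np.ndarray
    items: tuple[str, ...]

    @property
    def condition_number(self) -> float:
        ev = np.linalg.eigvalsh(self.omega)
        return float(ev[-1] / ev[0])

    @property
    def digits_lost(self) -> float:
        return math.log10(self.condition_number)


def default_target(r: np.ndarray) -> np.ndarray:
    """Scalar-identity shrinkage target p/trace(R) * I (= I for a
    correlation-scale input); keeps the estimator rotation-equivariant."""
    p = r.shape[0]
    return np.eye(p) * (p / np.trace(r))


def ridge_precision(
    r: np.ndarray | pd.DataFrame,
    lam: float,
    target: np.ndarray | None = None,
    items: tuple[str, ...] | None = None,
) -> RidgeEstimate:
    """Closed-form ridge precision estimate (see module docstring)."""
    if lam <= 0:
        raise ValueError("penalty must be positive")
    if isinstance(r, pd.DataFrame):
        items = items or tuple(r.columns)
        r = r.to_numpy()
    r = np.asarray(r, dtype=float)
    if not np.allclose(r, r.T):
        raise ValueError("input matrix must be symmetric")
    t = default_target(r) if target is None else np.asarray(target, dtype=float)
    a = r - lam * t
    evals, evecs = np.linalg.eigh((a + a.T) / 2)
    # inverse of per-eigenvalue d/2 + sqrt(d^2/4 + lambda), always > 0
    inv_spec = 1.0 / (evals / 2 + np.sqrt(evals**2 / 4 + lam))
    omega = (evecs * inv_spec) @ evecs.T
    omega = (omega + omega.T) / 2
    if items is None:
        items = tuple(f"V{i + 1}" for i in range(r.shape[0]))
    return RidgeEstimate(omega=omega, lam=lam, target=t, items=tuple(items))


def default_penalty_grid(n_points: int = 200) -> np.ndarray:
    return np.logspace(-4, 2, n_points)


def select_penalty(
    r: np.ndarray | pd.DataFrame,
    target: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    max_digits: float = 2.0,
) -> tuple[float, pd.DataFrame]:
    """Smallest grid penalty whose estimate loses at most ``max_digits``
    digits of accuracy (log10 of the condition number); also returns
    the full (lambda, kappa, digits_lost) path."""
    grid = default_penalty_grid() if grid is None else np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any():
        raise ValueError("penalty grid must be strictly increasing")
    rows = []
    lam_star = None
    for lam in grid:
        est = ridge_precision(r, lam, target)
        kappa = est.condition_number
        digits = math.log10(kappa)
        rows.append({"lam": lam, "kappa": kappa, "digits_lost": digits})
        if lam_star is None and digits <= max_digits:
            lam_star = float(lam)
    path = pd.DataFrame(rows)
    if lam_star is None:
        raise ValueError(
            "no grid penalty satisfies the conditioning bound; minimum "
            f"digits lost = {path['digits_lost'].min():.3f}"
        )
    return lam_star, path


def partial_correlations(est: RidgeEstimate) -> pd.DataFrame:
    """Unordered item pairs with rho_ij = -omega_ij/sqrt(omega_ii omega_jj)."""
    d = np.sqrt(np.diag(est.omega))
    rho = -est.omega / np.outer(d, d)
    items = est.items
    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            rows.append(
                {"item_i": items[i], "item_j": items[j], "rho": float(rho[i, j])}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LfdrFit:
    eta0: float
    k_df: float
    loglik: float
    converged: bool
    degenerate: bool = False

    def null_density(self, r: np.ndarray) -> np.ndarray:
        return _null_density(np.asarray(r, dtype=float), self.k_df)

    def mixture_density(self, r: np.ndarray) -> np.ndarray:
        return self.eta0 * self.null_density(r) + (1 - self.eta0) * 0.5

    def posterior_present(self, r: np.ndarray) -> np.ndarray:
        """Posterior probability the edge is real: alternative share of
        the mixture density at the observed partial correlation."""
        r = np.asarray(r, dtype=float)
        if self.degenerate or self.eta0 >= 1.0:
            return np.zeros_like(r)
        return (1 - self.eta0) * 0.5 / self.mixture_density(r)


def _null_density(r: np.ndarray, k: float) -> np.ndarray:
    log_b = special.betaln(0.5, (k - 1) / 2)
    inside = np.clip(1 - r**2, 1e-300, None)
    return np.exp((k - 3) / 2 * np.log(inside) - log_b)


def _neg_loglik(params: np.ndarray, r: np.ndarray) -> float:
    eta0, log_k = params
    k = math.exp(log_k)
    f = eta0 * _null_density(r, k) + (1 - eta0) * 0.5
    return -float(np.sum(np.log(np.clip(f, 1e-300, None))))


def fit_lfdr(
    partials: np.ndarray,
    tol: float = 1e-6,
    k_grid: np.ndarray | None = None,
    eta0_grid: np.ndarray | None = None,
) -> LfdrFit:
    """Maximum-likelihood fit of the null/uniform mixture by a coarse
    grid search followed by bounded quasi-Newton refinement."""
    r = np.asarray(partials, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 10:
        raise ValueError("need at least 10 partial correlations")
    if not ((r > -1) & (r < 1)).all():
        raise ValueError("partial correlations must lie in (-1, 1)")
    if np.ptp(r) == 0:
        return LfdrFit(eta0=1.0, k_df=4.0, loglik=math.nan, converged=False,
                       degenerate=True)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)

    k_grid = np.logspace(math.log10(4), 5, 40) if k_grid is None else k_grid
    eta0_grid = np.linspace(0.0, 1.0, 21) if eta0_grid is None else eta0_grid
    best, best_nll = None, math.inf
    for k in k_grid:
        for eta0 in eta0_grid:
            nll = _neg_loglik(np.array([eta0, math.log(k)]), r)
            if nll < best_nll:
                best_nll, best = nll, (eta0, k)

    res = optimize.minimize(
        _neg_loglik,
        x0=np.array([best[0], math.log(best[1])]),
        args=(r,),
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (math.log(3.0 + 1e-6), math.log(1e6))],
        options={"ftol": tol},
    )
    eta0, log_k = res.x
    nll = min(best_nll, float(res.fun))
    if res.fun > best_nll:  # refinement failed to improve; keep grid point
        eta0, log_k = best[0], math.log(best[1])
    return LfdrFit(
        eta0=float(eta0),
        k_df=float(math.exp(log_k)),
        loglik=-nll,
        converged=bool(res.success),
    )


def sparsify(
    edges: pd.DataFrame, fit: LfdrFit, retention: float = 0.75
) -> pd.DataFrame:
    """Attach posteriors and the retained flag (inclusive threshold)."""
    out = edges.copy()
    out["posterior"] = fit.posterior_present(out["rho"].to_numpy())
    out["retained"] = out["posterior"] >= retention
    return out


@dataclass
class NetworkResult:
    edges: pd.DataFrame  # item_i, item_j, rho, posterior, retained
    estimate: RidgeEstimate
    lam: float
    path: pd.DataFrame
    lfdr: LfdrFit

    @property
    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"]].reset_index(drop=True)


def extract_network(
    m: ResponseMatrix,
    min_pairs: int = 3,
    grid: np.ndarray | None = None,
    max_digits: float = 2.0,
    retention: float = 0.75,
) -> NetworkResult:
    """Full extraction for one respondent role (steps 1-5 above)."""
    corr = spearman_pairwise(m, min_pairs=min_pairs)
    lam, path = select_penalty(corr.r, grid=grid, max_digits=max_digits)
    est = ridge_precision(corr.r, lam)
    edges = partial_correlations(est)
    fit = fit_lfdr(edges["rho"].to_numpy())
    edges = sparsify(edges, fit, retention=retention)
    return NetworkResult(edges=edges, estimate=est, lam=lam, path=path, lfdr=fit)
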
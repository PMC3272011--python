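"""Correlation-scale PCA of the cohort matrix with two retention criteria.

The assembly x feature matrix mixes counts spanning orders of magnitude
with bp-scale metrics such as N50, so principal components are extracted
from the sample correlation matrix (z-scored columns).  Two rules decide
how many components carry signal:

* the 80%-cumulative-variance heuristic, and
* a random-matrix-theory rule: fit the Marčenko–Pastur (MP) law — the
  limiting eigenvalue distribution of pure-noise sample covariance
  matrices — to the empirical spectrum and keep only eigenvalues above the
  fitted bulk edge λ₊ = σ²(1 + √γ)², γ = p/n.

A Kaiser-style count (eigenvalues > 1) is available as a secondary
reference, which is meaningful on the correlation scale only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    loadings: pd.DataFrame           # feature x PC, unit-norm columns
    explained_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    n_obs: int
    n_var: int


@dataclass
class MPFit:
    """Fitted Marčenko–Pastur bulk: aspect ratio, noise scale and edges."""

    gamma: float
    sigma2: float
    lambda_minus: float
    lambda_plus: float
    fit_distance: float


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, sample SD 1, ddof=1); constant columns
    are dropped with a warning."""
    if matrix.shape[0] < 2:
        raise ValueError("standardize needs at least 2 rows")
    X = matrix.astype(float)
    sd = X.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    return (X - X.mean(axis=0)) / sd


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Eigen-decomposition of the sample correlation matrix of a
    standardized cohort matrix.

    Loadings are sign-fixed so that each component's largest-magnitude
    coefficient is positive, making the tables reproducible.
    """
    Z = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite values in matrix")
    n, p = Z.shape
    corr = Z.T @ Z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(p):
        imax = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[imax, j] < 0:
            eigvecs[:, j] *= -1
    frac = eigvals / eigvals.sum()
    loadings = pd.DataFrame(
        eigvecs,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(p)],
    )
    return PCAResult(
        eigenvalues=eigvals,
        loadings=loadings,
        explained_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
        n_obs=n,
        n_var=p,
    )


def retain_by_variance(result: PCAResult, threshold: float = 0.80) -> int:
    """Smallest k whose leading components explain >= ``threshold`` of the
    total variance."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return int(np.searchsorted(result.cumulative_fraction, threshold - 1e-12) + 1)


# ---------------------------------------------------------------------------
# Marčenko–Pastur


def mp_edges(gamma: float, sigma2: float) -> tuple[float, float]:
    root = np.sqrt(gamma)
    return sigma2 * (1 - root) ** 2, sigma2 * (1 + root) ** 2


def mp_pdf(x, gamma: float, sigma2: float):
    """MP density on the absolutely continuous part of the bulk."""
    lo, hi = mp_edges(gamma, sigma2)
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    inside = (x > lo) & (x < hi)
    xi = x[inside]
    out[inside] = np.sqrt((hi - xi) * (xi - lo)) / (2 * np.pi * gamma * sigma2 * xi)
    return out


def mp_cdf(x, gamma: float, sigma2: float, _grid: int = 2001):
    """MP distribution function, including the point mass at zero for
    gamma > 1 (more variables than observations)."""
    lo, hi = mp_edges(gamma, sigma2)
    grid = np.linspace(lo, hi, _grid)
    dens = mp_pdf(grid, gamma, sigma2)
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    if cdf[-1] > 0:
        cdf /= cdf[-1]
    mass0 = max(0.0, 1.0 - 1.0 / gamma)
    return mass0 + (1 - mass0) * np.interp(x, grid, cdf, left=0.0, right=1.0)


def fit_mp(
    eigenvalues,
    gamma: float,
    sigma2_grid=None,
) -> MPFit:
    """Fit sigma2 by grid search minimizing the Cramér–von Mises distance
    between the MP CDF and the empirical eigenvalue CDF."""
    eigs = np.sort(np.asarray(eigenvalues, dtype=float))
    if len(eigs) < 3:
        raise ValueError("need at least 3 eigenvalues to fit the MP bulk")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if np.ptp(eigs) == 0:
        raise ValueError("degenerate spectrum: all eigenvalues equal")
    if sigma2_grid is None:
        sigma2_grid = np.arange(0.05, 3.0 + 1e-9, 0.01)
    emp = (np.arange(1, len(eigs) + 1) - 0.5) / len(eigs)
    best_s2, best_d = None, np.inf
    for s2 in sigma2_grid:
        d = float(np.mean((mp_cdf(eigs, gamma, s2) - emp) ** 2))
        if d < best_d:
            best_s2, best_d = float(s2), d
    lo, hi = mp_edges(gamma, best_s2)
    return MPFit(
        gamma=float(gamma),
        sigma2=best_s2,
        lambda_minus=lo,
        lambda_plus=hi,
        fit_distance=best_d,
    )


def retain_by_mp(result: PCAResult, fit: MPFit) -> int:
    """Number of eigenvalues strictly above the fitted MP bulk edge —
    the components regarded as informative by the random-matrix rule."""
    return int(np.sum(result.eigenvalues > fit.lambda_plus))


def retain_by_kaiser(result: PCAResult) -> int:
    """Secondary count: eigenvalues strictly greater than one (correlation
    scale only)."""
    return int(np.sum(result.eigenvalues > 1.0))
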
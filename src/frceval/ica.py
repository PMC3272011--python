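"""ICA-based selection of a compact informative feature subset.

The cohort matrix is decomposed as X = A·S by FastICA into statistically
independent, non-Gaussian sources.  Sources are ranked by the magnitude of
their excess kurtosis (a strongly peaked or strongly flat source departs
most from what the central limit theorem would produce by accident); the
most non-Gaussian components are retained, and from each retained
component the single feature with the largest mixing-matrix contribution
is selected.  The union of those features is the reduced feature space on
which Feature-Response Curves become easier to read.

ICA is run on the standardized feature columns only — the N50 and
NUM_CONTIG metric columns are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .features import METRIC_COLUMNS

_SEED_STRIDE = 7919  # derive restart seeds; keeps them below 2**31


@dataclass
class ICAResult:
    """Mixing matrix, sources, and per-component kurtosis of one ICA run."""

    mixing: pd.DataFrame              # feature x IC (the A in X = A S)
    sources: np.ndarray               # IC x observation (the S)
    kurtosis: np.ndarray              # excess kurtosis per IC source
    seed: int
    n_restarts_used: int = 1
    retained_ics: list[int] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]


def excess_kurtosis(samples) -> float:
    """Fisher excess kurtosis in population-moment form:
    m4 / m2**2 - 3 (zero for a Gaussian)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    x = x - x.mean()
    m2 = np.mean(x**2)
    if m2 == 0:
        raise ValueError("zero variance")
    return float(np.mean(x**4) / m2**2 - 3.0)


def _drop_metric_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in matrix.columns if c not in METRIC_COLUMNS]
    return matrix[keep]


def run_ica(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ICAResult:
    """FastICA on a standardized cohort matrix (feature columns only).

    Up to ``n_restarts`` runs with derived seeds are performed; the
    solution with the largest total |excess kurtosis| of its sources is
    kept (mixtures of independent sources are less kurtotic than the
    sources themselves, so this favours the best-separated solution).
    Source signs are fixed to positive skewness, falling back to a
    positive largest-magnitude mixing coefficient for symmetric sources.
    """
    Z = _drop_metric_columns(matrix)
    n_obs, n_var = Z.shape
    if n_components is None:
        n_components = min(n_var, n_obs - 1)
    if n_components > min(n_var, n_obs - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_obs - 1, n_var)="
            f"{min(n_obs - 1, n_var)}"
        )
    X = Z.to_numpy(dtype=float)

    best = None
    n_used = 0
    last_err: Exception | None = None
    for r in range(n_restarts):
        rstate = (seed + _SEED_STRIDE * r) % (2**31)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                est = FastICA(
                    n_components=n_components,
                    algorithm="parallel",
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=rstate,
                )
                S = est.fit_transform(X)           # n_obs x IC
            converged = True
        except ConvergenceWarning as err:  # keep it as fallback only
            last_err = err
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est = FastICA(
                    n_components=n_components,
                    algorithm="parallel",
                    fun="logcosh",
                    whiten="unit-variance",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=rstate,
                )
                S = est.fit_transform(X)
            converged = False
        n_used = r + 1
        kurt = stats.kurtosis(S, axis=0, fisher=True, bias=True)
        score = float(np.abs(kurt).sum())
        key = (converged, score)
        if best is None or key > best[0]:
            best = (key, est.mixing_.copy(), S.copy(), kurt.copy())
    if best is None:
        raise RuntimeError(f"FastICA failed after {n_restarts} restarts: {last_err}")
    if not best[0][0]:
        warnings.warn("FastICA did not converge in any restart; using best effort")

    _, mixing, S, kurt = best
    # sign convention
    for j in range(n_components):
        skew = stats.skew(S[:, j], bias=True)
        if abs(skew) > 1e-8:
            flip = skew < 0
        else:
            flip = mixing[np.argmax(np.abs(mixing[:, j])), j] < 0
        if flip:
            S[:, j] *= -1
            mixing[:, j] *= -1

    mixing_df = pd.DataFrame(
        mixing, index=Z.columns, columns=[f"IC{i + 1}" for i in range(n_components)]
    )
    return ICAResult(
        mixing=mixing_df,
        sources=S.T,
        kurtosis=np.asarray(kurt, dtype=float),
        seed=seed,
        n_restarts_used=n_used,
        retained_ics=list(range(n_components)),
    )


def retain_ics(
    result: ICAResult,
    fraction: float = 0.80,
    method: str = "cumulative",
) -> list[int]:
    """Retain the most non-Gaussian independent components.

    method="cumulative" (default): sort ICs by |excess kurtosis| descending
    (ties by index) and keep the shortest prefix holding >= ``fraction`` of
    the total |kurtosis| mass.  method="percentile": keep ICs whose
    |kurtosis| reaches the (1 - fraction) quantile of the |kurtosis|
    distribution.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    kabs = np.abs(result.kurtosis)
    total = kabs.sum()
    if total == 0:
        warnings.warn("all components have zero kurtosis; nothing to retain")
        return []
    order = np.argsort(-kabs, kind="stable")
    if method == "cumulative":
        kept: list[int] = []
        acc = 0.0
        for i in order:
            if kabs[i] == 0 and fraction >= 1:
                break
            kept.append(int(i))
            acc += kabs[i]
            if acc >= fraction * total - 1e-12:
                break
        return kept
    if method == "percentile":
        cut = np.quantile(kabs, 1 - fraction)
        return [int(i) for i in order if kabs[i] >= cut and kabs[i] > 0]
    raise ValueError(f"unknown retention method {method!r}")


def select_features(result: ICAResult, retained: list[int] | None = None) -> list[str]:
    """From each retained IC, the feature with the largest |mixing
    coefficient|; duplicates removed preserving first occurrence."""
    if retained is None:
        retained = result.retained_ics
    if not retained:
        raise ValueError("no retained components to select features from")
    A = result.mixing.to_numpy()
    names = list(result.mixing.index)
    out: list[str] = []
    for ic in retained:
        feat = names[int(np.argmax(np.abs(A[:, ic])))]
        if feat not in out:
            out.append(feat)
    return out


def select_informative_features(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    fraction: float = 0.80,
    seed: int = 0,
    method: str = "cumulative",
) -> tuple[list[str], ICAResult]:
    """Full selection pipeline: ICA, kurtosis ranking, per-IC argmax.

    Returns the ordered selected feature list and the underlying result,
    whose ``retained_ics``/``selected_features`` fields are filled in.
    """
    result = run_ica(matrix, n_components=n_components, seed=seed)
    retained = retain_ics(result, fraction=fraction, method=method)
    result.retained_ics = retained
    result.selected_features = select_features(result, retained) if retained else []
    return result.selected_features, result
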
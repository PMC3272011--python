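"""Feature-Response Curves.

The FRC summarizes the trade-off between contig size and contig
trustworthiness.  Contigs are sorted by size; for a feature threshold phi,
the longest prefix of that order whose cumulative diagnostic-feature count
stays <= phi is tallied, and the summed length of the prefix over the
genome size is the approximate genome coverage attained at phi.  Sweeping
phi from 0 to the total feature count traces the curve; a better assembly
reaches high coverage at a low feature budget.

The curve can be computed on the full feature space or restricted to any
subset of analysis feature types (for example, an ICA-selected subset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import Assembly, CountingConfig, FeatureCountTable, _check_subset, count_features


@dataclass
class FRCurve:
    """The (phi -> coverage) response curve of one assembly."""

    phi: np.ndarray
    coverage: np.ndarray
    genome_size: int
    feature_subset: tuple[str, ...] | None  # None means the full space
    label: str = ""

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if len(self.phi) != len(self.coverage):
            raise ValueError("phi and coverage length mismatch")
        if len(self.phi) == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.label, "phi": self.phi, "coverage": self.coverage}
        )


def _sorted_contigs(assembly: Assembly):
    # length descending, ties broken by id ascending, for determinism
    return sorted(assembly.contigs, key=lambda c: (-c.length, c.id))


def compute_frc(
    assembly: Assembly,
    counts: FeatureCountTable | None = None,
    subset: Iterable[str] | None = None,
    genome_size: int | None = None,
    thresholds: Sequence[int] | None = None,
    cfg: CountingConfig | None = None,
    per_contig: bool = False,
) -> FRCurve:
    """Compute the Feature-Response Curve of one assembly.

    Parameters
    ----------
    counts
        Precomputed per-contig count table; computed from ``cfg`` if absent.
    subset
        Analysis feature types to restrict the curve to (default: all).
    genome_size
        Coverage denominator; falls back to the assembly's genome-size
        estimate, then to the total assembly length.
    thresholds
        Explicit phi values; default is every integer 0..total feature count.
    per_contig
        Variant semantics: instead of accumulating feature counts along the
        size-sorted prefix, tally every contig whose own count is <= phi.
    """
    if counts is None:
        counts = count_features(assembly, cfg)
    if genome_size is None:
        genome_size = assembly.genome_size or assembly.total_length
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")

    if subset is None:
        per_ctg = counts.totals
        subset_t = None
    else:
        subset_cols = _check_subset(subset, counts.counts.columns)
        per_ctg = counts.counts[subset_cols].sum(axis=1)
        subset_t = tuple(subset_cols)

    order = _sorted_contigs(assembly)
    lengths = np.array([c.length for c in order], dtype=float)
    ctg_counts = np.array([per_ctg.get(c.id, 0) for c in order], dtype=float)

    total = int(ctg_counts.sum())
    if thresholds is None:
        phi = np.arange(0, total + 1)
    else:
        phi = np.asarray(sorted(set(int(t) for t in thresholds)))
        if len(phi) and phi[0] < 0:
            raise ValueError("negative feature threshold")

    if per_contig:
        # each contig contributes as soon as its own count fits the budget
        cov = np.array(
            [lengths[ctg_counts <= p].sum() for p in phi], dtype=float
        )
    else:
        cum_counts = np.cumsum(ctg_counts)
        cum_lengths = np.cumsum(lengths)
        # longest prefix with cumulative count <= phi
        idx = np.searchsorted(cum_counts, phi, side="right")
        cov = np.where(idx > 0, cum_lengths[np.maximum(idx, 1) - 1], 0.0)
    return FRCurve(
        phi=phi,
        coverage=cov / genome_size,
        genome_size=int(genome_size),
        feature_subset=subset_t,
        label=assembly.label,
    )


def frc_auc(curve: FRCurve, phi_max: int | None = None) -> float:
    """Normalized trapezoidal area under the curve over [0, phi_max].

    The curve is extended at its last coverage value up to ``phi_max``;
    the result lies in [0, 1] and is the natural scalar for ranking curves.
    """
    phi = np.asarray(curve.phi, dtype=float)
    cov = curve.coverage
    if phi_max is None:
        phi_max = float(phi[-1])
    if phi_max < phi[-1]:
        keep = phi <= phi_max
        phi, cov = phi[keep], cov[keep]
    if phi_max > phi[-1]:
        phi = np.append(phi, phi_max)
        cov = np.append(cov, cov[-1])
    if len(phi) == 1:  # degenerate single-point curve
        return float(cov[0])
    return float(np.trapezoid(cov, phi) / (phi[-1] - phi[0]))


def compare_frc(curves: Sequence[FRCurve], phi_max: int | None = None):
    """Long-format table of several curves plus an AUC ranking.

    Returns ``(points, ranking)`` DataFrames.  Curves with mismatched genome
    sizes trigger a warning (their coverages are not on a common scale).
    """
    if not curves:
        raise ValueError("no curves to compare")
    sizes = {c.genome_size for c in curves}
    if len(sizes) > 1:
        warnings.warn(f"curves have different genome sizes: {sorted(sizes)}")
    if phi_max is None:
        phi_max = int(max(c.phi[-1] for c in curves))
    points = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    ranking = pd.DataFrame(
        {
            "label": [c.label for c in curves],
            "auc": [frc_auc(c, phi_max) for c in curves],
        }
    ).sort_values("auc", ascending=False, ignore_index=True)
    return points, ranking


def plot_frc(curves: Sequence[FRCurve], path=None, ax=None):
    """Basic step plot of one or more FRCs (coverage vs phi)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.step(c.phi, c.coverage, where="post", label=c.label or None)
    ax.set_xlabel(r"feature threshold $\varphi$")
    ax.set_ylabel("approximate genome coverage")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
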
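"""Synthetic cohorts and toy assemblies with planted, recoverable structure.

Two generators make the whole stack testable without any external data:

``simulate_matrix``
    An assembly x feature cohort matrix X = A·S + ε with a small number of
    independent non-Gaussian factors.  Each factor drives a disjoint group
    of feature columns and is *dominated* by one nearly noise-free column
    of that group, so the ground truth of both dimensionality (for the
    Marčenko–Pastur retention rule) and per-factor dominant features (for
    the ICA selection rule) is known by construction.

``simulate_assembly``
    A toy assembly: contig lengths from a log-normal law, planted
    mis-assemblies per contig, each emitting a truth interval plus a burst
    of co-occurring diagnostic features at the same locus (mate-pair
    violations cluster where the layout is wrong), and a uniform sprinkle
    of background features.  The emitted feature records, contig table and
    truth intervals are mutually consistent and round-trip through the
    package's parsers.

All randomness flows from a single integer seed; contig structure and
error placement use separate derived streams so that two specs differing
only in ``error_rate`` share the same contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import inv, sqrtm

from .features import (
    ANALYSIS_COLUMNS,
    Assembly,
    Contig,
    FeatureKind,
    FeatureRecord,
    FeatureType,
)
from .validation import MisassemblyInterval, MisassemblyKind


# ---------------------------------------------------------------------------
# cohort matrices


@dataclass
class CohortTruth:
    loadings: pd.DataFrame            # feature x factor
    dominant_features: list[str]      # one per factor
    sources: np.ndarray               # factor x observation


@dataclass
class CohortSpec:
    """Planted low-rank cohort.

    The defaults emulate the scale of a realistic evaluation cohort:
    ~80 assemblies described by the 11 analysis feature types, driven by
    3 latent error factors.  Feature groups per factor hold one dominant
    column (loading 1.0, idiosyncratic noise SD ``dominant_noise_sd``)
    and members at ``member_loading`` with noise SD ``noise_sd``.
    Sources are drawn by stratified inverse-CDF sampling and empirically
    decorrelated, so each realized factor genuinely carries its family's
    non-Gaussian signature.  The raw low-rank field is mapped to
    non-negative counts through the chosen link.
    """

    n_assemblies: int = 80
    n_features: int = 11
    n_factors: int = 3
    factor_loadings: str | np.ndarray = "random"
    source_family: str = "laplace"    # laplace | exponential | uniform
    noise_sd: float = 0.5
    dominant_noise_sd: float = 0.05
    member_loading: float = 0.5
    count_link: str = "round_softplus"  # round_softplus | poisson | none
    count_loc: float = 300.0
    count_scale: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors > self.n_features:
            raise ValueError("n_factors must be <= n_features")
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if self.noise_sd <= 0 or self.dominant_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")


def _stratified_standard_source(rng: np.random.Generator, n: int, family: str) -> np.ndarray:
    """Unit-variance draws via inverse CDF at permuted stratum midpoints."""
    u = (np.arange(n) + 0.5) / n
    if family == "laplace":
        x = np.where(u < 0.5, np.log(2 * u), -np.log(2 * (1 - u))) / np.sqrt(2)
    elif family == "exponential":
        x = -np.log(1 - u) - 1.0  # centred, unit variance
    elif family == "uniform":
        x = (u - 0.5) * np.sqrt(12)
    else:
        raise ValueError(f"unknown source family {family!r}")
    return x[rng.permutation(n)]


def _feature_names(p: int) -> list[str]:
    if p == len(ANALYSIS_COLUMNS):
        return list(ANALYSIS_COLUMNS)
    return [f"F{i + 1:02d}" for i in range(p)]


def simulate_matrix(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a cohort matrix with planted factors; returns the matrix
    and the ground truth (loadings, dominant features, sources)."""
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_assemblies, spec.n_features, spec.n_factors
    names = _feature_names(p)

    noise_scale = np.full(p, spec.noise_sd)
    if isinstance(spec.factor_loadings, np.ndarray):
        A = np.asarray(spec.factor_loadings, dtype=float)
        if A.shape != (p, k):
            raise ValueError(f"factor_loadings must have shape {(p, k)}")
        dom_idx = [int(np.argmax(np.abs(A[:, j]))) for j in range(k)]
        for j, f in enumerate(dom_idx):
            noise_scale[f] = spec.dominant_noise_sd
    else:
        A = np.zeros((p, k))
        perm = rng.permutation(p)
        groups = np.array_split(perm, k) if k else []
        dom_idx = []
        for j, g in enumerate(groups):
            A[g, j] = spec.member_loading
            A[g[0], j] = 1.0
            noise_scale[g[0]] = spec.dominant_noise_sd
            dom_idx.append(int(g[0]))

    if k:
        S = np.vstack(
            [_stratified_standard_source(rng, n, spec.source_family) for _ in range(k)]
        )
        S = S - S.mean(axis=1, keepdims=True)
        S = np.real(inv(sqrtm(S @ S.T / n))) @ S   # exact empirical decorrelation
        signal = (A @ S).T
    else:
        S = np.empty((0, n))
        signal = np.zeros((n, p))

    X = signal + rng.normal(0.0, 1.0, (n, p)) * noise_scale

    if spec.count_link == "round_softplus":
        z = spec.count_loc + spec.count_scale * X
        X = np.round(np.logaddexp(0.0, z))
    elif spec.count_link == "poisson":
        lam = np.logaddexp(0.0, spec.count_loc + spec.count_scale * X)
        X = rng.poisson(lam).astype(float)
    elif spec.count_link != "none":
        raise ValueError(f"unknown count link {spec.count_link!r}")

    matrix = pd.DataFrame(
        X,
        index=pd.Index([f"asm{i + 1:03d}" for i in range(n)], name="assembly"),
        columns=names,
    )
    truth = CohortTruth(
        loadings=pd.DataFrame(A, index=names, columns=[f"factor{j + 1}" for j in range(k)]),
        dominant_features=[names[f] for f in dom_idx],
        sources=S,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# toy assemblies


@dataclass
class ToyAssemblySpec:
    """Planted-error toy assembly.

    ``error_rate`` is the per-contig probability of a planted
    mis-assembly.  Each error emits one truth interval and a burst of
    1 + Poisson(``features_per_error``-1) co-located diagnostic features
    of mixed types; background features arrive at
    ``background_feature_rate`` per kb, uniformly over each contig.
    """

    label: str = "toy"
    n_contigs: int = 30
    length_log_mu: float = float(np.log(30_000))
    length_log_sigma: float = 0.7
    genome_size: int | None = None     # default: 1.25 x total contig length
    error_rate: float = 0.1
    features_per_error: float = 3.0
    background_feature_rate: float = 0.02   # per kb
    error_interval_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.background_feature_rate < 0:
            raise ValueError("background_feature_rate must be >= 0")
        if self.n_contigs < 1:
            raise ValueError("need at least one contig")


_ERROR_KINDS = (
    MisassemblyKind.RELOCATION,
    MisassemblyKind.INVERSION,
    MisassemblyKind.INDEL,
    MisassemblyKind.OTHER,
)


def _emit_feature(
    rng: np.random.Generator, contig: Contig, center: int, note: str
) -> FeatureRecord:
    ftype = FeatureType(list(FeatureType)[rng.integers(len(FeatureType))])
    if ftype.extent_kind is FeatureKind.POINT:
        start = int(np.clip(center, 0, contig.length - 1))
        return FeatureRecord(contig.id, ftype, start, start + 1, note)
    span = int(rng.integers(200, 2000))
    start = int(np.clip(center - span // 2, 0, max(0, contig.length - span - 1)))
    end = min(contig.length, start + span)
    return FeatureRecord(contig.id, ftype, start, max(end, start + 1), note)


def simulate_assembly(
    spec: ToyAssemblySpec,
) -> tuple[Assembly, list[FeatureRecord], list[MisassemblyInterval]]:
    """Generate (assembly, feature records, truth intervals).

    Contig structure and error placement draw from separate seed-derived
    streams, so varying ``error_rate`` alone leaves the contigs unchanged.
    """
    rng_ctg = np.random.default_rng([spec.seed, 11])
    rng_err = np.random.default_rng([spec.seed, 13])

    lengths = np.maximum(
        1000,
        rng_ctg.lognormal(spec.length_log_mu, spec.length_log_sigma, spec.n_contigs)
        .astype(int),
    )
    contigs = [Contig(f"ctg{i + 1:04d}", int(L)) for i, L in enumerate(lengths)]

    features: list[FeatureRecord] = []
    truth: list[MisassemblyInterval] = []
    for contig in contigs:
        # planted errors
        if rng_err.random() < spec.error_rate:
            margin = min(2000, contig.length // 4)
            lo = margin
            hi = max(lo + 1, contig.length - margin - spec.error_interval_length)
            pos = int(rng_err.integers(lo, hi))
            iv_end = min(contig.length, pos + spec.error_interval_length)
            kind = _ERROR_KINDS[rng_err.integers(len(_ERROR_KINDS))]
            truth.append(MisassemblyInterval(contig.id, pos, max(iv_end, pos + 1), kind))
            n_feat = 1 + rng_err.poisson(max(0.0, spec.features_per_error - 1))
            center = pos + spec.error_interval_length // 2
            for _ in range(n_feat):
                jitter = int(rng_err.integers(-200, 201))
                features.append(
                    _emit_feature(rng_err, contig, center + jitter, "planted")
                )
        # background
        n_bg = rng_err.poisson(spec.background_feature_rate * contig.length / 1000)
        for _ in range(n_bg):
            center = int(rng_err.integers(0, contig.length))
            features.append(_emit_feature(rng_err, contig, center, "background"))

    total = int(lengths.sum())
    genome_size = spec.genome_size or int(np.ceil(total * 1.25))
    assembly = Assembly(
        label=spec.label, contigs=contigs, features=features, genome_size=genome_size
    )
    return assembly, features, truth


# ---------------------------------------------------------------------------
# text-file emitters (round-trip through the parsers)


def write_feature_file(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("# contig_id\ttype\tstart\tend\tnote\n")
        for rec in features:
            fh.write(
                f"{rec.contig_id}\t{rec.ftype.name}\t{rec.start}\t{rec.end}\t{rec.note}\n"
            )


def write_contig_tsv(contigs, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f"{c.id}\t{c.length}\n")


def write_assembly_dir(
    assembly: Assembly,
    truth: list[MisassemblyInterval],
    outdir,
) -> dict[str, Path]:
    """Write feature TSV, contig TSV and truth BED for one toy assembly."""
    from .validation import write_intervals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / f"{assembly.label}.feat",
        "contigs": outdir / f"{assembly.label}.contigs.tsv",
        "truth": outdir / f"{assembly.label}.truth.bed",
    }
    write_feature_file(assembly.features, paths["features"])
    write_contig_tsv(assembly.contigs, paths["contigs"])
    write_intervals(truth, paths["truth"])
    return paths
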
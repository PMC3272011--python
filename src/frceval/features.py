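"""Mis-assembly feature taxonomy, file parsing, counting rules and the
assembly x feature matrix.

An assembly validation pipeline of the amosvalidate family inspects the
read layout of each contig and emits localized diagnostic *features*:
mate-pair violations, coverage anomalies, k-mer frequency anomalies,
clustered SNPs and leftover-read breakpoints.  Each feature is placed on a
contig interval.  This module defines the twelve-type feature taxonomy,
reads feature files and contig sets, applies the point/extent counting
rules, computes contig-size statistics (N50/NG50) and assembles a cohort
of assemblies into the observation x feature matrix consumed by the
multivariate analyses.

Coordinates are 0-based half-open throughout; point features are stored as
width-1 intervals.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd


class FeatureKind(Enum):
    POINT = "point"
    EXTENT = "extent"


class FeatureType(Enum):
    """The twelve diagnostic feature types reported per contig.

    ``BREAKPOINT`` (partial alignments of leftover reads) and ``HIGH_SNP``
    (high-coverage SNP clusters) are point-like signals; all other types
    describe an extended region of the contig.
    """

    BREAKPOINT = "BREAKPOINT"
    COMPRESSION = "COMPRESSION"
    STRETCH = "STRETCH"
    LOW_GOOD_CVG = "LOW_GOOD_CVG"
    HIGH_NORMAL_CVG = "HIGH_NORMAL_CVG"
    HIGH_LINKING_CVG = "HIGH_LINKING_CVG"
    HIGH_SPANNING_CVG = "HIGH_SPANNING_CVG"
    HIGH_OUTIE_CVG = "HIGH_OUTIE_CVG"
    HIGH_SINGLEMATE_CVG = "HIGH_SINGLEMATE_CVG"
    HIGH_READ_COVERAGE = "HIGH_READ_COVERAGE"
    HIGH_SNP = "HIGH_SNP"
    KMER_COV = "KMER_COV"

    @property
    def extent_kind(self) -> FeatureKind:
        if self in _POINT_TYPES:
            return FeatureKind.POINT
        return FeatureKind.EXTENT


_POINT_TYPES = frozenset({FeatureType.BREAKPOINT, FeatureType.HIGH_SNP})

#: Raw column order: the twelve feature types as declared.
RAW_COLUMNS: tuple[str, ...] = tuple(t.name for t in FeatureType)

#: Analysis columns: HIGH_LINKING_CVG is folded into HIGH_SPANNING_CVG
#: (mates in another scaffold vs another contig flag the same kind of
#: inter-sequence inconsistency), leaving eleven columns.  Alphabetical
#: order, the order used in loading tables.
ANALYSIS_COLUMNS: tuple[str, ...] = (
    "BREAKPOINT",
    "COMPRESSION",
    "STRETCH",
    "HIGH_NORMAL_CVG",
    "HIGH_OUTIE_CVG",
    "HIGH_READ_COVERAGE",
    "HIGH_SINGLEMATE_CVG",
    "HIGH_SNP",
    "HIGH_SPANNING_CVG",
    "KMER_COV",
    "LOW_GOOD_CVG",
)

#: Contig-scale metric columns appended to the analysis matrix on request.
METRIC_COLUMNS: tuple[str, ...] = ("N50", "NUM_CONTIG")


def analysis_column(ftype: FeatureType, collapse: bool = True) -> str:
    """Map a feature type to its analysis column name."""
    if collapse and ftype is FeatureType.HIGH_LINKING_CVG:
        return FeatureType.HIGH_SPANNING_CVG.name
    return ftype.name


@dataclass
class FeatureRecord:
    """One diagnostic feature placed on a contig interval (0-based, half-open)."""

    contig_id: str
    ftype: FeatureType
    start: int
    end: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.contig_id}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Contig:
    id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r} has non-positive length {self.length}")


@dataclass
class Assembly:
    """One observation: a contig set, its feature records and an optional
    genome-size estimate."""

    label: str
    contigs: list[Contig]
    features: list[FeatureRecord] = field(default_factory=list)
    genome_size: int | None = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in assembly {self.label!r}")
        by_id = {c.id: c for c in self.contigs}
        for rec in self.features:
            ctg = by_id.get(rec.contig_id)
            if ctg is None:
                raise ValueError(
                    f"feature on unknown contig {rec.contig_id!r} in {self.label!r}"
                )
            if rec.end > ctg.length:
                raise ValueError(
                    f"feature [{rec.start},{rec.end}) exceeds contig "
                    f"{ctg.id!r} length {ctg.length}"
                )
        if self.genome_size is not None:
            longest = max((c.length for c in self.contigs), default=0)
            if self.genome_size < longest:
                raise ValueError("genome_size smaller than the longest contig")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def lengths(self) -> list[int]:
        return [c.length for c in self.contigs]

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class CountingConfig:
    """How feature records turn into counts.

    extent_window
        Window T in bp for extent features: a region of length L counts as
        max(1, ceil(L / T)) features, so long anomalies weigh proportionally
        to their footprint.  Default 10 kb.
    collapse_linking_spanning
        Fold HIGH_LINKING_CVG into HIGH_SPANNING_CVG (12 -> 11 analysis types).
    """

    extent_window: int = 10_000
    collapse_linking_spanning: bool = True

    def __post_init__(self) -> None:
        if self.extent_window < 1:
            raise ValueError("extent_window must be >= 1")

    @property
    def columns(self) -> tuple[str, ...]:
        return ANALYSIS_COLUMNS if self.collapse_linking_spanning else RAW_COLUMNS


@dataclass
class FeatureCountTable:
    """Per-contig feature counts: DataFrame (contig x type) plus totals."""

    counts: pd.DataFrame
    config: CountingConfig

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def type_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_totals(self, subset: Iterable[str]) -> pd.Series:
        cols = _check_subset(subset, self.counts.columns)
        return self.counts[cols].sum(axis=1)


def _check_subset(subset: Iterable[str], universe: Iterable[str]) -> list[str]:
    cols = [s.name if isinstance(s, FeatureType) else str(s) for s in subset]
    unknown = set(cols) - set(universe)
    if unknown:
        raise ValueError(f"unknown feature types in subset: {sorted(unknown)}")
    return cols


# ---------------------------------------------------------------------------
# parsing


def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, TextIO) or hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def parse_feature_file(source, strict: bool = False) -> list[FeatureRecord]:
    """Read a whitespace/TSV feature file: contig_id, type, start, end[, note].

    Lines starting with ``#`` are comments.  Point records given with
    start == end are widened to width-1 intervals.  Unknown feature tokens
    raise in strict mode and are skipped with a warning otherwise.
    """
    records: list[FeatureRecord] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"line {lineno}: expected >= 4 columns, got {len(parts)}")
        contig_id, token, s_raw, e_raw = parts[:4]
        note = " ".join(parts[4:])
        try:
            ftype = FeatureType[token.upper()]
        except KeyError:
            if strict:
                raise ValueError(f"line {lineno}: unknown feature type {token!r}")
            warnings.warn(f"line {lineno}: skipping unknown feature type {token!r}")
            continue
        start, end = int(s_raw), int(e_raw)
        if end < start:
            raise ValueError(f"line {lineno}: end {end} < start {start}")
        if end == start:
            end = start + 1
        records.append(FeatureRecord(contig_id, ftype, start, end, note))
    return records


def parse_contigs(source, format: str = "fasta") -> list[Contig]:
    """Read contigs from FASTA or a two-column ``id<TAB>length`` TSV."""
    contigs: list[Contig] = []
    if format == "fasta":
        from Bio import SeqIO

        if isinstance(source, (str, Path)):
            handle: TextIO = open(source)
        elif hasattr(source, "read"):
            handle = source
        else:
            handle = io.StringIO("".join(source))
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                contigs.append(Contig(rec.id, len(rec.seq)))
        finally:
            if isinstance(source, (str, Path)):
                handle.close()
    elif format == "tsv":
        for lineno, line in enumerate(_as_lines(source), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            contigs.append(Contig(parts[0], int(parts[1])))
    else:
        raise ValueError(f"unknown contig format {format!r}")
    ids = [c.id for c in contigs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate contig ids")
    return contigs


# ---------------------------------------------------------------------------
# counting


def count_feature(record: FeatureRecord, cfg: CountingConfig | None = None) -> int:
    """Count contribution of one record: points count once; an extent of
    length L counts max(1, ceil(L / extent_window)) times."""
    cfg = cfg or CountingConfig()
    if record.ftype.extent_kind is FeatureKind.POINT:
        return 1
    return max(1, math.ceil(record.length / cfg.extent_window))


def count_features(assembly: Assembly, cfg: CountingConfig | None = None) -> FeatureCountTable:
    """Tally features per contig and per analysis type."""
    cfg = cfg or CountingConfig()
    cols = cfg.columns
    index = [c.id for c in assembly.contigs]
    counts = pd.DataFrame(0, index=pd.Index(index, name="contig_id"), columns=list(cols))
    known = set(index)
    for rec in assembly.features:
        if rec.contig_id not in known:
            raise ValueError(f"feature on unknown contig {rec.contig_id!r}")
        col = analysis_column(rec.ftype, cfg.collapse_linking_spanning)
        counts.loc[rec.contig_id, col] += count_feature(rec, cfg)
    return FeatureCountTable(counts=counts, config=cfg)


def n50(lengths: Sequence[int], genome_size: int | None = None) -> int:
    """Smallest contig length L such that contigs of length >= L sum to at
    least half the denominator.

    The denominator is the assembly total by default (the conventional N50);
    passing ``genome_size`` yields NG50 instead.
    """
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    denom = genome_size if genome_size is not None else sum(lengths)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    half = denom / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise ValueError("contigs sum to less than half the genome size (no NG50)")


def build_matrix(
    assemblies: Sequence[Assembly],
    cfg: CountingConfig | None = None,
    include_n50: bool = True,
    include_num_contig: bool = True,
) -> pd.DataFrame:
    """Assemble the observation x feature matrix: one row per assembly, one
    column per analysis feature type, optionally + N50 and NUM_CONTIG."""
    if len(assemblies) < 2:
        raise ValueError("need at least 2 assemblies to build a cohort matrix")
    cfg = cfg or CountingConfig()
    labels = [a.label for a in assemblies]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate assembly labels")
    rows = []
    for asm in assemblies:
        table = count_features(asm, cfg)
        row = table.type_totals.astype(float)
        if include_n50:
            row["N50"] = float(n50(asm.lengths))
        if include_num_contig:
            row["NUM_CONTIG"] = float(len(asm.contigs))
        rows.append(row)
    matrix = pd.DataFrame(rows, index=pd.Index(labels, name="assembly"))
    return matrix


def write_matrix(matrix: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write the cohort matrix as CSV (first column = assembly label)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_csv(fh)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, comment="#")
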
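"""Scoring diagnostic features against true mis-assembly intervals.

When a reference genome is available, whole-genome alignment of the
contigs (dnadiff/nucmer style) yields the *real* mis-assemblies as
intervals on the contigs.  A diagnostic feature is "correct" if its
interval overlaps a true mis-assembly on the same contig.  Before
scoring, small differences (SNPs, short indels) are ignored and
breakpoints within a margin of the contig ends are disregarded, since
alignment ends are noisy there.

Overlap is half-open with >= 1 bp intersection: touching intervals do not
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .features import (
    Assembly,
    Contig,
    CountingConfig,
    FeatureRecord,
    _as_lines,
    _check_subset,
    analysis_column,
    count_feature,
)


class MisassemblyKind(Enum):
    BREAKPOINT = "breakpoint"
    RELOCATION = "relocation"
    INVERSION = "inversion"
    INDEL = "indel"
    SNP = "snp"
    OTHER = "other"


@dataclass(frozen=True)
class MisassemblyInterval:
    contig_id: str
    start: int
    end: int
    kind: MisassemblyKind = MisassemblyKind.OTHER

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ValidationSummary:
    """# Feat / # corr Feat bookkeeping, on the full space and a subset."""

    n_features: int
    n_correct: int
    n_features_subset: int | None = None
    n_correct_subset: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_features:
            raise ValueError("n_correct out of range")


def load_intervals(source) -> list[MisassemblyInterval]:
    """Read BED-like truth intervals: contig, start, end[, kind]."""
    out: list[MisassemblyInterval] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 columns")
        contig_id, s_raw, e_raw = parts[:3]
        kind = MisassemblyKind.OTHER
        if len(parts) >= 4:
            try:
                kind = MisassemblyKind(parts[3].lower())
            except ValueError:
                kind = MisassemblyKind.OTHER
        start, end = int(s_raw), int(e_raw)
        if start >= end:
            raise ValueError(f"line {lineno}: start {start} >= end {end}")
        out.append(MisassemblyInterval(contig_id, start, end, kind))
    return out


def write_intervals(intervals: Iterable[MisassemblyInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.kind.value}\n")


def filter_intervals(
    intervals: Sequence[MisassemblyInterval],
    contigs: Sequence[Contig],
    edge_margin: int = 1000,
    min_indel_length: int = 10,
) -> list[MisassemblyInterval]:
    """Drop small differences and edge breakpoints before scoring.

    SNP and indel intervals shorter than ``min_indel_length`` are removed;
    breakpoint intervals starting within ``edge_margin`` bp of either
    contig end are removed.
    """
    lengths = {c.id: c.length for c in contigs}
    kept: list[MisassemblyInterval] = []
    for iv in intervals:
        if iv.kind in (MisassemblyKind.SNP, MisassemblyKind.INDEL):
            if iv.length < min_indel_length:
                continue
        if iv.kind is MisassemblyKind.BREAKPOINT:
            clen = lengths.get(iv.contig_id)
            if clen is not None and (
                iv.start < edge_margin or iv.start >= clen - edge_margin
            ):
                continue
        kept.append(iv)
    return kept


def score_features(
    features: Sequence[FeatureRecord],
    cfg: CountingConfig | None,
    intervals: Sequence[MisassemblyInterval],
    subset: Iterable[str] | None = None,
) -> ValidationSummary:
    """Count features and features overlapping >= 1 true interval.

    Each record contributes its counting-rule weight (an extent feature
    spanning c windows adds c) to ``n_features`` and, if it overlaps a
    true interval on the same contig, the same weight to ``n_correct``.
    ``subset`` restricts the companion subset tallies to the given
    analysis feature types.
    """
    cfg = cfg or CountingConfig()
    subset_cols = None
    if subset is not None:
        universe = cfg.columns
        subset_cols = set(_check_subset(subset, universe))

    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.contig_id, IntervalTree()).addi(iv.start, iv.end)

    n_feat = n_corr = 0
    n_feat_sub = n_corr_sub = 0
    for rec in features:
        weight = count_feature(rec, cfg)
        tree = trees.get(rec.contig_id)
        hit = bool(tree is not None and tree.overlap(rec.start, rec.end))
        n_feat += weight
        if hit:
            n_corr += weight
        if subset_cols is not None:
            if analysis_column(rec.ftype, cfg.collapse_linking_spanning) in subset_cols:
                n_feat_sub += weight
                if hit:
                    n_corr_sub += weight
    if subset_cols is None:
        return ValidationSummary(n_feat, n_corr)
    return ValidationSummary(n_feat, n_corr, n_feat_sub, n_corr_sub)


def score_assembly(
    assembly: Assembly,
    intervals: Sequence[MisassemblyInterval],
    cfg: CountingConfig | None = None,
    subset: Iterable[str] | None = None,
    edge_margin: int = 1000,
    min_indel_length: int = 10,
) -> ValidationSummary:
    """Convenience wrapper: filter intervals against the assembly's contigs,
    then score its feature records."""
    filtered = filter_intervals(
        intervals, assembly.contigs, edge_margin=edge_margin,
        min_indel_length=min_indel_length,
    )
    return score_features(assembly.features, cfg, filtered, subset=subset)


def read_mcoords_breakpoints(source, min_gap: int = 0) -> list[MisassemblyInterval]:
    """Best-effort converter from dnadiff ``.mcoords``-style alignment rows
    to breakpoint intervals at internal alignment boundaries.

    Expects whitespace rows whose columns 3, 4 are the contig-coordinate
    start/end of an alignment block and whose last column is the contig
    id (the ``show-coords -rclTH`` layout).  A breakpoint interval of
    width 1 is emitted at every internal block boundary.
    """
    blocks: dict[str, list[tuple[int, int]]] = {}
    for line in _as_lines(source):
        parts = line.split()
        if len(parts) < 5:
            continue
        try:
            qs, qe = int(parts[2]), int(parts[3])
        except ValueError:
            continue
        qid = parts[-1]
        lo, hi = min(qs, qe), max(qs, qe)
        blocks.setdefault(qid, []).append((lo, hi))
    out: list[MisassemblyInterval] = []
    for qid, spans in blocks.items():
        spans.sort()
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            if start_b - end_a >= min_gap:
                pos = max(0, end_a)
                out.append(
                    MisassemblyInterval(qid, pos, pos + 1, MisassemblyKind.BREAKPOINT)
                )
    return out
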
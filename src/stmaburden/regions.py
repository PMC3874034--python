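"""Genomic intervals: CNV parsing, region merging and gene-overlap mapping.

Coordinates are 0-based half-open throughout (BED convention): an interval
covers bases ``start .. end-1``.  Two intervals overlap iff they share at
least one base; abutting intervals (``end == start``) do *not* overlap and
are not merged.

Overlapping CNVs within a dataset are merged into **maximal regions** (the
union of each overlap cluster — the potential maximally affected region).
**Minimal regions** are the sub-intervals of each cluster covered by at least
two member CNVs (the presumed dosage-critical core); a cluster with a single
member passes through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class RegionKind(str, Enum):
    MAXIMAL = "MAXIMAL"
    MINIMAL = "MINIMAL"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with an optional sample/dataset label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnvRegion:
    """A merged CNV region with its member count and (optionally) mapped genes."""

    chrom: str
    start: int
    end: int
    n_members: int
    kind: RegionKind = RegionKind.MAXIMAL
    genes: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """One genomic interval of a gene (a symbol may have several isoform intervals)."""

    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")


@dataclass(frozen=True)
class RegionStats:
    total_size_mb: float
    mean_size_mb: float | None  # None when there are no regions
    n_regions: int


# ---------------------------------------------------------------------------
# I/O

def read_cnv_bed(path: str | Path, label: str | None = None) -> list[GenomicInterval]:
    """Read a BED-like file (>= 3 whitespace/tab-separated columns) of CNVs.

    Column 4, when present, is kept as the sample label unless ``label``
    overrides it.  Malformed lines raise a validation error naming the line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates {s!r}/{e!r}") from err
            lab = label if label is not None else (fields[3] if len(fields) > 3 else "")
            try:
                intervals.append(GenomicInterval(chrom, start, end, lab))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    if not intervals:
        logger.warning("%s: no intervals read", path)
    return intervals


def write_regions_bed(regions: Sequence[CnvRegion], path: str | Path) -> None:
    """Write merged regions as BED4 (name = n_members) plus a genes column when mapped."""
    with Path(path).open("w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            genes = ",".join(sorted(r.genes)) if r.genes else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_members}\t{genes}\n")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotation as BED4 (chrom start end symbol) or TSV with those columns."""
    path = Path(path)
    genes: list[GeneAnnotation] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need chrom start end symbol")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
            genes.append(GeneAnnotation(fields[3], iv))
    return genes


# ---------------------------------------------------------------------------
# core interval operations

def filter_min_length(
    intervals: Iterable[GenomicInterval], min_length: int = 100_000
) -> list[GenomicInterval]:
    """Keep intervals strictly longer than ``min_length`` bp.

    Used to remove the very short calls that dominate control CNV datasets
    (>100 kb size selection); disease datasets pass unfiltered.
    """
    return [iv for iv in intervals if iv.length > min_length]


def _clusters(intervals: Sequence[GenomicInterval]):
    """Yield (chrom, cluster_members) for each connected overlap cluster.

    Sweep-line over intervals sorted by (chrom, start): a new interval joins
    the open cluster iff it starts strictly before the cluster's current end
    (abutting intervals start a new cluster).
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    cluster: list[GenomicInterval] = []
    cur_chrom, cur_end = None, -1
    for iv in by_pos:
        if cluster and iv.chrom == cur_chrom and iv.start < cur_end:
            cluster.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            if cluster:
                yield cur_chrom, cluster
            cluster = [iv]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cluster:
        yield cur_chrom, cluster


def merge_maximal(intervals: Iterable[GenomicInterval]) -> list[CnvRegion]:
    """Merge overlapping CNVs into disjoint maximal regions.

    Every input interval is contained in exactly one output region; the union
    of output spans equals the union of input spans.  Output order is by
    (chrom, start) and independent of input order.
    """
    regions = []
    for chrom, members in _clusters(list(intervals)):
        regions.append(
            CnvRegion(
                chrom=chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                n_members=len(members),
                kind=RegionKind.MAXIMAL,
            )
        )
    return regions


def minimal_overlap_regions(intervals: Iterable[GenomicInterval]) -> list[CnvRegion]:
    """Minimal / critical overlap regions: sub-intervals covered by >= 2 CNVs.

    Within each overlap cluster, coverage is counted per base (via boundary
    events) and the maximal runs with coverage >= 2 are emitted; adjacent
    qualifying runs are contiguous by construction.  A cluster with a single
    member emits its interval unchanged.  ``n_members`` counts the cluster
    members overlapping the emitted sub-interval.
    """
    out: list[CnvRegion] = []
    for chrom, members in _clusters(list(intervals)):
        if len(members) == 1:
            m = members[0]
            out.append(CnvRegion(chrom, m.start, m.end, 1, RegionKind.MINIMAL))
            continue
        events = sorted(
            [(m.start, +1) for m in members] + [(m.end, -1) for m in members]
        )
        cov = 0
        run_start = None
        runs: list[tuple[int, int]] = []
        for pos, delta in events:
            prev = cov
            cov += delta
            if prev < 2 <= cov:
                run_start = pos
            elif prev >= 2 > cov:
                if pos > run_start:
                    runs.append((run_start, pos))
                run_start = None
        # merge touching runs (coverage dipped to 1 exactly at a shared boundary
        # cannot happen with half-open arithmetic, but keep the contract explicit)
        merged: list[tuple[int, int]] = []
        for s, e in runs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            n = sum(1 for m in members if m.start < e and m.end > s)
            out.append(CnvRegion(chrom, s, e, n, RegionKind.MINIMAL))
    return out


def map_genes(
    regions: Sequence[CnvRegion], annotation: Sequence[GeneAnnotation]
) -> list[CnvRegion]:
    """Attach gene symbols to regions by >= 1 bp interval overlap (in place).

    Regions must be disjoint per chromosome (the post-merge contract), which
    allows a sorted binary-search join.  A symbol with several isoform
    intervals is attached once per region it touches; a gene spanning two
    regions is attached to both.
    """
    if not annotation:
        logger.warning("empty gene annotation: regions get empty gene sets")
    for r in regions:
        r.genes = set()
    by_chrom: dict[str, list[CnvRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    ann_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        ann_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        starts = np.fromiter((r.start for r in rs), dtype=np.int64, count=len(rs))
        ends = np.fromiter((r.end for r in rs), dtype=np.int64, count=len(rs))
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"regions on {chrom} are not disjoint; merge first")
        genes = ann_by_chrom.get(chrom, [])
        if not genes:
            continue
        gs = np.fromiter((g.interval.start for g in genes), dtype=np.int64, count=len(genes))
        ge = np.fromiter((g.interval.end for g in genes), dtype=np.int64, count=len(genes))
        # regions overlapping [gs, ge): those with end > gs and start < ge
        lo = np.searchsorted(ends, gs, side="right")
        hi = np.searchsorted(starts, ge, side="left")
        for g, l, h in zip(genes, lo, hi):
            for r in rs[l:h]:
                r.genes.add(g.symbol)
    return list(regions)


def dataset_gene_set(regions: Iterable[CnvRegion]) -> set[str]:
    """Union of mapped genes over regions (a symbol in two regions counts once)."""
    out: set[str] = set()
    for r in regions:
        out |= r.genes
    return out


def region_stats(regions: Sequence[CnvRegion]) -> RegionStats:
    """Total and mean region size in Mb; mean is undefined (None) with no regions."""
    n = len(regions)
    total = sum(r.length for r in regions) / 1e6
    return RegionStats(total, (total / n) if n else None, n)
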
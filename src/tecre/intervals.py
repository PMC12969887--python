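"""Genomic interval model and the overlap / closest-distance primitives.

All coordinates are 0-based half-open throughout the package; readers convert
1-based conventions (GTF, RepeatMasker .out) on input and writers convert
back. Abutting features (``end == start``) are assigned distance 0 — a
deliberate, documented deviation from some bedtools builds that report 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TEInstance:
    """One genomic copy of a repeat family; the counting unit of enrichment."""

    interval: GenomicInterval
    family: str
    id: str
    divergence: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.divergence is not None and self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass(frozen=True)
class Peak:
    """A called peak from one ChIP/ATAC dataset (peak calling is upstream)."""

    interval: GenomicInterval
    signal: float = 0.0
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_end: Optional[int] = None
    polya_site: Optional[int] = None

    def __post_init__(self) -> None:
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = ex

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    def terminal_exon(self, strand: str) -> GenomicInterval:
        """3'-most exon in the transcript's reading direction."""
        return self.exons[-1] if strand != "-" else self.exons[0]


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        return self.span.start if self.strand != "-" else self.span.end

    @property
    def end3(self) -> int:
        """Strand-aware 3' terminus (max coordinate on +, min on -)."""
        return self.span.end if self.strand != "-" else self.span.start


def as_interval(x) -> GenomicInterval:
    """Accept a GenomicInterval or any record carrying one in ``.interval``."""
    return x if isinstance(x, GenomicInterval) else x.interval


def overlap_join(
    a: Sequence,
    b: Sequence,
    min_fraction_of_a: float = 0.0,
) -> list[tuple[int, int, int]]:
    """All pairs (a_index, b_index, overlap_bp) with >= 1 bp overlap.

    A pair is reported iff ``overlap_bp / len(a)`` reaches
    ``min_fraction_of_a``; 0 reproduces bedtools any-overlap mode. The
    fraction is measured against the *first* argument (conventionally the
    peak), matching a "70% of the peak must be inside the repeat" reading;
    swap the arguments for fraction-of-TE.
    """
    if not 0.0 <= min_fraction_of_a <= 1.0:
        raise ValueError("min_fraction_of_a must lie in [0, 1]")
    trees: dict[str, IntervalTree] = {}
    for j, rec in enumerate(b):
        iv = as_interval(rec)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    out: list[tuple[int, int, int]] = []
    for i, rec in enumerate(a):
        iv = as_interval(rec)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = []
        for hit in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if ov >= 1 and ov / len(iv) >= min_fraction_of_a:
                hits.append((hit.data, ov))
        out.extend((i, j, ov) for j, ov in sorted(hits))
    return out


def closest_distance(
    query: Sequence,
    targets: Iterable[tuple[str, str, int]],
) -> list[tuple[int, str, int]]:
    """Distance from each query interval to its nearest anchor point.

    ``targets`` are (target_id, chrom, position) anchor points, e.g. gene 3'
    ends. Distance is 0 when the anchor lies within or abuts the half-open
    interval; ties go to the smaller target coordinate, then lexicographic
    target_id. Queries on chromosomes with no anchor are skipped with a
    logged warning. Raises if the target set is empty.
    """
    tgt = list(targets)
    if not tgt:
        raise ValueError("closest_distance requires a non-empty target set")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for tid, chrom, pos in tgt:
        by_chrom.setdefault(chrom, []).append((pos, tid))
    for lst in by_chrom.values():
        lst.sort()
    out: list[tuple[int, str, int]] = []
    for i, rec in enumerate(query):
        iv = as_interval(rec)
        anchors = by_chrom.get(iv.chrom)
        if anchors is None:
            logger.warning("no anchor on chromosome %s; query %d skipped", iv.chrom, i)
            continue
        best: Optional[tuple[int, int, str]] = None  # (distance, pos, id)
        for pos, tid in anchors:
            if iv.start <= pos <= iv.end:
                d = 0
            elif pos < iv.start:
                d = iv.start - pos
            else:
                d = pos - iv.end
            key = (d, pos, tid)
            if best is None or key < best:
                best = key
        assert best is not None
        out.append((i, best[2], best[0]))
    return out
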
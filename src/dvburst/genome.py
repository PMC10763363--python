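"""Genomic coordinate primitives: intervals, TADs, gene models, overlap.

Coordinates are 0-based half-open throughout (BED convention).  The TSS of
a minus-strand gene is the *end* coordinate of its annotation, and all
windows are strand-aware.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.name!r}: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.name!r}: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.name!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test; touching intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TadDomain:
    interval: GenomicInterval
    id: str


def validate_tads(tads: list[TadDomain]) -> list[TadDomain]:
    """Check that TADs on the same chromosome do not overlap.

    Overlapping domains would make enhancer-gene pairing ambiguous, so a
    violation is an error, not a warning.
    """
    by_chrom: dict[str, list[TadDomain]] = {}
    for tad in tads:
        by_chrom.setdefault(tad.interval.chrom, []).append(tad)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda t: t.interval.start)
        for prev, cur in zip(group, group[1:]):
            if cur.interval.start < prev.interval.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: {prev.id} and {cur.id}"
                )
    return tads


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    cds: tuple[GenomicInterval, ...]

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS, strand and one or more CDS-defined transcripts."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    transcripts: tuple[Transcript, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for tx in self.transcripts:
            for iv in tx.cds:
                if iv.chrom != self.chrom:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS interval on {iv.chrom}, "
                        f"gene on {self.chrom}"
                    )
                if iv.strand != self.strand:
                    raise ValueError(
                        f"gene {self.gene_id}: CDS strand {iv.strand} differs "
                        f"from gene strand {self.strand}"
                    )


def interval_overlap(
    query: list[GenomicInterval], subject: list[GenomicInterval]
) -> list[tuple[str, str]]:
    """All (query.name, subject.name) pairs whose intervals overlap.

    Half-open semantics: [10, 20) and [20, 30) do not overlap.  Output is
    sorted by (query_name, subject_name).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for group in by_chrom.values():
        group.sort(key=lambda iv: iv.start)
    starts = {chrom: [iv.start for iv in group] for chrom, group in by_chrom.items()}

    pairs: list[tuple[str, str]] = []
    for q in query:
        group = by_chrom.get(q.chrom)
        if not group:
            continue
        # subjects with start < q.end are the only candidates
        hi = bisect_left(starts[q.chrom], q.end)
        for s in group[:hi]:
            if s.end > q.start:
                pairs.append((q.name, s.name))
    pairs.sort()
    return pairs


def tad_of_region(region: GenomicInterval, tads: list[TadDomain]) -> TadDomain | None:
    """TAD containing the region's midpoint (regions spanning a boundary are
    resolved by midpoint)."""
    mid = region.midpoint
    for tad in tads:
        if tad.interval.chrom == region.chrom and tad.interval.contains(mid):
            return tad
    return None


def tad_of_position(chrom: str, pos: int, tads: list[TadDomain]) -> TadDomain | None:
    for tad in tads:
        if tad.interval.chrom == chrom and tad.interval.contains(pos):
            return tad
    return None
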
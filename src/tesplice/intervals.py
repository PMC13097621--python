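"""Genomic interval primitives shared across the package.

All coordinates in this package are 0-based half-open ([start, end)),
the BED convention.  1-based inclusive formats (GFF3, RepeatMasker
``.out``, SAM POS) are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with an optional strand.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/contig) identifier.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, a 0-based point coordinate."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_one_based(self) -> tuple[str, int, int]:
        """Convert to 1-based inclusive (GFF-style) coordinates."""
        return self.chrom, self.start + 1, self.end

    @classmethod
    def from_one_based(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates."""
        return cls(chrom, start1 - 1, end1, strand)

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open integer intervals as a sorted, disjoint list."""
    pairs = sorted(p for p in pairs)
    merged: list[list[int]] = []
    for s, e in pairs:
        if e <= s:
            raise ValueError(f"degenerate interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_covered(pairs: Iterable[tuple[int, int]]) -> int:
    """Number of bases covered by the union of the given intervals."""
    return sum(e - s for s, e in merge_intervals(pairs))


def intersect_with_window(
    pairs: Iterable[tuple[int, int]], window: tuple[int, int]
) -> list[tuple[int, int]]:
    """Clip a set of intervals to a window, returning the merged pieces inside."""
    ws, we = window
    clipped = [
        (max(s, ws), min(e, we)) for s, e in pairs if max(s, ws) < min(e, we)
    ]
    return merge_intervals(clipped) if clipped else []


@dataclass
class TranscriptModel:
    """An ordered exon chain: one isoform, or one long-read transcript model.

    ``exons`` are (start, end) pairs in ascending genomic order regardless of
    strand; transcription order is derived from ``strand`` where needed.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: degenerate exon ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons at {s}"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcript 5' end (point)."""
        return self.start if self.strand != "-" else self.end - 1

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    def introns(self) -> list[tuple[int, int]]:
        """Introns in ascending genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def junctions(self) -> list[tuple[int, int]]:
        """Splice junctions as (donor-side boundary, acceptor-side boundary)
        pairs in ascending genomic order (same values as introns)."""
        return self.introns()


@dataclass
class Gene:
    """A gene: one or more isoforms sharing an id, chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged exons over all isoforms."""
        return merge_intervals(
            [(s, e) for t in self.transcripts for s, e in t.exons]
        )

    def reference_isoform(self) -> TranscriptModel:
        """Isoform used for intron ordinals: most exons, ties by id."""
        return min(self.transcripts, key=lambda t: (-len(t.exons), t.transcript_id))
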
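"""Cross-assembly quantities: occupancy, enrichment, synteny, coverage,
and junction-spanning presence calls for TE insertions."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .insertion_catalog import TEInsertion, filter_full_length
from .intervals import GenomicInterval, intersect_with_window, merge_intervals
from .io_formats import AlignedReadRecord, AlignmentBlock


@dataclass(frozen=True)
class OccupancyRecord:
    """Fraction of a genome covered by the merged copies of one family."""

    family: str
    covered_bases: int
    genome_len: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.genome_len


@dataclass(frozen=True)
class PresenceCall:
    """Verdict on whether an insertion predates a sequencing dataset."""

    insertion_id: str
    verdict: str  # "preexisting" | "novel"
    left_support: int
    right_support: int


def occupancy(
    intervals: Iterable[tuple[int, int]] | Iterable[GenomicInterval],
    genome_len: int,
    family: str = "",
) -> OccupancyRecord:
    """Merged (union) coverage of a family's copies over a genome."""
    if genome_len <= 0:
        raise ValueError("genome_len must be > 0")
    pairs = [
        (iv.start, iv.end) if isinstance(iv, GenomicInterval) else (iv[0], iv[1])
        for iv in intervals
    ]
    for s, e in pairs:
        if e > genome_len or s < 0:
            raise ValueError(f"interval ({s}, {e}) extends beyond genome of {genome_len}")
    merged = merge_intervals(pairs) if pairs else []
    covered = sum(e - s for s, e in merged)
    return OccupancyRecord(family, covered, genome_len)


def enrichment(
    family: str,
    assembly_a: tuple[Sequence[TEInsertion], int],
    assembly_b: tuple[Sequence[TEInsertion], int],
    mode: str = "occupancy",
    consensus_len: int | None = None,
    full_length_min_len: int | None = None,
    full_length_min_frac: float = 0.995,
) -> float:
    """Family enrichment of assembly A over baseline assembly B.

    ``occupancy`` mode takes the ratio of merged-coverage fractions;
    ``copy_number`` mode takes the ratio of full-length copy counts
    (full-length per :func:`filter_full_length`, default >= 99.5% of the
    consensus).  A zero baseline yields ``inf`` (or ``nan`` when the
    numerator is also zero), not an exception.
    """
    ins_a, len_a = assembly_a
    ins_b, len_b = assembly_b
    fam_a = [i for i in ins_a if i.family == family]
    fam_b = [i for i in ins_b if i.family == family]
    if mode == "occupancy":
        num = occupancy([i.interval for i in fam_a], len_a, family).fraction
        den = occupancy([i.interval for i in fam_b], len_b, family).fraction
    elif mode == "copy_number":
        kw = dict(
            consensus_len=consensus_len,
            min_len=full_length_min_len,
            min_frac=full_length_min_frac if consensus_len else None,
        )
        if kw["min_frac"] is None and kw["min_len"] is None:
            raise ValueError("copy_number mode needs consensus_len or full_length_min_len")
        num = float(len(filter_full_length(fam_a, **kw)))
        den = float(len(filter_full_length(fam_b, **kw)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def syntenic_fraction(
    region: GenomicInterval,
    blocks: Sequence[AlignmentBlock],
    coordinate_side: str = "target",
) -> tuple[float, float]:
    """(syntenic %, non-syntenic %) of a region covered by syntenic blocks.

    Blocks are filtered to the syntenic class (blocks without a class are
    kept), projected onto ``region``'s assembly via their query or target
    interval, unioned, and clipped to the region.
    """
    if region.length == 0:
        raise ValueError("empty region")
    if coordinate_side not in ("query", "target"):
        raise ValueError("coordinate_side must be 'query' or 'target'")
    pairs = []
    for b in blocks:
        if b.block_class not in (None, "syntenic"):
            continue
        iv = b.target if coordinate_side == "target" else b.query
        if iv.chrom != region.chrom:
            continue
        pairs.append((iv.start, iv.end))
    covered = intersect_with_window(pairs, (region.start, region.end))
    syn_bases = sum(e - s for s, e in covered)
    syn_pct = 100.0 * syn_bases / region.length
    return syn_pct, 100.0 - syn_pct


@dataclass
class RegionCoverageProfile:
    """Binned, normalised read depth over a region."""

    region: GenomicInterval
    bin_size: int
    values: np.ndarray  # per-bin mean depth, scaled

    @property
    def coefficient_of_variation(self) -> float:
        mean = float(self.values.mean())
        if mean == 0:
            return math.nan
        return float(self.values.std() / mean)


def region_coverage_profile(
    alignments: Iterable[AlignedReadRecord],
    region: GenomicInterval,
    bin_size: int = 1000,
    normalizer: float | None = None,
    total_reads: int | None = None,
) -> RegionCoverageProfile:
    """Per-bin mean depth over a region, reads-per-million scaled.

    ``normalizer`` multiplies the raw depth directly; when absent it
    defaults to 1e6 / ``total_reads`` (or 1.0 if that is unknown).
    The uniformity summary is the coefficient of variation across bins.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    depth = np.zeros(region.length, dtype=float)
    n_reads = 0
    for aln in alignments:
        n_reads += 1
        if aln.reference != region.chrom:
            continue
        s = max(aln.start, region.start) - region.start
        e = min(aln.end, region.end) - region.start
        if e > s:
            depth[s:e] += 1.0
    if normalizer is None:
        denom = total_reads if total_reads is not None else n_reads
        normalizer = 1e6 / denom if denom else 1.0
    n_bins = math.ceil(region.length / bin_size)
    values = np.array(
        [
            depth[i * bin_size : min((i + 1) * bin_size, region.length)].mean()
            for i in range(n_bins)
        ]
    )
    return RegionCoverageProfile(region, bin_size, values * normalizer)


def junction_support(
    insertion: TEInsertion,
    alignments: Iterable[AlignedReadRecord],
    min_overhang: int = 10,
    min_support: int = 1,
) -> PresenceCall:
    """Call an insertion preexisting when reads span both TE junctions.

    A read supports a junction at position p iff its aligned interval
    covers [p - min_overhang, p + min_overhang) entirely, i.e. it anchors
    ``min_overhang`` bases on each side.  The verdict is ``preexisting``
    when both junctions reach ``min_support``, else ``novel``.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    iv = insertion.interval
    left, right = iv.start, iv.end
    left_n = right_n = 0
    for aln in alignments:
        if aln.reference != iv.chrom:
            continue
        if aln.start <= left - min_overhang and aln.end >= left + min_overhang:
            left_n += 1
        if aln.start <= right - min_overhang and aln.end >= right + min_overhang:
            right_n += 1
    verdict = "preexisting" if (left_n >= min_support and right_n >= min_support) else "novel"
    return PresenceCall(insertion.insertion_id, verdict, left_n, right_n)
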
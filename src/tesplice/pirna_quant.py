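"""Strand-resolved small-RNA quantification on TE consensus sequences.

piRNAs that match the TE mRNA strand ("sense") cannot base-pair with it
and are useless for silencing, so the sense fraction per family is the
operative readout.  Reads are size-filtered to the piRNA window
(20-35 nt), counted once per read by alignment orientation, and
normalised to counts per million mapped reads (CPM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignedReadRecord

logger = logging.getLogger(__name__)


@dataclass
class FeatureCounts:
    sense: int = 0
    antisense: int = 0
    sense_cpm: float | None = None
    antisense_cpm: float | None = None

    @property
    def total(self) -> int:
        return self.sense + self.antisense

    @property
    def sense_fraction(self) -> float | None:
        """Sense share in percent; None when the feature has no reads."""
        if self.total == 0:
            return None
        return 100.0 * self.sense / self.total


@dataclass
class StrandedCountTable:
    """Per-feature sense/antisense counts plus the normalisation library size."""

    counts: dict[str, FeatureCounts] = field(default_factory=dict)
    library_size: int | None = None
    skipped_unknown: int = 0

    def feature(self, name: str) -> FeatureCounts:
        return self.counts.setdefault(name, FeatureCounts())

    def total_counted(self) -> int:
        return sum(c.total for c in self.counts.values())


@dataclass
class ConsensusCoverage:
    """Per-position sense/antisense coverage on one consensus, in CPM."""

    feature: str
    sense: np.ndarray
    antisense: np.ndarray

    def __post_init__(self) -> None:
        if self.sense.shape != self.antisense.shape:
            raise ValueError("sense/antisense arrays must match in length")

    @property
    def consensus_len(self) -> int:
        return int(self.sense.size)


def size_filter(
    reads: Iterable[AlignedReadRecord], min_len: int = 20, max_len: int = 35
) -> list[AlignedReadRecord]:
    """Keep reads whose length is within [min_len, max_len], inclusive."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in reads if min_len <= r.read_length <= max_len]


def count_by_feature_strand(
    alignments: Iterable[AlignedReadRecord],
    features: Sequence[str],
) -> StrandedCountTable:
    """Count sense (forward flag) and antisense (reverse flag) reads per feature.

    Each read counts once — multi-mapping is assumed collapsed to a single
    alignment upstream.  Alignments to references outside ``features``
    are skipped with a logged warning.
    """
    table = StrandedCountTable()
    known = set(features)
    for name in features:
        table.feature(name)
    for aln in alignments:
        if aln.reference not in known:
            table.skipped_unknown += 1
            continue
        fc = table.feature(aln.reference)
        if aln.is_reverse:
            fc.antisense += 1
        else:
            fc.sense += 1
    if table.skipped_unknown:
        logger.warning(
            "skipped %d alignments to references outside the feature set",
            table.skipped_unknown,
        )
    return table


def cpm_normalize(table: StrandedCountTable, denominator: int) -> StrandedCountTable:
    """Attach CPM values: 1e6 * count / denominator (library size)."""
    if denominator <= 0:
        raise ValueError("CPM denominator must be > 0")
    table.library_size = denominator
    for fc in table.counts.values():
        fc.sense_cpm = 1e6 * fc.sense / denominator
        fc.antisense_cpm = 1e6 * fc.antisense / denominator
    return table


def top_k_by_total(table: StrandedCountTable, k: int = 30) -> list[str]:
    """Features ranked by total (sense + antisense) reads; ties by name."""
    if k <= 0:
        raise ValueError("k must be > 0")
    ranked = sorted(table.counts, key=lambda f: (-table.counts[f].total, f))
    return ranked[:k]


def sense_bias_ranking(
    table_a: StrandedCountTable, table_b: StrandedCountTable
) -> "pd.DataFrame":
    """Per-feature sense percentages in two libraries and their difference.

    Features absent (or unread) in one table get an undefined (NaN)
    fraction there; delta = sense%A - sense%B.
    """
    import pandas as pd

    names = sorted(set(table_a.counts) | set(table_b.counts))
    rows = []
    for name in names:
        fa = table_a.counts.get(name)
        fb = table_b.counts.get(name)
        pa = fa.sense_fraction if fa else None
        pb = fb.sense_fraction if fb else None
        rows.append(
            {
                "feature": name,
                "sense_pct_a": math.nan if pa is None else pa,
                "sense_pct_b": math.nan if pb is None else pb,
                "delta": math.nan if pa is None or pb is None else pa - pb,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "sense_pct_a", "sense_pct_b", "delta"])


def per_position_coverage(
    alignments: Iterable[AlignedReadRecord],
    feature: str,
    consensus_len: int,
    denominator: int,
) -> ConsensusCoverage:
    """Per-position strand-split coverage on a consensus, scaled to CPM.

    Every aligned base increments its position on the matching strand;
    alignments running past the consensus end are clipped (and logged).
    """
    if denominator <= 0:
        raise ValueError("CPM denominator must be > 0")
    sense = np.zeros(consensus_len, dtype=float)
    antisense = np.zeros(consensus_len, dtype=float)
    clipped = 0
    for aln in alignments:
        if aln.reference != feature:
            continue
        s = max(0, aln.start)
        e = min(consensus_len, aln.end)
        if aln.end > consensus_len:
            clipped += 1
        if e <= s:
            continue
        (antisense if aln.is_reverse else sense)[s:e] += 1.0
    if clipped:
        logger.warning("clipped %d alignments extending past the consensus end", clipped)
    scale = 1e6 / denominator
    return ConsensusCoverage(feature, sense * scale, antisense * scale)


def table_to_dataframe(table: StrandedCountTable) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for name in sorted(table.counts):
        fc = table.counts[name]
        rows.append(
            {
                "feature": name,
                "sense": fc.sense,
                "antisense": fc.antisense,
                "total": fc.total,
                "sense_pct": math.nan if fc.sense_fraction is None else fc.sense_fraction,
                "sense_cpm": math.nan if fc.sense_cpm is None else fc.sense_cpm,
                "antisense_cpm": math.nan if fc.antisense_cpm is None else fc.antisense_cpm,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature", "sense", "antisense", "total", "sense_pct", "sense_cpm", "antisense_cpm"],
    )


def coverage_to_bedgraph_tracks(cov: ConsensusCoverage):
    """Two CoverageTrack objects (sense, antisense) for bedGraph export."""
    from .io_formats import CoverageTrack

    def runs(arr: np.ndarray) -> "CoverageTrack":
        track = CoverageTrack()
        i = 0
        n = arr.size
        while i < n:
            j = i
            while j + 1 < n and arr[j + 1] == arr[i]:
                j += 1
            if arr[i] != 0:
                track.add(cov.feature, i, j + 1, float(arr[i]))
            i = j + 1
        return track

    return runs(cov.sense), runs(cov.antisense)
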
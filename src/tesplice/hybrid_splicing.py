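"""Host-TE hybrid-splice detection from long-read transcript models.

An LTR retrotransposon sitting forward-oriented in an intron can start
transcription from its 5' LTR and splice from an internal GT-type donor
(GTAAGTG in the Springer family, 43 nt past the LTR) straight into a
downstream host exon, producing a TE-initiated host isoform that omits
the upstream host exons.  The caller below recognises such events in
genome-anchored exon chains: the transcript must start inside the TE,
its first junction must leave the TE from an internal donor, and the
junction must land on the 5' boundary of an annotated host exon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .insertion_catalog import ContextCall, TEInsertion
from .intervals import Gene, TranscriptModel
from .stats_core import mann_whitney_u, median

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class DonorSite:
    """A GT-type splice donor on a TE consensus sequence."""

    position: int  # 0-based offset of the G of GT on the consensus
    heptamer: str
    offset: int  # nt downstream of the 5' LTR end

    def __post_init__(self) -> None:
        if not self.heptamer.startswith("GT"):
            raise ValueError("donor heptamer must start with GT")
        if self.offset < 0:
            raise ValueError("donor offset must be >= 0")


@dataclass(frozen=True)
class HybridSpliceEvent:
    """One TE-initiated transcript splicing into a host exon."""

    insertion_id: str
    transcript_id: str
    donor_genomic: int  # first intronic base after the TE-derived exon
    donor_offset_on_te: int  # donor offset from the TE 5' end, TE orientation
    acceptor_exon_ordinal: int  # 1-based, transcription order
    skipped_exons: frozenset[int]
    te_segment_length: int  # length of the TE-derived leading exon

    def __post_init__(self) -> None:
        if self.te_segment_length < 1:
            raise ValueError("TE-derived segment must be >= 1 nt")
        if self.acceptor_exon_ordinal < 1:
            raise ValueError("acceptor exon ordinal is 1-based")


def find_donor_motifs(
    te_sequence: str,
    ltr_end: int,
    pattern: str = "GTAAGT",
) -> list[DonorSite]:
    """Scan a TE consensus for GT-type donor motifs downstream of the LTR.

    All forward-strand matches at or past ``ltr_end`` are reported with
    offsets relative to ``ltr_end``, sorted ascending.  The pattern is an
    IUPAC string and must start with GT (donors are GT-type here); the
    recorded heptamer is the 7-mer starting at the match.
    """
    if not pattern.upper().startswith("GT"):
        raise ValueError(f"donor pattern must start with GT, got {pattern!r}")
    seq = te_sequence.upper()
    if not 0 <= ltr_end <= len(seq):
        raise ValueError("ltr_end outside sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide symbols {sorted(bad)}")
    regex = re.compile("".join(_IUPAC[c] for c in pattern.upper()))
    sites = []
    pos = ltr_end
    while True:
        m = regex.search(seq, pos)
        if m is None:
            break
        p = m.start()
        hept = seq[p : p + 7]
        if len(hept) == 7 and hept.startswith("GT"):
            sites.append(DonorSite(position=p, heptamer=hept, offset=p - ltr_end))
        pos = p + 1
    return sites


def _first_junction(tx: TranscriptModel) -> tuple[int, int] | None:
    """(donor base position, acceptor boundary) of the first junction in
    transcription order, or None for single-exon transcripts.

    For ``+`` transcripts the donor base is the first intronic base after
    exon 1 and the acceptor boundary is the genomic start of exon 2; for
    ``-`` transcripts both are mirrored.
    """
    if len(tx.exons) < 2:
        return None
    if tx.strand != "-":
        return tx.exons[0][1], tx.exons[1][0]
    return tx.exons[-1][0] - 1, tx.exons[-2][1]


def call_hybrid_events(
    insertions: Sequence[TEInsertion],
    calls: Sequence[ContextCall],
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[Gene],
    acceptor_tolerance: int = 5,
    require_start_in_te: bool = True,
    min_support: int = 1,
) -> tuple[list[HybridSpliceEvent], dict[str, bool]]:
    """Call hybrid-splice events for forward intronic insertions.

    An event is emitted when (a) a transcript's 5' end lies within the
    insertion interval (or, relaxed, its first exon overlaps it), (b) the
    first splice junction donates from inside the insertion and accepts
    at the 5' boundary of an annotated host-gene exon within
    ``acceptor_tolerance`` nt, and (c) the transcript runs in the host
    gene's direction.  Returns the events plus a per-insertion verdict
    (True when supported by at least ``min_support`` transcripts).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    chroms = {g.chrom for g in genes}
    for tx in transcripts:
        if tx.chrom not in chroms:
            raise ValueError(
                f"transcript {tx.transcript_id} on chromosome {tx.chrom} "
                "absent from the annotation"
            )
    ins_by_id = {i.insertion_id: i for i in insertions}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append(tx)

    events: list[HybridSpliceEvent] = []
    verdicts: dict[str, bool] = {}
    for call in calls:
        if call.context != "intronic" or call.orientation != "forward":
            continue
        ins = ins_by_id[call.insertion_id]
        host = gene_by_id[call.host_gene]
        iv = ins.interval
        n_support = 0
        iso = host.reference_isoform()
        host_exons_tx_order = iso.exons_in_transcription_order()
        for tx in by_chrom.get(iv.chrom, []):
            if tx.strand != host.strand:
                continue
            if require_start_in_te:
                if not iv.contains_point(tx.five_prime):
                    continue
            else:
                first_exon = tx.exons_in_transcription_order()[0]
                from .intervals import GenomicInterval

                if not iv.overlaps(
                    GenomicInterval(tx.chrom, first_exon[0], first_exon[1])
                ):
                    continue
            jn = _first_junction(tx)
            if jn is None:
                continue
            donor_pos, acceptor = jn
            if not iv.contains_point(donor_pos):
                continue
            # acceptor must land on the 5' (transcription-order) boundary
            # of an annotated host exon
            acceptor_ord = None
            for k, (es, ee) in enumerate(host_exons_tx_order, start=1):
                boundary = es if host.strand != "-" else ee
                if abs(acceptor - boundary) <= acceptor_tolerance:
                    acceptor_ord = k
                    break
            if acceptor_ord is None:
                continue
            first_exon = tx.exons_in_transcription_order()[0]
            te_seg = first_exon[1] - first_exon[0]
            if iv.strand == "-":
                donor_offset = iv.end - 1 - donor_pos
            else:
                donor_offset = donor_pos - iv.start
            events.append(
                HybridSpliceEvent(
                    insertion_id=ins.insertion_id,
                    transcript_id=tx.transcript_id,
                    donor_genomic=donor_pos,
                    donor_offset_on_te=donor_offset,
                    acceptor_exon_ordinal=acceptor_ord,
                    skipped_exons=frozenset(range(1, acceptor_ord)),
                    te_segment_length=te_seg,
                )
            )
            n_support += 1
        verdicts[call.insertion_id] = n_support >= min_support
    return events, verdicts


@dataclass(frozen=True)
class CompetenceTestResult:
    """Distance comparison between spliced and unspliced intF insertions."""

    u: float
    p_value: float
    method: str
    median_with: float
    median_without: float
    delta: float  # median(without) - median(with)
    n_with: int
    n_without: int


def splicing_competence_test(
    distances_with: Sequence[float], distances_without: Sequence[float]
) -> CompetenceTestResult:
    """Two-sided Mann-Whitney U test of downstream-exon distances,
    spliced versus unspliced insertions, with group medians and their
    difference."""
    if len(distances_with) == 0 or len(distances_without) == 0:
        raise ValueError("both groups must be non-empty")
    res = mann_whitney_u(distances_with, distances_without)
    m_with = median(distances_with)
    m_without = median(distances_without)
    return CompetenceTestResult(
        u=res.u,
        p_value=res.p_value,
        method=res.method,
        median_with=m_with,
        median_without=m_without,
        delta=m_without - m_with,
        n_with=len(distances_with),
        n_without=len(distances_without),
    )
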
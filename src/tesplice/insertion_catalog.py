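"""Classification of TE insertions by genomic context.

An insertion is *exonic* if it overlaps at least one base of any exon of
any isoform of an overlapping gene, *intronic* if it lies inside a gene
span without touching an exon, and *intergenic* otherwise.  Intronic
insertions whose strand matches the host gene ("intF" insertions) are
the ones that can feed a host-TE hybrid transcript, so for those the
distance to the next downstream exon is the key covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    Gene,
    GenomicInterval,
    TranscriptModel,
    merge_intervals,
    total_covered,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import AlignmentBlock


@dataclass(frozen=True)
class TEInsertion:
    """One annotated TE copy.

    ``cons_span`` is the half-open interval the copy covers on the family
    consensus, when the annotation provides it.
    """

    insertion_id: str
    family: str
    interval: GenomicInterval
    cons_span: tuple[int, int] | None = None
    divergence: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ContextCall:
    """Classification verdict for one insertion."""

    insertion_id: str
    context: str  # "exonic" | "intronic" | "intergenic"
    host_gene: str | None = None
    orientation: str = "not-applicable"  # "forward" | "reverse" | "not-applicable"
    intron_ordinal: int | None = None  # 1-based, transcription order
    distance_downstream: int | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.context not in ("exonic", "intronic", "intergenic"):
            raise ValueError(f"bad context {self.context!r}")
        if self.context == "intergenic" and (
            self.host_gene is not None or self.orientation != "not-applicable"
        ):
            raise ValueError("intergenic calls carry no host gene or orientation")
        if self.intron_ordinal is not None and self.intron_ordinal < 1:
            raise ValueError("intron ordinal is 1-based")
        if self.distance_downstream is not None and self.distance_downstream < 0:
            raise ValueError("downstream distance must be >= 0")


@dataclass(frozen=True)
class LiftedSite:
    """An insertion point lifted to another assembly via its flanks."""

    source_id: str
    status: str  # concordant | discordant-chrom | discordant-strand | discordant-gap | unmapped
    target_chrom: str | None = None
    target_position: int | None = None
    target_strand: str | None = None

    _STATUSES = (
        "concordant",
        "discordant-chrom",
        "discordant-strand",
        "discordant-gap",
        "unmapped",
    )

    def __post_init__(self) -> None:
        if self.status not in self._STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.target_position is not None and self.target_position < 0:
            raise ValueError("target position must be >= 0")


# ---------------------------------------------------------------------------
# full-length filtering


def filter_full_length(
    insertions: Iterable[TEInsertion],
    consensus_len: int | None = None,
    min_len: int | None = None,
    min_frac: float | None = None,
) -> list[TEInsertion]:
    """Keep copies long enough to count as full-length.

    A copy is retained iff its genomic length is >= ``min_len`` (when
    given) and >= ``min_frac * consensus_len`` (when given); both bounds
    are inclusive.  For the Springer family the operative thresholds are
    7,500 nt, i.e. >= 99.5% of the 7,546-nt consensus.
    """
    if min_len is None and min_frac is None:
        raise ValueError("supply at least one of min_len / min_frac")
    if min_frac is not None:
        if not 0 < min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")
        if consensus_len is None or consensus_len <= 0:
            raise ValueError("min_frac requires a positive consensus_len")
    out = []
    for ins in insertions:
        if min_len is not None and ins.length < min_len:
            continue
        if min_frac is not None and ins.length < min_frac * consensus_len:
            continue
        out.append(ins)
    return out


# ---------------------------------------------------------------------------
# classification


def _intron_ordinal(isoform: TranscriptModel, point: int) -> int | None:
    """1-based index, in transcription order, of the intron containing a point."""
    introns = isoform.introns()
    for i, (s, e) in enumerate(introns):
        if s <= point < e:
            return i + 1 if isoform.strand != "-" else len(introns) - i
    return None


def classify_insertion(
    insertion: TEInsertion,
    genes: Sequence[Gene],
    known_chroms: set[str] | None = None,
) -> ContextCall:
    """Classify one insertion against a gene annotation.

    Exonic takes priority over intronic; with several overlapping genes
    the primary call goes to the gene whose exon is hit, else to the gene
    with the shortest enclosing intron (ties by gene id), and the
    ambiguity flag is set.  Intron ordinals are computed on the isoform
    with the most exons, at the insertion midpoint.
    """
    iv = insertion.interval
    if known_chroms is not None and iv.chrom not in known_chroms:
        raise ValueError(f"insertion {insertion.insertion_id}: unknown chromosome {iv.chrom}")
    overlapping = [g for g in genes if g.chrom == iv.chrom and g.span.overlaps(iv)]
    if known_chroms is None and not overlapping:
        chroms = {g.chrom for g in genes}
        if genes and iv.chrom not in chroms:
            raise ValueError(
                f"insertion {insertion.insertion_id}: unknown chromosome {iv.chrom}"
            )
    if not overlapping:
        return ContextCall(insertion.insertion_id, "intergenic")

    ambiguous = len(overlapping) > 1
    exon_hits = [
        g
        for g in overlapping
        if any(
            GenomicInterval(g.chrom, s, e).overlaps(iv) for s, e in g.exon_union()
        )
    ]
    if exon_hits:
        host = sorted(exon_hits, key=lambda g: g.gene_id)[0]
        orientation = (
            "forward"
            if iv.strand == host.strand
            else "reverse"
            if iv.strand in ("+", "-")
            else "not-applicable"
        )
        return ContextCall(
            insertion.insertion_id,
            "exonic",
            host_gene=host.gene_id,
            orientation=orientation,
            ambiguous=ambiguous,
        )

    # intronic: pick host with the shortest enclosing intron around the midpoint
    mid = iv.midpoint
    best: tuple[int, str, Gene] | None = None
    for g in overlapping:
        iso = g.reference_isoform()
        for s, e in iso.introns():
            if s <= mid < e:
                key = (e - s, g.gene_id)
                if best is None or key < (best[0], best[1]):
                    best = (e - s, g.gene_id, g)
    host = best[2] if best else sorted(overlapping, key=lambda g: g.gene_id)[0]
    iso = host.reference_isoform()
    ordinal = _intron_ordinal(iso, mid)
    orientation = (
        "forward"
        if iv.strand == host.strand
        else "reverse"
        if iv.strand in ("+", "-")
        else "not-applicable"
    )
    return ContextCall(
        insertion.insertion_id,
        "intronic",
        host_gene=host.gene_id,
        orientation=orientation,
        intron_ordinal=ordinal,
        ambiguous=ambiguous,
    )


def classify_all(
    insertions: Sequence[TEInsertion], genes: Sequence[Gene]
) -> list[ContextCall]:
    """Classify a batch of insertions with a per-chromosome gene index."""
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = set(by_chrom)
    out = []
    for ins in insertions:
        if ins.interval.chrom not in chroms:
            raise ValueError(
                f"insertion {ins.insertion_id}: unknown chromosome {ins.interval.chrom}"
            )
        out.append(
            classify_insertion(ins, by_chrom[ins.interval.chrom], known_chroms=chroms)
        )
    return out


def context_composition(calls: Sequence[ContextCall]) -> dict[str, float]:
    """Fractions of exonic / intronic / intergenic calls (sum to 1)."""
    if not calls:
        raise ValueError("no calls")
    n = len(calls)
    return {
        cat: sum(1 for c in calls if c.context == cat) / n
        for cat in ("exonic", "intronic", "intergenic")
    }


def genome_feature_composition(
    genes: Sequence[Gene], genome_len: int
) -> dict[str, float]:
    """Fractions of the genome that are exonic / intronic / intergenic.

    Computed on merged, disjoint partitions: exonic = union of all exons;
    intronic = union of gene spans minus exonic; intergenic = the rest.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be > 0")
    exons = [(s, e) for g in genes for s, e in g.exon_union()]
    spans = [(g.start, g.end) for g in genes]
    exonic = total_covered(exons) if exons else 0
    genic = total_covered(spans) if spans else 0
    intronic = genic - exonic
    return {
        "exonic": exonic / genome_len,
        "intronic": intronic / genome_len,
        "intergenic": (genome_len - genic) / genome_len,
    }


# ---------------------------------------------------------------------------
# downstream-exon distance


def distance_to_downstream_exon(
    insertion: TEInsertion,
    gene: Gene,
    boundary: str = "start",
) -> int | None:
    """Distance from an intronic forward insertion to the next downstream exon.

    For a ``+``-strand gene this is (first exon start past the insertion)
    minus the insertion end; ``-``-strand genes are handled mirror-
    symmetrically.  ``boundary="end"`` measures to the 3' boundary of that
    exon instead.  Returns None when no annotated exon lies downstream.
    """
    if boundary not in ("start", "end"):
        raise ValueError("boundary must be 'start' or 'end'")
    iv = insertion.interval
    exons = gene.exon_union()
    if gene.strand != "-":
        downstream = [ex for ex in exons if ex[0] >= iv.end]
        if not downstream:
            return None
        ex = min(downstream)
        ref = ex[0] if boundary == "start" else ex[1]
        return ref - iv.end
    downstream = [ex for ex in exons if ex[1] <= iv.start]
    if not downstream:
        return None
    ex = max(downstream)
    ref = ex[1] if boundary == "start" else ex[0]
    return iv.start - ref


# ---------------------------------------------------------------------------
# flank-based lift-over


def lift_by_flanks(
    source_id: str,
    left_flank_hit: "AlignmentBlock | None",
    right_flank_hit: "AlignmentBlock | None",
    max_gap: int = 100,
) -> LiftedSite:
    """Locate an insertion point on another assembly from its flank hits.

    The two 100-bp flanks are aligned externally; the call is concordant
    when both best hits land on the same chromosome, in the same relative
    orientation, with inner ends separated by at most ``max_gap`` (the
    default 100 nt absorbs target-site duplications).  The lifted point
    is the floor midpoint between the inner ends.
    """
    if left_flank_hit is None or right_flank_hit is None:
        return LiftedSite(source_id, "unmapped")
    lt, rt = left_flank_hit.target, right_flank_hit.target
    if lt.chrom != rt.chrom:
        return LiftedSite(source_id, "discordant-chrom")
    if left_flank_hit.strand != right_flank_hit.strand:
        return LiftedSite(source_id, "discordant-strand")
    first, second = (lt, rt) if lt.start <= rt.start else (rt, lt)
    gap = second.start - first.end
    if gap > max_gap:
        return LiftedSite(source_id, "discordant-gap")
    pos = (first.end + second.start) // 2
    return LiftedSite(
        source_id,
        "concordant",
        target_chrom=lt.chrom,
        target_position=max(0, pos),
        target_strand=left_flank_hit.strand,
    )


# ---------------------------------------------------------------------------
# positional and expression stratification


def intron_position_distribution(calls: Sequence[ContextCall]) -> dict[int, int]:
    """Histogram of intron ordinals over intronic calls with a known ordinal."""
    hist: dict[int, int] = {}
    for c in calls:
        if c.context == "intronic" and c.intron_ordinal is not None:
            hist[c.intron_ordinal] = hist.get(c.intron_ordinal, 0) + 1
    return dict(sorted(hist.items()))


def expression_stratify(
    calls: Sequence[ContextCall],
    expression: Mapping[str, float],
    n_bins: int = 5,
) -> "pd.DataFrame":
    """Bin genes into expression quantiles and count insertions per bin.

    Strata are equal-count quantile bins over all genes with expression
    data; per-bin enrichment is (insertion share) / (gene share), so a
    value above 1 marks preferential insertion into that stratum.
    """
    import pandas as pd

    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = pd.Series(expression, dtype=float).sort_values(kind="mergesort")
    if genes.empty:
        raise ValueError("empty expression table")
    bins = pd.qcut(genes.rank(method="first"), n_bins, labels=False)
    gene_bin = dict(zip(genes.index, bins))
    ins_counts = np.zeros(n_bins, dtype=int)
    for c in calls:
        if c.host_gene is not None and c.host_gene in gene_bin:
            ins_counts[gene_bin[c.host_gene]] += 1
    gene_counts = np.bincount(list(gene_bin.values()), minlength=n_bins)
    total_ins = ins_counts.sum()
    total_genes = gene_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = (ins_counts / max(total_ins, 1)) / (gene_counts / total_genes)
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "n_insertions": ins_counts,
            "n_genes": gene_counts,
            "enrichment": enrich,
        }
    )


def calls_to_dataframe(calls: Sequence[ContextCall]) -> "pd.DataFrame":
    """ContextCall table with a stable column order (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "insertion_id": c.insertion_id,
                "context": c.context,
                "host_gene": c.host_gene if c.host_gene is not None else "",
                "orientation": c.orientation,
                "intron_ordinal": c.intron_ordinal if c.intron_ordinal is not None else "",
                "distance_downstream": (
                    c.distance_downstream if c.distance_downstream is not None else ""
                ),
                "ambiguous": int(c.ambiguous),
            }
            for c in calls
        ],
        columns=[
            "insertion_id",
            "context",
            "host_gene",
            "orientation",
            "intron_ordinal",
            "distance_downstream",
            "ambiguous",
        ],
    )
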
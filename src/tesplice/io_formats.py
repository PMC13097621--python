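"""Readers and writers for the external formats the pipeline touches.

Every reader converts to the package-wide 0-based half-open convention
(see :mod:`tesplice.intervals`); every writer converts back.  SAM is
handled through pysam, GFF3 through gffutils, FASTA through Biopython.
RepeatMasker ``.out``, BED12, bedGraph, PAF and the expression table are
plain-text dialects parsed directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Gene, GenomicInterval, TranscriptModel
from .insertion_catalog import TEInsertion


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read, reduced to what the quantification steps need."""

    read_id: str
    reference: str
    start: int  # 0-based leftmost reference position
    aligned_span: int  # reference bases consumed by the alignment
    is_reverse: bool
    mapq: int
    read_length: int

    def __post_init__(self) -> None:
        if self.aligned_span < 1:
            raise ValueError(f"read {self.read_id}: aligned span must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.aligned_span


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block (e.g. a PAF row)."""

    query: GenomicInterval
    target: GenomicInterval
    strand: str  # "+" same orientation, "-" opposite
    block_class: str | None = None  # "syntenic" | "rearranged" | None


# ---------------------------------------------------------------------------
# RepeatMasker .out / GFF export

_RM_MIN_COLS = 14


def _parse_rm_out_line(fields: list[str], lineno: int) -> TEInsertion:
    try:
        divergence = float(fields[1])
        chrom = fields[4]
        start1, end1 = int(fields[5]), int(fields[6])
        strand_sym = fields[8]
        family = fields[9]
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed RepeatMasker row at line {lineno}: {exc}") from exc
    if strand_sym == "+":
        strand = "+"
        cons_a, cons_b = fields[11], fields[12]
    elif strand_sym in ("C", "-"):
        strand = "-"
        # on the C strand the consensus columns run (left) end begin
        cons_a, cons_b = fields[13], fields[12]
    else:
        raise ParseError(
            f"unknown strand symbol {strand_sym!r} at line {lineno} "
            "(expected '+', '-' or 'C')"
        )
    cons_span = None
    try:
        cb, ce = int(cons_a), int(cons_b)
        if 1 <= cb <= ce:
            cons_span = (cb - 1, ce)
    except ValueError:
        pass
    interval = GenomicInterval.from_one_based(chrom, start1, end1, strand)
    return TEInsertion(
        insertion_id=f"rm_{lineno}",
        family=family,
        interval=interval,
        cons_span=cons_span,
        divergence=divergence,
    )


def _parse_rm_gff_line(fields: list[str], lineno: int) -> TEInsertion:
    chrom, _, _, start1, end1, _, strand_sym = fields[:7]
    if strand_sym not in ("+", "-", "C"):
        raise ParseError(f"unknown strand symbol {strand_sym!r} at line {lineno}")
    strand = "-" if strand_sym in ("-", "C") else "+"
    attrs = fields[8]
    family = None
    cons_span = None
    # GFF2 export: Target "Motif:FAM" beg end ; GFF3 export: Target=FAM beg end
    token = attrs.replace('"', " ").replace("=", " ").replace(":", " ")
    parts = token.split()
    for i, p in enumerate(parts):
        if p in ("Target", "Motif") and i + 1 < len(parts):
            cand = parts[i + 1]
            if cand not in ("Motif",):
                family = cand
                if i + 3 < len(parts) + 1:
                    try:
                        cb, ce = int(parts[i + 2]), int(parts[i + 3])
                        cons_span = (cb - 1, ce)
                    except (ValueError, IndexError):
                        pass
                break
    if family is None:
        raise ParseError(f"no Target family in attributes at line {lineno}")
    interval = GenomicInterval.from_one_based(chrom, int(start1), int(end1), strand)
    return TEInsertion(
        insertion_id=f"rm_{lineno}", family=family, interval=interval, cons_span=cons_span
    )


def read_repeatmasker_out(
    path: str | os.PathLike,
    family_filter: str | None = None,
    merge_gap: int | None = None,
) -> list[TEInsertion]:
    """Parse RepeatMasker ``.out`` (or its GFF export) into TE insertions.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    strand ``C`` maps to ``-``; consensus begin/end and percent divergence
    are retained when present.  Output is sorted by (chrom, start).

    Parameters
    ----------
    family_filter : str, optional
        Keep only rows whose repeat name equals this family.
    merge_gap : int, optional
        When set, adjacent same-family same-strand rows separated by less
        than this many bases with compatible consensus coordinates are
        merged into one insertion (LTR copies are often reported
        fragmented).  ``None`` (default) reproduces raw row counts.
    """
    records: list[TEInsertion] = []
    is_gff = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                if line.startswith("##gff-version"):
                    is_gff = True
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if is_gff is None:
                # .out has 3 header lines starting with column names/blank
                first = fields[0]
                if first in ("SW", "score") or line.lstrip().startswith("SW"):
                    continue
                if not first.lstrip("-").isdigit() and len(fields) == 9:
                    is_gff = True
                else:
                    is_gff = False
            if is_gff:
                if len(fields) < 9:
                    raise ParseError(f"malformed GFF row at line {lineno}: "
                                     f"{len(fields)} columns (expected >= 9)")
                rec = _parse_rm_gff_line(fields, lineno)
            else:
                if not fields[0].lstrip("-").isdigit():
                    continue  # header continuation
                if len(fields) < _RM_MIN_COLS:
                    raise ParseError(
                        f"malformed RepeatMasker row at line {lineno}: "
                        f"{len(fields)} columns (expected >= {_RM_MIN_COLS})"
                    )
                rec = _parse_rm_out_line(fields, lineno)
            if family_filter is None or rec.family == family_filter:
                records.append(rec)
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    if merge_gap is not None:
        records = _merge_fragmented(records, merge_gap)
    return records


def _merge_fragmented(records: list[TEInsertion], gap: int) -> list[TEInsertion]:
    merged: list[TEInsertion] = []
    for rec in records:
        if merged:
            prev = merged[-1]
            same = (
                prev.family == rec.family
                and prev.interval.chrom == rec.interval.chrom
                and prev.interval.strand == rec.interval.strand
                and 0 <= rec.interval.start - prev.interval.end < gap
            )
            compatible = (
                prev.cons_span is None
                or rec.cons_span is None
                or (
                    rec.cons_span[0] >= prev.cons_span[0]
                    if prev.interval.strand == "+"
                    else rec.cons_span[1] <= prev.cons_span[1]
                )
            )
            if same and compatible:
                cons = None
                if prev.cons_span and rec.cons_span:
                    cons = (
                        min(prev.cons_span[0], rec.cons_span[0]),
                        max(prev.cons_span[1], rec.cons_span[1]),
                    )
                merged[-1] = TEInsertion(
                    insertion_id=prev.insertion_id,
                    family=prev.family,
                    interval=GenomicInterval(
                        prev.interval.chrom,
                        prev.interval.start,
                        rec.interval.end,
                        prev.interval.strand,
                    ),
                    cons_span=cons,
                    divergence=prev.divergence,
                )
                continue
        merged.append(rec)
    return merged


def write_repeatmasker_out(path: str | os.PathLike, records: Sequence[TEInsertion]) -> None:
    """Emit a minimal RepeatMasker ``.out`` (3 header lines + rows)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching"
            "       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat"
            "       class/family         begin  end (left)   ID\n\n"
        )
        for i, rec in enumerate(records, start=1):
            chrom, b1, e1 = rec.interval.to_one_based()
            div = rec.divergence if rec.divergence is not None else 0.0
            cb, ce = rec.cons_span if rec.cons_span else (0, rec.interval.length)
            if rec.interval.strand == "+":
                strand, cons = "+", f"{cb + 1} {ce} (0)"
            else:
                strand, cons = "C", f"(0) {ce} {cb + 1}"
            fh.write(
                f"1000 {div:.1f} 0.0 0.0 {chrom} {b1} {e1} (0) {strand} "
                f"{rec.family} LTR/Unknown {cons} {i}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 genes


def read_gff3_genes(path: str | os.PathLike) -> list[Gene]:
    """Load gene models (gene -> mRNA -> exon) from a GFF3 file.

    Exon chains are converted to 0-based half-open and sorted; each
    transcript is linked to its gene id and strand.  An exon whose Parent
    cannot be resolved, or overlapping exons within one transcript, raise
    an error.
    """
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts_by_id: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    tx_gene: dict[str, str] = {}
    known_tx: set[str] = set()
    for feat in db.features_of_type(("mRNA", "transcript")):
        parents = [p.id for p in db.parents(feat, featuretype="gene")]
        gene_id = parents[0] if parents else feat.id
        known_tx.add(feat.id)
        tx_gene[feat.id] = gene_id
        transcripts_by_id[feat.id] = (feat.seqid, feat.strand, gene_id, [])
    for exon in db.features_of_type("exon"):
        parent_ids = exon.attributes.get("Parent")
        if not parent_ids:
            raise ParseError(f"exon {exon.id} has no Parent attribute")
        for pid in parent_ids:
            if pid not in known_tx:
                raise ParseError(
                    f"exon {exon.id}: Parent {pid!r} does not resolve to a transcript"
                )
            transcripts_by_id[pid][3].append((exon.start - 1, exon.end))
    genes: dict[str, Gene] = {}
    for tx_id, (chrom, strand, gene_id, exons) in transcripts_by_id.items():
        if not exons:
            continue
        model = TranscriptModel(tx_id, chrom, strand, exons, gene_id=gene_id)
        gene = genes.setdefault(gene_id, Gene(gene_id, chrom, strand))
        gene.transcripts.append(model)
    return [genes[g] for g in sorted(genes)]


def write_gff3_genes(path: str | os.PathLike, genes: Sequence[Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            c, b1, e1 = gene.span.to_one_based()
            fh.write(
                f"{c}\ttesplice\tgene\t{b1}\t{e1}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                c, b1, e1 = tx.span.to_one_based()
                fh.write(
                    f"{c}\ttesplice\tmRNA\t{b1}\t{e1}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(tx.exons, start=1):
                    fh.write(
                        f"{c}\ttesplice\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                        f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED12


def read_bed12_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse BED12 into exon-chain transcript models.

    blockStarts are relative to chromStart per the BED specification; a
    blockCount that disagrees with the blockSizes/blockStarts lists is an
    error.
    """
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"BED12 requires 12 columns at line {lineno}")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(
                    f"blockCount mismatch at line {lineno}: declared {n_blocks}, "
                    f"got {len(sizes)} sizes / {len(starts)} starts"
                )
            exons = [(start + st, start + st + sz) for st, sz in zip(starts, sizes)]
            out.append(TranscriptModel(name, chrom, strand, exons))
    return out


def write_bed12(path: str | os.PathLike, transcripts: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            start, end = tx.start, tx.end
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            starts = ",".join(str(s - start) for s, _ in tx.exons)
            fh.write(
                f"{tx.chrom}\t{start}\t{end}\t{tx.transcript_id}\t0\t{tx.strand}\t"
                f"{start}\t{end}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# SAM

_SUPPORTED_CIGAR_OPS = set(range(9))  # MIDNSHP=X


def read_sam(
    path: str | os.PathLike, min_mapq: int = 0
) -> Iterator[AlignedReadRecord]:
    """Stream primary alignments from a SAM file.

    Secondary (0x100) and supplementary (0x800) alignments and unmapped
    reads are dropped; an optional mapping-quality floor is applied.
    Orientation comes from flag 0x10.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            for op, _ in aln.cigartuples or []:
                if op not in _SUPPORTED_CIGAR_OPS:
                    raise ParseError(
                        f"unsupported CIGAR op code {op} in read {aln.query_name}"
                    )
            span = aln.reference_length or 0
            if span < 1:
                continue
            rlen = aln.infer_read_length() or aln.query_length or span
            yield AlignedReadRecord(
                read_id=aln.query_name,
                reference=aln.reference_name,
                start=aln.reference_start,
                aligned_span=span,
                is_reverse=aln.is_reverse,
                mapq=aln.mapping_quality,
                read_length=rlen,
            )


def write_sam(
    path: str | os.PathLike,
    records: Iterable[AlignedReadRecord],
    reference_lengths: Mapping[str, int],
) -> None:
    """Write fully-aligned records as SAM (CIGAR ``<len>M``, no SEQ)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.is_reverse else 0
            a.reference_id = tid[rec.reference]
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            a.cigarstring = f"{rec.read_length}M"
            out.write(a)


# ---------------------------------------------------------------------------
# bedGraph


@dataclass
class CoverageTrack:
    """Sparse per-chromosome coverage from a bedGraph file."""

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self.intervals.setdefault(chrom, []).append((start, end, value))

    def chrom_end(self, chrom: str) -> int:
        iv = self.intervals.get(chrom)
        return max(e for _, e, _ in iv) if iv else 0

    def dense(self, chrom: str, length: int | None = None):
        """Materialise one chromosome as a float array (missing = 0)."""
        import numpy as np

        n = length if length is not None else self.chrom_end(chrom)
        arr = np.zeros(n, dtype=float)
        for s, e, v in self.intervals.get(chrom, []):
            arr[max(0, s) : min(n, e)] = v
        return arr


def read_bedgraph(path: str | os.PathLike) -> CoverageTrack:
    track = CoverageTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) != 4:
                raise ParseError(f"bedGraph requires 4 columns at line {lineno}")
            track.add(f[0], int(f[1]), int(f[2]), float(f[3]))
    return track


def write_bedgraph(path: str | os.PathLike, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.intervals:
            for s, e, v in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# PAF

_SYNTENY_TAG = "sc"  # custom tag carrying the synteny class (S or R)


def read_paf(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Parse PAF rows (columns 1-12, optional tags) into alignment blocks.

    A custom ``sc:A:S`` / ``sc:A:R`` tag, when present, sets the block
    class to syntenic or rearranged.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"PAF requires >= 12 columns at line {lineno}")
            strand = f[4]
            if strand not in ("+", "-"):
                raise ParseError(f"bad PAF strand {strand!r} at line {lineno}")
            block_class = None
            for tag in f[12:]:
                if tag.startswith(f"{_SYNTENY_TAG}:A:"):
                    block_class = {"S": "syntenic", "R": "rearranged"}.get(tag[-1])
            blocks.append(
                AlignmentBlock(
                    query=GenomicInterval(f[0], int(f[2]), int(f[3])),
                    target=GenomicInterval(f[5], int(f[7]), int(f[8])),
                    strand=strand,
                    block_class=block_class,
                )
            )
    return blocks


def write_paf(
    path: str | os.PathLike,
    blocks: Sequence[AlignmentBlock],
    query_lengths: Mapping[str, int] | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            qlen = (query_lengths or {}).get(b.query.chrom, b.query.end)
            tlen = (target_lengths or {}).get(b.target.chrom, b.target.end)
            span = min(b.query.length, b.target.length)
            tag = ""
            if b.block_class:
                tag = f"\t{_SYNTENY_TAG}:A:{'S' if b.block_class == 'syntenic' else 'R'}"
            fh.write(
                f"{b.query.chrom}\t{qlen}\t{b.query.start}\t{b.query.end}\t{b.strand}\t"
                f"{b.target.chrom}\t{tlen}\t{b.target.start}\t{b.target.end}\t"
                f"{span}\t{span}\t60{tag}\n"
            )


# ---------------------------------------------------------------------------
# expression table / FASTA


def read_expression_tsv(path: str | os.PathLike) -> dict[str, float]:
    """Two-column gene -> expression TSV; a non-numeric first row is a header."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ParseError(f"expression TSV requires 2 columns at line {lineno}")
            try:
                out[f[0]] = float(f[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"non-numeric expression at line {lineno}")
    return out


def write_expression_tsv(path: str | os.PathLike, table: Mapping[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for gene, val in table.items():
            fh.write(f"{gene}\t{val:g}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
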
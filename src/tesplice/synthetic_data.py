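"""Seeded generator for a complete toy dataset with known ground truth.

The bundle emulates the statistical structure every downstream stage
assumes: a two-haplotype genome with genes and planted TE insertions of
known class/orientation, hybrid transcripts whose occurrence follows a
logistic function of the distance to the next downstream exon,
strand-controlled small-RNA reads on TE consensus sequences, an
accessibility peak at a fixed offset upstream of every insertion, AT-rich
arrays around insertion points with Beta-distributed relative positions,
and planted rearrangements in a dedicated "cluster" chromosome.

All randomness flows from one seed; each output stream draws from a
fixed substream id, so identical seeds give byte-identical bundles.
"""

from __future__ import annotations

import json
import math
import os
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_formats
from .insertion_catalog import TEInsertion
from .intervals import Gene, GenomicInterval, TranscriptModel
from .io_formats import AlignedReadRecord, AlignmentBlock, CoverageTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TEFamilyConfig:
    """Geometry of one TE family's consensus."""

    consensus_len: int
    ltr_len: int = 405
    donor_pattern: str = "GTAAGTG"
    donor_offset: int = 43  # nt downstream of the 5' LTR end
    tss_offset: int = 100  # transcription start within the 5' LTR


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults define the study conditions."""

    haplotypes: tuple[str, ...] = ("hap1", "hap2")
    n_genes: int = 160  # per haplotype
    exon_count_range: tuple[int, int] = (4, 8)
    exon_len_range: tuple[int, int] = (150, 300)
    intron_len_range: tuple[int, int] = (800, 3000)
    spacer_len_range: tuple[int, int] = (1000, 3000)

    # planted insertions per haplotype, by context
    n_forward_intronic: int = 100
    n_reverse_intronic: int = 25
    n_exonic: int = 10
    n_intergenic: int = 15
    n_intergenic_secondary: int = 5  # secondary family (copia-like)

    te_families: dict[str, TEFamilyConfig] = field(
        default_factory=lambda: {
            "Springer": TEFamilyConfig(7546, 405, "GTAAGTG", 43),
            "copia": TEFamilyConfig(5146, 276, "GTATGTT", 43),
            "gypsy1": TEFamilyConfig(6500, 400, "GTAAGAG", 60),
            "Transpac": TEFamilyConfig(5200, 350, "GTAAGCG", 50),
            "Xanthias": TEFamilyConfig(5400, 360, "GTAAGGG", 55),
        }
    )
    primary_family: str = "Springer"
    secondary_family: str = "copia"

    # logistic splicing model: P(spliced) = sigmoid(alpha - beta*log10(d)),
    # log10(d) ~ Normal(mu, sd).  Calibrated so the unspliced/spliced
    # median-distance ratio is ~3.6 and the spliced fraction ~0.6.
    distance_log10_mu: float = 3.65
    distance_log10_sd: float = 0.5
    splice_alpha: float = 13.265
    splice_beta: float = 3.5
    distance_clip: tuple[int, int] = (200, 50000)
    upstream_margin_range: tuple[int, int] = (200, 1000)
    hybrid_support: int = 1  # hybrid transcripts per spliced insertion

    # intron ordinal bias toward the 5' end (geometric success prob)
    ordinal_geometric_p: float = 0.45

    # gene expression (log-normal) and expression-weighted host choice
    expression_mu: float = 1.0
    expression_sigma: float = 1.2

    # small RNA model: per-library per-family sense fractions
    smallrna_libraries: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "osc": {
                "Springer": 0.90,
                "copia": 0.80,
                "gypsy1": 0.75,
                "Transpac": 0.70,
                "Xanthias": 0.65,
            },
            "ovary": {
                "Springer": 0.20,
                "copia": 0.25,
                "gypsy1": 0.15,
                "Transpac": 0.30,
                "Xanthias": 0.25,
            },
        }
    )
    smallrna_reads_per_family: int = 10000
    smallrna_len_range: tuple[int, int] = (23, 29)

    # accessibility model: triangular peak at a fixed offset upstream of
    # each insertion's 5' junction, on a constant background
    atac_background: float = 1.0
    atac_peak_height: float = 8.0
    atac_peak_offset: int = -1000  # nt, negative = upstream
    atac_peak_half_width: int = 150
    atac_bin: int = 10

    # AT-rich arrays around insertion points; relative position ~ Beta(a, b)
    array_len_range: tuple[int, int] = (2000, 4000)
    array_beta: tuple[float, float] = (3.0, 3.0)
    at_rich_prob: float = 0.35  # per-base prob of A and of T in array flanks

    # cluster chromosome with planted rearrangements
    cluster_len: int = 100000
    cluster_region: tuple[int, int] = (10000, 90000)
    cluster_nonsyntenic_fraction: float = 0.529
    cluster_n_rearranged: int = 6


@dataclass
class SyntheticDataset:
    """In-memory handles plus file paths for one generated bundle."""

    config: SyntheticConfig
    seed: int
    out_dir: Path
    paths: dict[str, Path]
    truth: dict
    genes: dict[str, list[Gene]]
    insertions: dict[str, list[TEInsertion]]
    transcripts: dict[str, list[TranscriptModel]]
    chrom_lengths: dict[str, dict[str, int]]
    consensus: dict[str, str]
    atac_tracks: dict[str, CoverageTrack]
    paf_blocks: list[AlignmentBlock]


def _random_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    if n <= 0:
        return ""
    if probs is None:
        idx = rng.integers(0, 4, n)
    else:
        idx = rng.choice(4, size=n, p=probs)
    return _BASES[idx].tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "N": "[ACGT]",
}


def _scrub_pattern(seq: list[str], pattern: str, keep: int, start: int) -> None:
    """Destroy spurious matches of an IUPAC pattern in-place, sparing ``keep``."""
    regex = re.compile("".join(_IUPAC_RE.get(c, c) for c in pattern.upper()))
    while True:
        text = "".join(seq)
        dirty = [
            p
            for p in range(start, len(text) - len(pattern) + 1)
            if p != keep and regex.match(text, p)
        ]
        if not dirty:
            return
        for p in dirty:
            seq[p] = "C"  # break the GT dinucleotide; cannot create a new match


def make_consensus(family: str, cfg: TEFamilyConfig, seed: int) -> str:
    """Deterministic consensus sequence with the donor motif planted at
    ltr_len + donor_offset and no spurious donor match downstream of the LTR."""
    rng = np.random.default_rng([seed, zlib.crc32(family.encode()) % (2**31)])
    seq = list(_random_seq(rng, cfg.consensus_len))
    pos = cfg.ltr_len + cfg.donor_offset
    for i, b in enumerate(cfg.donor_pattern):
        seq[pos + i] = b
    _scrub_pattern(seq, cfg.donor_pattern[:6], keep=pos, start=cfg.ltr_len)
    return "".join(seq)


def sample_splicing_distances(
    n: int, config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (distances, spliced flags) from the logistic splicing model.

    This is the same model `generate_dataset` uses for forward intronic
    insertions, exposed so the distance-effect statistics can be
    replicated without building whole genomes.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    log_d = rng.normal(cfg.distance_log10_mu, cfg.distance_log10_sd, n)
    d = np.clip(np.round(10**log_d), *cfg.distance_clip).astype(int)
    p = 1.0 / (1.0 + np.exp(-(cfg.splice_alpha - cfg.splice_beta * np.log10(d))))
    spliced = rng.random(n) < p
    return d, spliced


def simulate_genomic_reads(
    chrom_lengths: Mapping[str, int],
    depth: float = 10.0,
    read_len: int = 150,
    seed: int | None = None,
    mapq: int = 60,
) -> list[AlignedReadRecord]:
    """Uniform perfect reads over an assembly at a target mean depth."""
    rng = np.random.default_rng(seed)
    reads: list[AlignedReadRecord] = []
    for chrom, length in chrom_lengths.items():
        if length < read_len:
            continue
        n = int(round(depth * length / read_len))
        starts = rng.integers(0, length - read_len + 1, n)
        rev = rng.random(n) < 0.5
        for i, (s, r) in enumerate(zip(starts, rev)):
            reads.append(
                AlignedReadRecord(
                    read_id=f"g_{chrom}_{i}",
                    reference=chrom,
                    start=int(s),
                    aligned_span=read_len,
                    is_reverse=bool(r),
                    mapq=mapq,
                    read_length=read_len,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# haplotype construction


@dataclass
class _PlannedInsertion:
    insertion_id: str
    family: str
    context: str  # exonic / intronic / intergenic
    orientation: str | None  # forward / reverse (genic only)
    gene_idx: int | None
    ordinal: int | None  # transcription-order intron ordinal
    distance: int | None
    upstream_margin: int | None
    spliced: bool = False


def _plan_haplotype(cfg: SyntheticConfig, rng: np.random.Generator, hap: str):
    """Draw gene skeletons, expression, and the insertion plan for one haplotype."""
    n_genes = cfg.n_genes
    skeletons = []
    for gi in range(n_genes):
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(*cfg.exon_len_range, size=n_ex).tolist()
        intron_lens = rng.integers(*cfg.intron_len_range, size=n_ex - 1).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        skeletons.append(
            {"n_ex": n_ex, "exon_lens": exon_lens, "intron_lens": intron_lens, "strand": strand}
        )
    expression = np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma, n_genes))

    n_genic = cfg.n_forward_intronic + cfg.n_reverse_intronic + cfg.n_exonic
    if n_genic > n_genes:
        raise ValueError("insertions exceed available genes (infeasible geometry)")
    probs = expression / expression.sum()
    hosts = rng.choice(n_genes, size=n_genic, replace=False, p=probs)
    fwd_hosts = hosts[: cfg.n_forward_intronic]
    rev_hosts = hosts[cfg.n_forward_intronic : cfg.n_forward_intronic + cfg.n_reverse_intronic]
    ex_hosts = hosts[cfg.n_forward_intronic + cfg.n_reverse_intronic :]

    fam = cfg.primary_family
    plans: list[_PlannedInsertion] = []
    distances, spliced = sample_splicing_distances(
        cfg.n_forward_intronic, cfg, seed=rng.integers(0, 2**31)
    )
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{hap}_ins{counter:04d}"

    for k, gidx in enumerate(fwd_hosts):
        sk = skeletons[gidx]
        ordinal = min(int(rng.geometric(cfg.ordinal_geometric_p)), sk["n_ex"] - 1)
        plans.append(
            _PlannedInsertion(
                next_id(), fam, "intronic", "forward", int(gidx), ordinal,
                int(distances[k]), int(rng.integers(*cfg.upstream_margin_range)),
                bool(spliced[k]),
            )
        )
    rev_d, _ = sample_splicing_distances(
        cfg.n_reverse_intronic, cfg, seed=rng.integers(0, 2**31)
    )
    for k, gidx in enumerate(rev_hosts):
        sk = skeletons[gidx]
        ordinal = min(int(rng.geometric(cfg.ordinal_geometric_p)), sk["n_ex"] - 1)
        plans.append(
            _PlannedInsertion(
                next_id(), fam, "intronic", "reverse", int(gidx), ordinal,
                int(rev_d[k]), int(rng.integers(*cfg.upstream_margin_range)), False,
            )
        )
    for gidx in ex_hosts:
        plans.append(
            _PlannedInsertion(next_id(), fam, "exonic",
                              "forward" if rng.random() < 0.5 else "reverse",
                              int(gidx), None, None, None, False)
        )
    for _ in range(cfg.n_intergenic):
        plans.append(
            _PlannedInsertion(next_id(), fam, "intergenic", None, None, None, None, None, False)
        )
    for _ in range(cfg.n_intergenic_secondary):
        plans.append(
            _PlannedInsertion(next_id(), cfg.secondary_family, "intergenic",
                              None, None, None, None, None, False)
        )
    return skeletons, expression, plans


def _build_haplotype(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    hap: str,
    consensus: Mapping[str, str],
    skeletons,
    plans: list[_PlannedInsertion],
):
    """Assemble one haplotype chromosome, returning sequence + annotations."""
    chrom = f"{hap}_chr1"
    at = cfg.at_rich_prob
    at_probs = np.array([at, 0.5 - at, 0.5 - at, at])

    by_gene: dict[int, list[_PlannedInsertion]] = {}
    intergenic_plans = []
    for p in plans:
        if p.gene_idx is not None:
            by_gene.setdefault(p.gene_idx, []).append(p)
        else:
            intergenic_plans.append(p)

    segments: list[str] = []
    cursor = 0
    genes: list[Gene] = []
    insertions: list[TEInsertion] = []
    arrays: list[dict] = []
    truth_rows: list[dict] = []
    hybrid_txs: list[TranscriptModel] = []
    canonical_txs: list[TranscriptModel] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        segments.append(seq)
        s = cursor
        cursor += len(seq)
        return s, cursor

    def te_sequence(fam: str, strand: str) -> str:
        seq = consensus[fam]
        return seq if strand == "+" else _revcomp(seq)

    def place_te(plan: _PlannedInsertion, strand: str, flank_at_rich: bool):
        """Emit a TE at the current cursor; record insertion, array, truth."""
        fam = plan.family
        te_len = len(consensus[fam])
        s, e = emit(te_sequence(fam, strand))
        iv = GenomicInterval(chrom, s, e, strand)
        insertions.append(
            TEInsertion(plan.insertion_id, fam, iv, cons_span=(0, te_len))
        )
        L = int(rng.integers(*cfg.array_len_range))
        u = float(rng.beta(*cfg.array_beta))
        a_start = max(0, s - int(round(u * L)))
        arrays.append(
            {"hap": hap, "chrom": chrom, "start": a_start, "end": a_start + L, "u": u}
        )
        return iv

    # intergenic plans are distributed over the first spacers
    intergenic_iter = iter(intergenic_plans)

    n_genes = len(skeletons)
    for gidx in range(n_genes):
        sk = skeletons[gidx]
        # spacer before the gene (may host one intergenic TE)
        sp_len = int(rng.integers(*cfg.spacer_len_range))
        plan = next(intergenic_iter, None)
        if plan is not None:
            left = sp_len // 2
            emit(_random_seq(rng, left, at_probs))
            iv = place_te(plan, "+" if rng.random() < 0.5 else "-", True)
            emit(_random_seq(rng, sp_len - left, at_probs))
            truth_rows.append(
                {
                    "insertion_id": plan.insertion_id, "hap": hap, "chrom": chrom,
                    "start": iv.start, "end": iv.end, "strand": iv.strand,
                    "family": plan.family, "context": "intergenic",
                    "orientation": "not-applicable", "host_gene": None,
                    "intron_ordinal": None, "distance_downstream": None,
                    "spliced": False,
                }
            )
        else:
            emit(_random_seq(rng, sp_len))

        gene_id = f"{hap}_g{gidx:04d}"
        strand = sk["strand"]
        n_ex = sk["n_ex"]
        gene_plans = by_gene.get(gidx, [])
        intronic_plan = next((p for p in gene_plans if p.context == "intronic"), None)
        exonic_plan = next((p for p in gene_plans if p.context == "exonic"), None)

        # genomic intron index hosting the intronic TE
        host_gi = None
        if intronic_plan is not None:
            o = intronic_plan.ordinal
            host_gi = o - 1 if strand == "+" else (n_ex - 1) - o

        exon_coords: list[tuple[int, int]] = []
        te_iv: GenomicInterval | None = None
        for ei in range(n_ex):
            if exonic_plan is not None and ei == n_ex // 2:
                # exon containing an exonic TE: flank + TE + flank, all exon
                f1 = int(rng.integers(80, 150))
                f2 = int(rng.integers(80, 150))
                es, _ = emit(_random_seq(rng, f1))
                te_strand = strand if exonic_plan.orientation == "forward" else (
                    "-" if strand == "+" else "+"
                )
                ex_iv = place_te(exonic_plan, te_strand, False)
                _, ee = emit(_random_seq(rng, f2))
                exon_coords.append((es, ee))
                truth_rows.append(
                    {
                        "insertion_id": exonic_plan.insertion_id, "hap": hap,
                        "chrom": chrom, "start": ex_iv.start, "end": ex_iv.end,
                        "strand": ex_iv.strand, "family": exonic_plan.family,
                        "context": "exonic", "orientation": exonic_plan.orientation,
                        "host_gene": gene_id, "intron_ordinal": None,
                        "distance_downstream": None, "spliced": False,
                    }
                )
            else:
                es, ee = emit(_random_seq(rng, int(sk["exon_lens"][ei])))
                exon_coords.append((es, ee))
            if ei == n_ex - 1:
                break
            # intron ei
            if host_gi is not None and ei == host_gi:
                p = intronic_plan
                d, u0 = p.distance, p.upstream_margin
                te_strand = strand if p.orientation == "forward" else (
                    "-" if strand == "+" else "+"
                )
                if strand == "+":
                    emit(_random_seq(rng, u0, at_probs))
                    te_iv = place_te(p, te_strand, True)
                    emit(_random_seq(rng, d, at_probs))
                else:
                    emit(_random_seq(rng, d, at_probs))
                    te_iv = place_te(p, te_strand, True)
                    emit(_random_seq(rng, u0, at_probs))
                truth_rows.append(
                    {
                        "insertion_id": p.insertion_id, "hap": hap, "chrom": chrom,
                        "start": te_iv.start, "end": te_iv.end, "strand": te_iv.strand,
                        "family": p.family, "context": "intronic",
                        "orientation": p.orientation, "host_gene": gene_id,
                        "intron_ordinal": p.ordinal,
                        "distance_downstream": d if p.orientation == "forward" else None,
                        "spliced": p.spliced,
                    }
                )
            else:
                emit(_random_seq(rng, int(sk["intron_lens"][ei])))

        tx = TranscriptModel(f"{gene_id}_t1", chrom, strand, exon_coords, gene_id=gene_id)
        gene = Gene(gene_id, chrom, strand, [tx])
        genes.append(gene)
        canonical_txs.append(
            TranscriptModel(f"{gene_id}_read1", chrom, strand, exon_coords)
        )

        # hybrid transcripts for the spliced forward intronic insertion
        if (
            intronic_plan is not None
            and intronic_plan.orientation == "forward"
            and intronic_plan.spliced
            and te_iv is not None
        ):
            famcfg = cfg.te_families[intronic_plan.family]
            for r in range(cfg.hybrid_support):
                if strand == "+":
                    tss = te_iv.start + famcfg.tss_offset
                    donor = te_iv.start + famcfg.ltr_len + famcfg.donor_offset
                    first_exon = (tss, donor)
                    rest = [ex for ex in exon_coords if ex[0] >= te_iv.end]
                    hx = [first_exon] + rest
                else:
                    tss = te_iv.end - 1 - famcfg.tss_offset
                    donor = te_iv.end - 1 - famcfg.ltr_len - famcfg.donor_offset
                    first_exon = (donor + 1, tss + 1)
                    rest = [ex for ex in exon_coords if ex[1] <= te_iv.start]
                    hx = rest + [first_exon]
                hybrid_txs.append(
                    TranscriptModel(
                        f"{intronic_plan.insertion_id}_hybrid{r + 1}", chrom, strand, hx
                    )
                )

    # trailing spacer
    emit(_random_seq(rng, int(rng.integers(*cfg.spacer_len_range))))
    sequence = "".join(segments)

    # independent cluster chromosome (no genes, no TEs)
    cluster_chrom = f"{hap}_cluster"
    cluster_seq = _random_seq(rng, cfg.cluster_len)

    return {
        "chrom": chrom,
        "sequence": sequence,
        "cluster_chrom": cluster_chrom,
        "cluster_seq": cluster_seq,
        "genes": genes,
        "insertions": insertions,
        "canonical": canonical_txs,
        "hybrid": hybrid_txs,
        "arrays": arrays,
        "truth_rows": truth_rows,
    }


def _build_atac_track(
    cfg: SyntheticConfig,
    chrom_lengths: Mapping[str, int],
    insertions: Sequence[TEInsertion],
) -> CoverageTrack:
    """Constant background plus a triangular peak offset upstream of each
    insertion's 5' junction (orientation-aware)."""
    b = cfg.atac_bin
    track = CoverageTrack()
    for chrom, length in chrom_lengths.items():
        n_bins = math.ceil(length / b)
        vals = np.full(n_bins, cfg.atac_background)
        for ins in insertions:
            if ins.interval.chrom != chrom:
                continue
            if ins.interval.strand == "-":
                site = ins.interval.end - 1
                center = site - cfg.atac_peak_offset
            else:
                site = ins.interval.start
                center = site + cfg.atac_peak_offset
            hw = cfg.atac_peak_half_width
            lo = max(0, (center - hw) // b)
            hi = min(n_bins, (center + hw) // b + 1)
            for k in range(lo, hi):
                mid = k * b + b // 2
                h = cfg.atac_peak_height * max(0.0, 1.0 - abs(mid - center) / hw)
                vals[k] = max(vals[k], cfg.atac_background + h)
        # run-length encode
        i = 0
        while i < n_bins:
            j = i
            while j + 1 < n_bins and vals[j + 1] == vals[i]:
                j += 1
            track.add(chrom, i * b, min((j + 1) * b, length), float(vals[i]))
            i = j + 1
    return track


def _build_cluster_paf(
    cfg: SyntheticConfig, rng: np.random.Generator, hap_q: str, hap_t: str
) -> tuple[list[AlignmentBlock], list[tuple[int, int]]]:
    """Syntenic tiling of the cluster chromosome with planted rearranged
    intervals inside the designated region on the target haplotype."""
    rs, re_ = cfg.cluster_region
    region_len = re_ - rs
    total_bad = int(round(cfg.cluster_nonsyntenic_fraction * region_len))
    k = cfg.cluster_n_rearranged
    cuts = np.sort(rng.choice(np.arange(1, total_bad), size=k - 1, replace=False))
    lens = np.diff(np.concatenate([[0], cuts, [total_bad]])).astype(int)
    gap_total = region_len - total_bad
    gcuts = np.sort(rng.choice(np.arange(1, gap_total), size=k, replace=False))
    gaps = np.diff(np.concatenate([[0], gcuts, [gap_total]])).astype(int)
    rearranged: list[tuple[int, int]] = []
    pos = rs
    for i in range(k):
        pos += int(gaps[i])
        rearranged.append((pos, pos + int(lens[i])))
        pos += int(lens[i])
    qc, tc = f"{hap_q}_cluster", f"{hap_t}_cluster"
    blocks: list[AlignmentBlock] = []
    syn_points = [0] + [x for iv in rearranged for x in iv] + [cfg.cluster_len]
    for a, b in zip(syn_points[::2], syn_points[1::2]):
        if b > a:
            blocks.append(
                AlignmentBlock(
                    GenomicInterval(qc, a, b), GenomicInterval(tc, a, b),
                    "+", "syntenic",
                )
            )
    for s, e in rearranged:
        blocks.append(
            AlignmentBlock(
                GenomicInterval(qc, s, e), GenomicInterval(tc, s, e),
                "-", "rearranged",
            )
        )
    return blocks, rearranged


def _smallrna_records(
    cfg: SyntheticConfig, rng: np.random.Generator, library: str,
    consensus: Mapping[str, str],
) -> list[AlignedReadRecord]:
    fracs = cfg.smallrna_libraries[library]
    records: list[AlignedReadRecord] = []
    for fam in sorted(fracs):
        clen = len(consensus[fam])
        f = fracs[fam]
        n = cfg.smallrna_reads_per_family
        lens = rng.integers(cfg.smallrna_len_range[0], cfg.smallrna_len_range[1] + 1, n)
        starts = rng.integers(0, clen - cfg.smallrna_len_range[1], n)
        sense = rng.random(n) < f
        for i in range(n):
            records.append(
                AlignedReadRecord(
                    read_id=f"{library}_{fam}_{i}",
                    reference=fam,
                    start=int(starts[i]),
                    aligned_span=int(lens[i]),
                    is_reverse=not bool(sense[i]),
                    mapq=42,
                    read_length=int(lens[i]),
                )
            )
    return records


def generate_dataset(
    out_dir: str | os.PathLike,
    seed: int,
    config: SyntheticConfig | None = None,
) -> SyntheticDataset:
    """Generate the full synthetic bundle under ``out_dir``.

    Emits per haplotype a FASTA, GFF3 gene models, a RepeatMasker-style
    ``.out``, BED12 transcript models and an accessibility bedGraph, plus
    consensus FASTA, two small-RNA SAM libraries, an expression TSV, a
    cluster-chromosome PAF and a ``truth.json`` recording every planted
    feature.  Identical seeds give byte-identical bundles.
    """
    cfg = config or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # feasibility check before writing anything
    n_genic = cfg.n_forward_intronic + cfg.n_reverse_intronic + cfg.n_exonic
    if n_genic > cfg.n_genes:
        raise ValueError("insertions exceed available genes (infeasible geometry)")
    min_introns = cfg.exon_count_range[0] - 1
    if min_introns < 1:
        raise ValueError("genes need at least 2 exons to host intronic insertions")

    consensus = {
        fam: make_consensus(fam, fc, seed) for fam, fc in sorted(cfg.te_families.items())
    }

    genes: dict[str, list[Gene]] = {}
    insertions: dict[str, list[TEInsertion]] = {}
    transcripts: dict[str, list[TranscriptModel]] = {}
    chrom_lengths: dict[str, dict[str, int]] = {}
    atac_tracks: dict[str, CoverageTrack] = {}
    truth_rows: list[dict] = []
    arrays: list[dict] = []
    hybrid_ids: list[str] = []
    canonical_ids: list[str] = []
    expression_all: dict[str, float] = {}
    paths: dict[str, Path] = {}

    for hidx, hap in enumerate(cfg.haplotypes):
        rng = np.random.default_rng([seed, 10 + hidx])
        skeletons, expression, plans = _plan_haplotype(cfg, rng, hap)
        built = _build_haplotype(cfg, rng, hap, consensus, skeletons, plans)
        genes[hap] = built["genes"]
        insertions[hap] = built["insertions"]
        transcripts[hap] = built["canonical"] + built["hybrid"]
        hybrid_ids += [t.transcript_id for t in built["hybrid"]]
        canonical_ids += [t.transcript_id for t in built["canonical"]]
        truth_rows += built["truth_rows"]
        arrays += built["arrays"]
        chrom_lengths[hap] = {
            built["chrom"]: len(built["sequence"]),
            built["cluster_chrom"]: len(built["cluster_seq"]),
        }
        for g, e in zip(built["genes"], expression):
            expression_all[g.gene_id] = float(e)

        fasta_path = out / f"{hap}.fasta"
        io_formats.write_fasta(
            fasta_path,
            {built["chrom"]: built["sequence"], built["cluster_chrom"]: built["cluster_seq"]},
        )
        paths[f"{hap}_fasta"] = fasta_path
        gff_path = out / f"{hap}.genes.gff3"
        io_formats.write_gff3_genes(gff_path, built["genes"])
        paths[f"{hap}_gff3"] = gff_path
        rm_path = out / f"{hap}.te.out"
        rm_sorted = sorted(
            built["insertions"], key=lambda r: (r.interval.chrom, r.interval.start)
        )
        io_formats.write_repeatmasker_out(rm_path, rm_sorted)
        paths[f"{hap}_te_out"] = rm_path
        bed_path = out / f"{hap}.transcripts.bed12"
        io_formats.write_bed12(bed_path, transcripts[hap])
        paths[f"{hap}_bed12"] = bed_path

        track = _build_atac_track(cfg, chrom_lengths[hap], built["insertions"])
        atac_tracks[hap] = track
        atac_path = out / f"{hap}.atac.bedgraph"
        io_formats.write_bedgraph(atac_path, track)
        paths[f"{hap}_atac"] = atac_path

    cons_path = out / "te_consensus.fasta"
    io_formats.write_fasta(cons_path, consensus)
    paths["consensus_fasta"] = cons_path

    for lib in sorted(cfg.smallrna_libraries):
        rng = np.random.default_rng([seed, 100 + sorted(cfg.smallrna_libraries).index(lib)])
        records = _smallrna_records(cfg, rng, lib, consensus)
        sam_path = out / f"smallrna_{lib}.sam"
        io_formats.write_sam(
            sam_path, records, {fam: len(s) for fam, s in consensus.items()}
        )
        paths[f"smallrna_{lib}"] = sam_path

    expr_path = out / "expression.tsv"
    io_formats.write_expression_tsv(expr_path, expression_all)
    paths["expression"] = expr_path

    rng_paf = np.random.default_rng([seed, 200])
    hap_q, hap_t = cfg.haplotypes[-1], cfg.haplotypes[0]
    blocks, rearranged = _build_cluster_paf(cfg, rng_paf, hap_q, hap_t)
    main_q = f"{hap_q}_chr1"
    main_t = f"{hap_t}_chr1"
    blocks.insert(
        0,
        AlignmentBlock(
            GenomicInterval(main_q, 0, chrom_lengths[hap_q][main_q]),
            GenomicInterval(main_t, 0, chrom_lengths[hap_t][main_t]),
            "+",
            "syntenic",
        ),
    )
    paf_path = out / f"{hap_q}_vs_{hap_t}.paf"
    io_formats.write_paf(
        paf_path,
        blocks,
        query_lengths=chrom_lengths[hap_q],
        target_lengths=chrom_lengths[hap_t],
    )
    paths["paf"] = paf_path

    rs, re_ = cfg.cluster_region
    bad = sum(e - s for s, e in rearranged)
    truth = {
        "seed": seed,
        "insertions": truth_rows,
        "donor_offsets": {fam: fc.donor_offset for fam, fc in cfg.te_families.items()},
        "donor_patterns": {fam: fc.donor_pattern for fam, fc in cfg.te_families.items()},
        "ltr_lengths": {fam: fc.ltr_len for fam, fc in cfg.te_families.items()},
        "consensus_lengths": {fam: len(s) for fam, s in consensus.items()},
        "sense_fractions": cfg.smallrna_libraries,
        "smallrna_reads_per_family": cfg.smallrna_reads_per_family,
        "atac_peak_offset": cfg.atac_peak_offset,
        "atac_peak_height": cfg.atac_peak_height,
        "atac_background": cfg.atac_background,
        "arrays": arrays,
        "array_beta": list(cfg.array_beta),
        "hybrid_transcripts": hybrid_ids,
        "canonical_transcripts": canonical_ids,
        "cluster": {
            "target_chrom": f"{hap_t}_cluster",
            "region": [rs, re_],
            "rearranged": [list(iv) for iv in rearranged],
            "nonsyntenic_pct": 100.0 * bad / (re_ - rs),
        },
        "chrom_lengths": chrom_lengths,
        "expression": expression_all,
    }
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path

    return SyntheticDataset(
        config=cfg,
        seed=seed,
        out_dir=out,
        paths=paths,
        truth=truth,
        genes=genes,
        insertions=insertions,
        transcripts=transcripts,
        chrom_lengths=chrom_lengths,
        consensus=consensus,
        atac_tracks=atac_tracks,
        paf_blocks=blocks,
    )


# ---------------------------------------------------------------------------
# the flagship single-locus fixture


@dataclass
class L3Fixture:
    """A minimal locus: a 4-exon gene with a forward TE in intron 3, one
    hybrid transcript that skips exons 1-3, and one canonical transcript."""

    gene: Gene
    insertion: TEInsertion
    te_consensus: str
    ltr_end: int
    donor_offset: int
    hybrid_transcript: TranscriptModel
    canonical_transcript: TranscriptModel
    distance_downstream: int
    sequence: str


def make_l3_fixture(seed: int = 7) -> L3Fixture:
    """Deterministic fixture mirroring the flagship intronic-TE case."""
    cfg = TEFamilyConfig(7546, 405, "GTAAGTG", 43)
    cons = make_consensus("Springer", cfg, seed)
    rng = np.random.default_rng([seed, 999])
    chrom = "fixture_chr"
    exon_len, intron_len = 200, 1500
    u0, d = 600, 900  # intron 3: margin + TE + remainder
    cursor = 500  # leading spacer
    pieces = [_random_seq(rng, cursor)]
    exons = []
    te_iv = None
    for ei in range(4):
        exons.append((cursor, cursor + exon_len))
        pieces.append(_random_seq(rng, exon_len))
        cursor += exon_len
        if ei == 2:
            pieces.append(_random_seq(rng, u0))
            cursor += u0
            te_iv = GenomicInterval(chrom, cursor, cursor + len(cons), "+")
            pieces.append(cons)
            cursor += len(cons)
            pieces.append(_random_seq(rng, d))
            cursor += d
        elif ei < 3:
            pieces.append(_random_seq(rng, intron_len))
            cursor += intron_len
    pieces.append(_random_seq(rng, 500))
    sequence = "".join(pieces)

    tx = TranscriptModel("l3_host_t1", chrom, "+", exons, gene_id="l3_host")
    gene = Gene("l3_host", chrom, "+", [tx])
    insertion = TEInsertion("l3_te", "Springer", te_iv, cons_span=(0, len(cons)))
    tss = te_iv.start + cfg.tss_offset
    donor = te_iv.start + cfg.ltr_len + cfg.donor_offset
    hybrid = TranscriptModel(
        "l3_hybrid_read", chrom, "+", [(tss, donor), exons[3]]
    )
    canonical = TranscriptModel("l3_canonical_read", chrom, "+", exons)
    return L3Fixture(
        gene=gene,
        insertion=insertion,
        te_consensus=cons,
        ltr_end=cfg.ltr_len,
        donor_offset=cfg.donor_offset,
        hybrid_transcript=hybrid,
        canonical_transcript=canonical,
        distance_downstream=d,
        sequence=sequence,
    )
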
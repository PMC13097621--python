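# Methods

## Insertion-context model

A TE insertion is classified against gene models built from GFF3
(gene → mRNA → exon). *Exonic* means ≥ 1 bp of overlap with any exon of any
isoform of an overlapping gene; *intronic* means inside a gene span without
touching an exon; everything else is *intergenic*. Exonic takes priority
over intronic, so the three categories are mutually exclusive and
exhaustive. Orientation is *forward* when the insertion strand equals the
host-gene strand; intergenic insertions carry no orientation rather than a
strand guess.

Intron ordinals are 1-based in transcription order and are computed on the
isoform with the most exons (ties broken by transcript id), at the insertion
midpoint. Annotations rarely state which isoform defines "first intron";
fixing the most-exon isoform makes the ordinal deterministic and maximally
granular. When several genes overlap an insertion, the primary call goes to
the gene whose exon is hit, else to the gene with the shortest enclosing
intron (ties by lexicographic gene id), and an ambiguity flag is always set.

The distance covariate for forward intronic (intF) insertions is measured
from the insertion's 3′ end (in gene orientation) to the **start** of the
nearest downstream exon; minus-strand genes are handled mirror-symmetrically
so that reverse-complementing a locus leaves the distance unchanged. A
`boundary="end"` switch measures to the exon's 3′ boundary instead — both
conventions circulate, and the difference is one exon length.

Full-length filtering retains copies with genomic length ≥ a minimum length
and/or ≥ a fraction of the family consensus (both bounds inclusive). For
*Springer* (7,546-nt consensus) the operative values are ≥ 7,500 nt,
i.e. ≥ 99.5 %.

RepeatMasker `.out` rows are taken at face value by default (raw row
counts). An optional `merge_gap` merges same-family, same-strand rows
separated by < gap bases with compatible (monotone) consensus coordinates,
for annotations where LTR copies are reported fragmented.

## Hybrid-splice calling

From genome-anchored exon chains (long-read transcript models in BED12), an
event for an intF insertion requires:

1. the transcript 5′ end inside the insertion interval (transcription
   initiates within the 5′ LTR; a relaxed mode accepts any transcript whose
   first exon overlaps the TE);
2. the first splice junction's donor base inside the insertion and its
   acceptor at the 5′ boundary of an annotated host exon within a tolerance
   (default 5 nt, absorbing long-read end wobble);
3. transcript direction equal to host-gene direction.

Skipped exons are the annotated exons 5′ of the acceptor exon. One insertion
may yield several events (distinct transcripts); the per-insertion verdict
"hybrid splicing: yes" requires ≥ 1 supporting transcript (`min_support`
configurable). Donor motifs on a consensus are found by IUPAC scan
(`GTAAGT` by default; the weak copia-type donor `GTATGTT` uses the same
scanner with a different pattern — no donor-strength score is modelled) and
reported as offsets downstream of the 5′ LTR end.

## Mann–Whitney U

U = R₁ − n₁(n₁+1)/2 with midranks for ties. The two-sided p-value uses
exact enumeration of the tie-free null distribution (classic two-index
count recurrence) when n₁·n₂ ≤ 400 and the pooled data have no ties, with
p = min(1, 2·min(P(U ≤ u), P(U ≥ u))); otherwise a normal approximation
with tie-corrected variance
n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction — the
common default of mainstream implementations. When the variance is zero
(all values tied) p = 1. The exact path is verified in tests against full
permutation enumeration and an independent reference implementation.

## piRNA quantification

Reads are size-filtered to 20–35 nt inclusive, then counted once per read
(primary alignments only; multi-mapping is assumed collapsed upstream, e.g.
by `-k 1` mapping) as sense (forward flag) or antisense (reverse flag) per
consensus feature. CPM = 10⁶·count/denominator. The default denominator is
the size-filtered library (reads per million mapped reads); a
consensus-mapped denominator can be supplied instead where a tool chain
normalises against consensus-aligned totals. A family is "sense-biased" at
sense fraction ≥ 50 % (configurable; no standard cutoff exists).
Per-position coverage increments every aligned base on the matching strand
and scales by 10⁶/denominator; alignments running past the consensus end
are clipped and logged.

## PWM scanning

Scores are log₂(p/background) summed over the window against a 0-order
background (estimated from the scanned sequence unless supplied; zero
background for a base present in the sequence is an error — use
pseudocounts). P-values come from the exact distribution of discretised
scores under the background, computed by dynamic programming with a
discretisation step of 10⁻³ bits (score error bound w·step/2; at w = 7 the
reported p at the 10⁻³ threshold moves by far less than 1 %). Windows
containing N are skipped. Reverse-strand hits are scanned with the
reverse-complement matrix against the complemented background, which makes
the hit set exactly strand-symmetric. Tests verify the DP equals full 4^w
enumeration for w ≤ 6 and that an exact-match heptamer scores p = 4⁻⁷.

## Metaprofiles and controls

Metaprofiles are reference-point (site-centred): each site contributes one
row of 2·flank/bin bins (defaults ±5 kb, 10-bp bins), values are bin means
of the track with missing data as zero, rows of minus-strand sites are
flipped so negative offsets are always upstream in the site's own
orientation, and the mean profile is the column mean. Replicate profiles
are combined by arithmetic mean. Control sites are midpoints of windows
(default 7,546 nt, one full-length *Springer*) sampled uniformly over
chromosome lengths without overlap checking; the seed is mandatory.

## Genome metrics

Occupancy merges a family's intervals (union) and divides covered bases by
genome length. Enrichment is the ratio of occupancies, or of full-length
copy counts (`copy_number` mode) — both modes are first-class because both
conventions are used in practice; a zero baseline returns inf/nan rather
than raising. Syntenic fraction clips syntenic-class alignment blocks to a
region, unions them, and reports syntenic and non-syntenic percentages
(summing to 100 exactly). A presence call requires reads spanning **both**
TE junctions with ≥ 10 nt anchored on each side (`min_overhang`); requiring
both junctions is the stricter reading of "reads spanning the TE and its
flanking sequences", and a one-junction mode is available for truncated
copies.

## Synthetic data generator

The generator emits an internally consistent two-haplotype bundle whose
statistical structure matches what the downstream stages assume:

- **Genes**: 160 per haplotype; 4–8 exons of 150–300 nt; introns
  0.8–3 kb; random strand; log-normal expression (μ = 1, σ = 1.2 on the log
  scale). Host genes for genic insertions are drawn ∝ expression
  (emulating preferential insertion into active genes), and intron
  ordinals follow a geometric law (p = 0.45) capped at the intron count
  (5′ bias).
- **Insertions** per haplotype: 100 forward intronic, 25 reverse intronic,
  10 exonic, 15 intergenic *Springer*, plus 5 intergenic copia — 310 in
  total, a desk-scale stand-in for the hundreds of insertions a
  RepeatMasker annotation of a cultured-cell genome yields. TE copies are
  the full consensus sequence (7,546 nt for *Springer*, LTR 405 nt, donor
  `GTAAGTG` planted 43 nt past the LTR with spurious donor matches
  scrubbed). The LTR length is a configurable default: only the donor's
  offset from the LTR end is fixed by the biology.
- **Splicing model**: an intF insertion at distance d (nt) from the next
  downstream exon is spliced with probability σ(α − β·log₁₀ d) with
  log₁₀ d ~ N(3.65, 0.5) clipped to [200, 50,000], α = 13.265, β = 3.5.
  These defaults were calibrated once, numerically, so the
  unspliced/spliced median-distance ratio is ≈ 3.6 (group medians
  ≈ 2.6 kb vs ≈ 9.5 kb) and the spliced fraction ≈ 0.6. Spliced
  insertions get one hybrid transcript (5′ end 100 nt into the LTR, first
  exon ending at the donor, then the downstream host exons); every gene
  also gets one canonical transcript.
- **Small RNA**: per-library, per-family sense fractions (OSC-like library:
  Springer 0.90, copia 0.80, gypsy1 0.75, Transpac 0.70, Xanthias 0.65;
  ovary-like library: 0.15–0.30), 10⁴ reads per family, lengths 23–29 nt,
  Bernoulli strand sampling, written as SAM against the consensus set.
- **Accessibility**: constant background 1.0 with a triangular peak
  (height 8, half-width 150 nt) centred 1 kb upstream of each insertion's
  5′ junction, orientation-aware, in 10-bp bedGraph bins.
- **Arrays**: an AT-rich array (2–4 kb, A/T probability 0.35 each in the
  flanks) spans each insertion point, whose relative position in the array
  follows Beta(3, 3) — a central positional bias.
- **Cluster**: a separate 100-kb chromosome per haplotype; PAF blocks tile
  it with 6 planted rearranged (non-syntenic) intervals covering 52.9 % of
  the designated 80-kb region, the remainder syntenic.

All randomness flows from one seed through fixed substream ids, so equal
seeds give byte-identical bundles. What the generator does **not** emulate:
sequence divergence and truncation of TE copies, nested insertions,
read errors (perfect reads only), isoform diversity per gene (one canonical
isoform), alignment ambiguity (reads come pre-assigned), and realistic
intergenic/chromatin structure. Green tests therefore demonstrate that the
measurement chain is correct and calibrated on data with known truth — not
that real annotations, mappers, or assemblies are free of their own
artefacts.

## Degenerate inputs and tie-breaks

Zero-length intervals are unrepresentable; empty call sets, empty test
groups, non-positive CPM denominators, n_bins < 2, flank not a multiple of
the bin size, and infeasible generator geometry raise errors before output
is written. A missing flank hit yields status `unmapped` (not an
exception); a zero enrichment baseline yields inf/nan. Ranking ties break
lexicographically by feature name; intron-ordinal host ties break by gene
id; the lifted insertion point is the floor midpoint of the inner flank
ends (≤ 1 nt from the true point on self-lift).

## Problem sizes

Defaults throughout are desk-scale: 310 planted insertions, ~220
transcripts per haplotype, 10⁴ reads per TE family per library, 200
replicates for the distance-effect check, 2,000 null replicates for the
rank-test size check, 10× depth for presence calls. These sizes make the
full suite and the acceptance script run in well under a minute each while
keeping every statistical check comfortably powered.
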
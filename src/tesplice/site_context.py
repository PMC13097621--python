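"""Sequence and chromatin context of insertion sites.

PWM scanning follows the FIMO approach: a window's log-odds score (bits,
against a 0-order background) gets a p-value from the exact distribution
of scores of background-random sequences, computed by dynamic
programming over a discretised score grid.  Accessibility context is
summarised as site-centred metaprofiles with length-matched random
control windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .io_formats import CoverageTrack

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G

_NEG_INF_BITS = -64.0  # floor for log-odds of zero-probability cells


@dataclass
class PWM:
    """A position weight matrix over {A, C, G, T}.

    ``probs`` has one row per motif position, columns in A, C, G, T
    order; each row sums to 1.  ``background`` is the 0-order model used
    for both the log-odds scores and the p-value null.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM probs must be a (w, 4) array with w >= 1")
        if self.pseudocount:
            self.probs = self.probs + self.pseudocount
            self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background), zero cells floored."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs) - np.log2(self.background)[None, :]
        return np.where(np.isfinite(lo), lo, _NEG_INF_BITS)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, _COMPLEMENT],
            background=self.background[_COMPLEMENT],
        )

    @classmethod
    def from_consensus(cls, consensus: str, background=None) -> "PWM":
        """Exact-match PWM: probability 1 on the consensus base per position."""
        probs = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = 1.0
        kw = {} if background is None else {"background": np.asarray(background)}
        return cls(probs, **kw)

    @classmethod
    def from_meme(cls, path: str) -> "PWM":
        """Read the first motif from a MEME minimal motif file."""
        probs: list[list[float]] = []
        background = None
        with open(path) as fh:
            lines = iter(fh)
            for line in lines:
                stripped = line.strip()
                if stripped.startswith("Background letter frequencies"):
                    freq_line = next(lines).split()
                    background = np.array(
                        [float(freq_line[2 * i + 1]) for i in range(4)]
                    )
                if stripped.startswith("letter-probability matrix"):
                    for row in lines:
                        row = row.strip()
                        if not row or not row[0].isdigit() and row[0] != "0" and row[0] != ".":
                            break
                        probs.append([float(x) for x in row.split()[:4]])
                    break
        if not probs:
            raise ValueError(f"no letter-probability matrix found in {path}")
        kw = {} if background is None else {"background": background}
        return cls(np.array(probs), **kw)

    @classmethod
    def from_probability_tsv(cls, path: str) -> "PWM":
        """Read a 4-column (A C G T) per-position probability TSV."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line[0].isalpha():
                    continue
                rows.append([float(x) for x in line.split()[:4]])
        if not rows:
            raise ValueError(f"no probability rows in {path}")
        return cls(np.array(rows))


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    score: float  # log-odds, bits
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


class _ScoreDistribution:
    """Exact null distribution of discretised PWM scores under the background."""

    def __init__(self, pwm: PWM, step_bits: float = 1e-3):
        if step_bits <= 0:
            raise ValueError("discretisation step must be > 0")
        self.step = step_bits
        lo = pwm.log_odds()
        self.int_scores = np.round(lo / step_bits).astype(np.int64)
        self.error_bound = pwm.width * step_bits / 2.0
        bg = pwm.background
        offset = int(self.int_scores.min(axis=1).sum())
        span = int((self.int_scores.max(axis=1) - self.int_scores.min(axis=1)).sum())
        dist = np.zeros(span + 1)
        dist[0] = 1.0
        cum_min = 0
        for i in range(pwm.width):
            col = self.int_scores[i]
            cmin = int(col.min())
            new = np.zeros_like(dist)
            for b in range(4):
                if bg[b] == 0:
                    continue
                shift = int(col[b]) - cmin
                new[shift:] += dist[: dist.size - shift] * bg[b]
            dist = new
            cum_min += cmin
        self.offset = offset  # integer score of dist[0]
        # survival function: P(score_int >= offset + k)
        self.sf = np.minimum(1.0, dist[::-1].cumsum()[::-1])

    def window_int_score(self, base_indices: np.ndarray) -> int:
        return int(self.int_scores[np.arange(base_indices.size), base_indices].sum())

    def p_value(self, int_score: int) -> float:
        k = int_score - self.offset
        if k <= 0:
            return 1.0
        if k >= self.sf.size:
            return float(self.sf[-1]) if self.sf.size else 1.0
        return float(self.sf[k])


def pwm_scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-3,
    both_strands: bool = True,
    chrom: str = "seq",
    step_bits: float = 1e-3,
) -> list[MotifHit]:
    """Scan a sequence for PWM matches at a p-value threshold.

    Windows containing N are skipped.  P-values come from the exact DP
    distribution of discretised scores (step ``step_bits`` bits); the
    discretisation error bound on any score is width * step / 2.
    Reverse-strand hits are found by scanning with the reverse-complement
    PWM and reported on the same coordinates with strand ``-``.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid symbols {sorted(bad)}")
    present = [b for b in _BASES if b in seq]
    for b in present:
        if pwm.background[_BASE_INDEX[b]] == 0:
            raise ValueError(
                f"background probability of {b} is zero but {b} occurs in the "
                "sequence; supply pseudocounts or a fuller background"
            )
    hits: list[MotifHit] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    w = pwm.width
    codes = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    valid = codes >= 0
    ok_window = (
        np.convolve(valid.astype(int), np.ones(w, dtype=int), mode="valid") == w
        if len(seq) >= w
        else np.zeros(0, dtype=bool)
    )
    for strand, mat in strands:
        dist = _ScoreDistribution(mat, step_bits=step_bits)
        for pos in np.nonzero(ok_window)[0]:
            window = codes[pos : pos + w]
            s_int = dist.window_int_score(window)
            p = dist.p_value(s_int)
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, int(pos), int(pos) + w, strand),
                        score=s_int * dist.step,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


# ---------------------------------------------------------------------------
# insertion position within motif arrays


def insertion_position_in_motif_array(
    insertion_points: Sequence[tuple[str, int]],
    arrays: Sequence[GenomicInterval],
    n_bins: int = 20,
    max_distance: int = 0,
) -> tuple[np.ndarray, list[float], int]:
    """Histogram of insertion positions normalised across their arrays.

    Each insertion point is assigned to the array containing it (or the
    nearest one within ``max_distance``); its position maps to [0, 1]
    across that array.  Returns (bin counts, normalised positions,
    number of unassigned insertions).
    """
    if not arrays:
        raise ValueError("no arrays supplied")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in arrays:
        by_chrom.setdefault(a.chrom, []).append(a)
    positions: list[float] = []
    unassigned = 0
    for chrom, pos in insertion_points:
        best = None
        for a in by_chrom.get(chrom, []):
            if a.start <= pos < a.end:
                dist = 0
            else:
                dist = max(a.start - pos, pos - (a.end - 1))
            if dist <= max_distance and (best is None or dist < best[0]):
                best = (dist, a)
        if best is None:
            unassigned += 1
            continue
        a = best[1]
        u = (pos - a.start) / a.length
        positions.append(min(max(u, 0.0), 1.0 - 1e-12))
    hist, _ = np.histogram(positions, bins=n_bins, range=(0.0, 1.0))
    return hist, positions, unassigned


# ---------------------------------------------------------------------------
# metaprofiles


@dataclass
class CoverageMatrix:
    """Sites x bins signal matrix around a set of anchor points."""

    matrix: np.ndarray
    flank: int
    bin_size: int
    missing_as_zero: bool = True

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[1])

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def bin_centers(self) -> np.ndarray:
        """Offsets (nt) of bin centers relative to the anchor point."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0


def metaprofile(
    sites: Sequence[tuple[str, int, str]],
    track: CoverageTrack,
    flank: int = 5000,
    bin_size: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageMatrix:
    """Site-centred signal matrix: one row per site, 2*flank/bin bins.

    Each row resamples the track into ``bin_size``-nt bins across
    [site - flank, site + flank); positions without data count as zero.
    Rows of minus-strand sites are flipped so that negative offsets are
    always upstream in the site's own orientation.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    n_bins = 2 * flank // bin_size
    dense_cache: dict[str, np.ndarray] = {}
    rows = np.zeros((len(sites), n_bins))
    for r, (chrom, pos, strand) in enumerate(sites):
        if chrom not in dense_cache:
            length = (chrom_lengths or {}).get(chrom)
            dense_cache[chrom] = track.dense(chrom, length)
        arr = dense_cache[chrom]
        window = np.zeros(2 * flank)
        lo, hi = pos - flank, pos + flank
        src_lo, src_hi = max(0, lo), min(arr.size, hi)
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        binned = window.reshape(n_bins, bin_size).mean(axis=1)
        if strand == "-":
            binned = binned[::-1]
        rows[r] = binned
    return CoverageMatrix(rows, flank, bin_size)


def average_profiles(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of per-sample mean profiles (equal weighting)."""
    if not profiles:
        raise ValueError("no profiles")
    stacked = np.vstack(profiles)
    return stacked.mean(axis=0)


def random_control(
    reference_lengths: Mapping[str, int],
    n: int = 200,
    window_len: int = 7546,
    seed: int | None = None,
) -> list[tuple[str, int, str]]:
    """Uniformly sampled control windows, returned as their midpoints.

    Windows of ``window_len`` (default: the length of a full-length
    Springer element) are drawn uniformly over the given chromosome
    lengths without overlap checking; the seed is mandatory for
    reproducibility.
    """
    if seed is None:
        raise ValueError("random_control requires an explicit seed")
    rng = np.random.default_rng(seed)
    chroms = [c for c, ln in reference_lengths.items() if ln >= window_len]
    if not chroms:
        raise ValueError("no chromosome is long enough for the window length")
    lengths = np.array([reference_lengths[c] - window_len + 1 for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    sites = []
    for _ in range(n):
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, reference_lengths[chroms[ci]] - window_len + 1))
        sites.append((chroms[ci], start + window_len // 2, "+"))
    return sites
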
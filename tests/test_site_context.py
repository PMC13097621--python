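"""PWM scanning with exact p-value calibration, motif arrays, metaprofiles."""

import itertools

import numpy as np
import pytest
from scipy import stats as ss

from tesplice.intervals import GenomicInterval
from tesplice.io_formats import CoverageTrack
from tesplice.site_context import (
    PWM,
    _ScoreDistribution,
    insertion_position_in_motif_array,
    metaprofile,
    pwm_scan,
    random_control,
)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPWM:
    def test_width_one_match_probability(self):
        pwm = PWM(np.array([[1.0, 0, 0, 0]]))
        hits = pwm_scan("A", pwm, p_threshold=0.3, both_strands=False)
        assert hits[0].p_value == 0.25

    def test_exact_heptamer_p_value(self):
        pwm = PWM.from_consensus("GTAAGTG")
        hits = pwm_scan("CCGTAAGTGCC", pwm, p_threshold=1e-3, both_strands=True)
        assert len(hits) == 1
        assert hits[0].p_value == pytest.approx(0.25**7)
        assert hits[0].interval == GenomicInterval("seq", 2, 9, "+")

    @pytest.mark.parametrize("w", [2, 4, 6])
    def test_dp_equals_brute_force_enumeration(self, w):
        rng = np.random.default_rng(w)
        pwm = PWM(rng.dirichlet(np.ones(4), size=w))
        dist = _ScoreDistribution(pwm)
        bg = pwm.background
        words = np.array(list(itertools.product(range(4), repeat=w)))
        ints = np.array([dist.window_int_score(word) for word in words])
        probs = np.prod(bg[words], axis=1)
        for s in np.unique(ints):
            brute = probs[ints >= s].sum()
            # identical discretised scores, so agreement is exact up to fp error
            assert dist.p_value(int(s)) == pytest.approx(brute, abs=1e-12)

    def test_p_values_monotone_in_score(self):
        pwm = PWM(np.random.default_rng(0).dirichlet(np.ones(4), size=5))
        dist = _ScoreDistribution(pwm)
        assert np.all(np.diff(dist.sf) <= 1e-15)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        pwm = PWM(rng.dirichlet(np.ones(4) * 2, size=5))
        fwd = pwm_scan(seq, pwm, p_threshold=0.05)
        rc = pwm_scan(_revcomp(seq), pwm, p_threshold=0.05)
        m1 = sorted((h.interval.start, h.interval.strand) for h in fwd)
        m2 = sorted(
            (len(seq) - h.interval.end, "+" if h.interval.strand == "-" else "-")
            for h in rc
        )
        assert m1 == m2

    def test_n_windows_skipped(self):
        pwm = PWM.from_consensus("GTAAGTG")
        hits = pwm_scan("CCGTANGTGCCGTAAGTG", pwm, p_threshold=1e-3)
        assert [h.interval.start for h in hits if h.interval.strand == "+"] == [11]

    def test_zero_background_for_present_base_errors(self):
        pwm = PWM(np.array([[0.5, 0.5, 0.0, 0.0]]), background=np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError, match="pseudo"):
            pwm_scan("GGG", pwm)

    def test_from_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
            "MOTIF test\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            "1.0 0.0 0.0 0.0\n"
            "0.0 0.0 1.0 0.0\n"
        )
        pwm = PWM.from_meme(str(p))
        assert pwm.width == 2
        assert pwm.background[0] == 0.3
        assert pwm.probs[1, 2] == 1.0


class TestMotifArray:
    def test_midpoint_mass(self):
        arrays = [GenomicInterval("c", 0, 1000), GenomicInterval("c", 5000, 7000)]
        points = [("c", 500), ("c", 6000)]
        hist, positions, unassigned = insertion_position_in_motif_array(
            points, arrays, n_bins=10
        )
        assert hist[5] == 2 and hist.sum() == 2
        assert unassigned == 0

    def test_outside_any_array_is_unassigned(self):
        arrays = [GenomicInterval("c", 0, 100)]
        _, _, unassigned = insertion_position_in_motif_array([("c", 500)], arrays)
        assert unassigned == 1

    def test_empty_arrays_error(self):
        with pytest.raises(ValueError):
            insertion_position_in_motif_array([("c", 1)], [])

    def test_beta_law_recovery(self):
        rng = np.random.default_rng(3)
        arrays, points = [], []
        for k in range(500):
            start = k * 10000
            L = int(rng.integers(2000, 4000))
            arrays.append(GenomicInterval("c", start, start + L))
            u = rng.beta(3, 3)
            points.append(("c", start + int(u * L)))
        _, positions, unassigned = insertion_position_in_motif_array(points, arrays)
        assert unassigned == 0
        ks = ss.kstest(positions, ss.beta(3, 3).cdf).statistic
        assert ks < 0.1


class TestMetaprofile:
    def _flat_track(self, value=2.0, length=20000, chrom="c"):
        t = CoverageTrack()
        t.add(chrom, 0, length, value)
        return t

    def test_constant_track(self):
        track = self._flat_track(2.0)
        mat = metaprofile([("c", 10000, "+")], track, flank=1000, bin_size=10,
                          chrom_lengths={"c": 20000})
        assert np.allclose(mat.mean_profile(), 2.0)
        assert mat.n_bins == 200

    def test_planted_peak_offset(self):
        track = self._flat_track(0.0)
        for chrom, pos in [("c", 4900)]:
            track.add(chrom, pos, pos + 10, 5.0)  # delta at -100 from site 5000
        sites = [("c", 5000, "+")]
        mat = metaprofile(sites, track, flank=1000, bin_size=10, chrom_lengths={"c": 20000})
        centers = mat.bin_centers()
        assert centers[mat.mean_profile().argmax()] == pytest.approx(-95.0)

    def test_minus_strand_flip(self):
        track = self._flat_track(0.0)
        track.add("c", 5100, 5110, 5.0)  # +100 genomically = -100 in site orientation
        mat = metaprofile([("c", 5000, "-")], track, flank=1000, bin_size=10,
                          chrom_lengths={"c": 20000})
        centers = mat.bin_centers()
        assert centers[mat.mean_profile().argmax()] < 0

    def test_linearity(self):
        rng = np.random.default_rng(4)
        t1, t2 = CoverageTrack(), CoverageTrack()
        tsum = CoverageTrack()
        for k in range(0, 20000, 100):
            v1, v2 = float(rng.random()), float(rng.random())
            t1.add("c", k, k + 100, v1)
            t2.add("c", k, k + 100, v2)
            tsum.add("c", k, k + 100, v1 + v2)
        sites = [("c", int(p), "+") for p in rng.integers(2000, 18000, 5)]
        kw = dict(flank=1000, bin_size=10, chrom_lengths={"c": 20000})
        m1 = metaprofile(sites, t1, **kw).mean_profile()
        m2 = metaprofile(sites, t2, **kw).mean_profile()
        ms = metaprofile(sites, tsum, **kw).mean_profile()
        assert np.allclose(m1 + m2, ms)

    def test_flank_bin_validation(self):
        with pytest.raises(ValueError):
            metaprofile([], self._flat_track(), flank=1005, bin_size=10)


class TestRandomControl:
    def test_seed_mandatory_and_reproducible(self):
        lengths = {"c1": 100000, "c2": 50000}
        with pytest.raises(ValueError):
            random_control(lengths, n=10, window_len=1000)
        a = random_control(lengths, n=10, window_len=1000, seed=3)
        b = random_control(lengths, n=10, window_len=1000, seed=3)
        assert a == b

    def test_sites_within_bounds(self):
        lengths = {"c1": 100000}
        sites = random_control(lengths, n=200, window_len=7546, seed=1)
        for chrom, pos, strand in sites:
            assert chrom == "c1"
            assert 0 <= pos < 100000

    def test_flat_track_gives_flat_profile(self):
        lengths = {"c1": 500000}
        track = CoverageTrack()
        track.add("c1", 0, 500000, 1.0)
        sites = random_control(lengths, n=200, window_len=7546, seed=2)
        mat = metaprofile(sites, track, flank=5000, bin_size=10, chrom_lengths=lengths)
        prof = mat.mean_profile()
        # edge windows can clip past the chromosome ends (missing = 0)
        inner = prof[prof > 0]
        assert inner.max() / inner.min() < 1.2
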
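"""Direct-repeat detection, ORF/tandem prediction, peaks and distances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poolscan import ConfigError
from poolscan import structvar as sv


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindDirectRepeats:
    def test_identical_planted_copies(self, rng):
        copy = random_seq(rng, 470)
        seq = random_seq(rng, 1000) + copy + random_seq(rng, 5200) + copy + random_seq(rng, 1000)
        pairs = sv.find_direct_repeats(seq)
        assert len(pairs) == 1
        (p,) = pairs
        assert p.internal_length == 5200
        assert p.mismatches == 0 and p.identity_pct == 100.0

    def test_random_sequence_has_no_long_repeats(self, rng):
        assert sv.find_direct_repeats(random_seq(rng, 10_000)) == []

    def test_mismatched_copies_identity(self, rng):
        copy = random_seq(rng, 470)
        other = list(copy)
        for pos in (50, 150, 250, 350):
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        seq = random_seq(rng, 500) + copy + random_seq(rng, 2000) + "".join(other) + random_seq(rng, 500)
        (p,) = sv.find_direct_repeats(seq)
        assert p.mismatches == 4
        assert p.identity_pct == pytest.approx(100 * (1 - 4 / 470))  # ~99.1%

    def test_too_short_sequence_warns_empty(self, rng):
        assert sv.find_direct_repeats("N" * 1000) == []


class TestHammingDivergence:
    def test_ltr_pair_divergence_about_one_percent(self, rng):
        a = random_seq(rng, 470)
        b = list(a)
        for pos in (10, 100, 200, 300):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        mism, pct = sv.hamming_divergence(a, "".join(b))
        assert mism == 4
        assert pct == pytest.approx(100 * 4 / 470)
        assert sv.percent_label(pct) == "1%"

    def test_identical_and_disjoint(self):
        assert sv.hamming_divergence("ACGT", "ACGT") == (0, 0.0)
        assert sv.hamming_divergence("A" * 10, "C" * 10) == (10, 100.0)

    def test_case_insensitive(self):
        assert sv.hamming_divergence("acgt", "ACGT")[0] == 0

    def test_unequal_lengths_instruct_alignment(self):
        with pytest.raises(ConfigError, match="align"):
            sv.hamming_divergence("ACGT", "ACG")


class TestClassifySoloOrigin:
    def test_right_origin(self, rng):
        right = random_seq(rng, 100)
        left = list(right)
        for pos in (5, 20, 40, 60, 80):
            left[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[left[pos]]
        solo = list(right)
        solo[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[solo[50]]
        origin, d_left, d_right = sv.classify_solo_origin("".join(solo), "".join(left), right)
        assert origin == "right"
        assert (d_left, d_right) == (6, 1)

    def test_tie_is_ambiguous(self):
        assert sv.classify_solo_origin("AAAA", "AAAT", "AAAC")[0] == "ambiguous"


def brute_force_orf(seq):
    """All-substrings oracle over both strands: (nt_length, on_plus, -start)."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand, s in (("+", seq.upper()), ("-", sv.reverse_complement(seq.upper()))):
        for i in range(len(s) - 2):
            if s[i:i + 3] != "ATG":
                continue
            for j in range(i + 3, len(s) - 2, 3):
                codon = s[j:j + 3]
                if codon in stops:
                    nt = j + 3 - i
                    cand = (nt, strand == "+", -i)
                    if best is None or cand > best:
                        best = cand
                    break
    return best


SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]


def sense_body(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def embed_orf(rng, n_codons, left=300, right=300):
    """A clean reading frame of ``n_codons`` random sense codons embedded in
    random flanks, with an in-frame stop just upstream so the ORF cannot
    extend."""
    return (random_seq(rng, left) + "TAA" + "ATG" + sense_body(rng, n_codons)
            + "TGA" + random_seq(rng, right))


class TestLongestOrf:
    def test_minimal_orf(self):
        orf = sv.longest_orf("ATGTAA")
        assert (orf.nt_length, orf.aa_length) == (6, 1)

    def test_reported_element_orf_length(self, rng):
        orf = sv.longest_orf(embed_orf(rng, 1179))
        assert orf.nt_length == 3543
        assert orf.aa_length == 1180

    def test_reverse_strand_detection(self, rng):
        plus = "TAA" + "ATG" + sense_body(rng, 80) + "TGA"  # bounded by stops
        seq = random_seq(rng, 300) + sv.reverse_complement(plus) + random_seq(rng, 300)
        orf = sv.longest_orf(seq)
        assert orf.strand == "-"
        assert orf.nt_length == len(plus) - 3

    def test_no_orf(self):
        assert sv.longest_orf("CCCCCCCCCC") is None

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, int(rng.integers(60, 2000)))
        orf = sv.longest_orf(seq)
        expected = brute_force_orf(seq)
        if expected is None:
            assert orf is None
        else:
            assert (orf.nt_length, orf.strand == "+", -orf.start) == expected


class TestTandemRepeats:
    def test_exact_copies(self, rng):
        unit = random_seq(rng, 66)
        seq = random_seq(rng, 200) + unit * 3 + random_seq(rng, 200)
        copies, span = sv.count_tandem_repeats(seq, unit)
        assert copies == 3
        assert span == (200, 200 + 3 * 66)

    def test_absent_unit(self, rng):
        assert sv.count_tandem_repeats("A" * 500, "CGTACGTACG" * 3)[0] == 0

    def test_mismatch_tolerant_copy_counted(self, rng):
        unit = random_seq(rng, 66)
        degraded = list(unit)
        degraded[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[degraded[10]]
        degraded[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[degraded[30]]
        seq = random_seq(rng, 100) + unit * 2 + "".join(degraded) + unit * 2 + random_seq(rng, 100)
        copies, _ = sv.count_tandem_repeats(seq, unit, max_unit_mismatch=6)
        assert copies == 5

    def test_empty_unit_rejected(self):
        with pytest.raises(ConfigError):
            sv.count_tandem_repeats("ACGT", "")


class TestScorePeaks:
    def track(self, pos, scores):
        return sv.ScoreTrack(np.array(pos), np.array(scores))

    def test_no_qualifying_scores(self):
        t = self.track(range(100), [0.1] * 100)
        assert sv.call_score_peaks(t) == []

    def test_runs_within_gap_merge(self):
        t = self.track([10, 11, 411, 412], [0.5, 0.5, 0.9, 0.3])
        peaks = sv.call_score_peaks(t, group_window=500)
        assert peaks == [(10, 413, 0.9)]  # 400 bp gap <= 500 merges

    def test_runs_beyond_gap_split(self):
        t = self.track([10, 11, 611, 612], [0.5, 0.5, 0.9, 0.3])
        peaks = sv.call_score_peaks(t, group_window=500)
        assert [p[:2] for p in peaks] == [(10, 12), (611, 613)]

    def test_bins_mode_flag(self):
        # same seeds, fixed 500-bp bins: positions 10 and 611 are two bins
        # apart (bins 0 and 1 are adjacent, bin 0 and 2 are not... 611 // 500 == 1)
        t = self.track([10, 611, 1600], [0.5, 0.5, 0.5])
        merged = sv.call_score_peaks(t, group_window=500, mode="bins")
        assert [p[:2] for p in merged] == [(10, 612), (1600, 1601)]

    @given(st.lists(st.tuples(st.integers(0, 3000), st.floats(0, 1)),
                    min_size=1, max_size=40, unique_by=lambda t: t[0]))
    def test_peaks_disjoint_and_sorted(self, items):
        items.sort()
        t = self.track([i for i, _ in items], [s for _, s in items])
        peaks = sv.call_score_peaks(t)
        for (s1, e1, _), (s2, e2, _) in zip(peaks, peaks[1:]):
            assert e1 <= s2

    def test_track_validation(self):
        with pytest.raises(ConfigError):
            sv.ScoreTrack(np.array([2, 1]), np.array([0.5, 0.5]))
        with pytest.raises(ConfigError):
            sv.ScoreTrack(np.array([1, 2]), np.array([0.5, 1.5]))


class TestRegulatoryDistance:
    def test_insertion_present(self):
        model = sv.HaplotypeCoordModel(1900, True, 5200, 2150)
        assert sv.regulatory_distance(model) == 9.3

    def test_insertion_absent(self):
        model = sv.HaplotypeCoordModel(1900, False, 5200, 2150)
        assert sv.regulatory_distance(model) == 4.1

    def test_zero_gaps(self):
        assert sv.regulatory_distance(sv.HaplotypeCoordModel(0, False, 0, 0)) == 0.0

    def test_half_up_rounding(self):
        # 1250 bp -> 1.25 kb -> 1.3 (half-up, not banker's)
        assert sv.regulatory_distance(sv.HaplotypeCoordModel(1250, False, 0, 0)) == 1.3

    def test_presence_minus_absence_is_insertion_length(self):
        for gaps in [(1900, 2150), (123, 4567), (0, 1)]:
            present = sv.HaplotypeCoordModel(gaps[0], True, 5200, gaps[1])
            absent = sv.HaplotypeCoordModel(gaps[0], False, 5200, gaps[1])
            total_p = gaps[0] + 5200 + gaps[1]
            total_a = gaps[0] + gaps[1]
            assert total_p - total_a == 5200  # exact, pre-rounding
            assert sv.regulatory_distance(present) >= sv.regulatory_distance(absent)

    def test_negative_gap_rejected(self):
        with pytest.raises(ConfigError):
            sv.HaplotypeCoordModel(-1, True, 5200, 2150)
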
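import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esdeg.motifs import (
    MotifHit,
    PositionCountMatrix,
    encode_sequence,
    filter_motifs,
    information_content,
    parse_motif_library,
    pcm_to_pwm,
    scan_promoter,
    score_window,
    write_motif_library,
)
from esdeg.synthetic import random_pcm

COMPLEMENT = str.maketrans("ACGT", "TGCA")

TWO_MOTIF_LIBRARY = """\
>M1
10 0 0 0
0 10 0 0
0 0 10 0
0 0 0 10
1 2 3 4
>M2
5 5 5 5
1 1 1 17
"""


class TestParseLibrary:
    def test_two_motif_fixture(self, tmp_path):
        path = tmp_path / "lib.pcm"
        path.write_text(TWO_MOTIF_LIBRARY)
        pcms = parse_motif_library(path)
        assert [m.motif_id for m in pcms] == ["M1", "M2"]
        assert [m.length for m in pcms] == [5, 2]
        assert pcms[0].counts[4].tolist() == [1, 2, 3, 4]

    def test_write_then_parse_round_trip(self, tmp_path):
        pcms = [random_pcm(f"R{i}", 6 + i, seed=i) for i in range(3)]
        path = tmp_path / "rt.pcm"
        write_motif_library(pcms, path)
        again = parse_motif_library(path)
        assert [m.motif_id for m in again] == [m.motif_id for m in pcms]
        for a, b in zip(pcms, again):
            np.testing.assert_allclose(a.counts, b.counts, rtol=1e-5)

    def test_ragged_matrix_names_motif(self, tmp_path):
        path = tmp_path / "bad.pcm"
        path.write_text(">BAD\n1 2 3\n")
        with pytest.raises(ValueError, match="BAD"):
            parse_motif_library(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.pcm"
        path.write_text(">NEG\n1 2 -3 4\n")
        with pytest.raises(ValueError, match="negative"):
            parse_motif_library(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pcm"
        path.write_text("")
        with pytest.raises(ValueError, match="no motifs"):
            parse_motif_library(path)

    def test_plain_format(self, tmp_path):
        path = tmp_path / "lib.txt"
        path.write_text("M1\n1 2 3 4\n5 6 7 8\n\nM2\n9 9 9 9\n")
        pcms = parse_motif_library(path, format="plain")
        assert [(m.motif_id, m.length) for m in pcms] == [("M1", 2), ("M2", 1)]


class TestFilterMotifs:
    def test_empty_exclusion_list_is_identity(self):
        pcms = [random_pcm(f"R{i}", 8, seed=i) for i in range(4)]
        assert filter_motifs(pcms, exclude=[]) == pcms

    def test_exclusion_list_drops_named(self):
        pcms = [random_pcm(f"R{i}", 8, seed=i) for i in range(6)]
        kept = filter_motifs(pcms, exclude=["R1", "R4"])
        assert [m.motif_id for m in kept] == ["R0", "R2", "R3", "R5"]

    def test_fallback_rule_drops_short_motif(self):
        short = random_pcm("SHORT", 4, seed=1, concentration=0.05)
        informative = random_pcm("LONG", 10, seed=2, concentration=0.05)
        flat = PositionCountMatrix("FLAT", np.full((8, 4), 25.0))
        assert information_content(flat) < 1e-9
        kept = filter_motifs([short, informative, flat])
        assert [m.motif_id for m in kept] == ["LONG"]


class TestPcmToPwm:
    def test_uniform_column_gives_equal_weights(self):
        pcm = PositionCountMatrix("U", np.array([[1.0, 1.0, 1.0, 1.0]]))
        pwm = pcm_to_pwm(pcm)
        assert np.allclose(pwm.weights[0], pwm.weights[0, 0])

    def test_closed_form_arithmetic(self):
        pcm = PositionCountMatrix("A10", np.array([[10.0, 0.0, 0.0, 0.0]]))
        pwm = pcm_to_pwm(pcm, pseudocount=1.0)
        assert pwm.weights[0, 0] == pytest.approx(math.log(10.25 / 11) - math.log(0.25))
        assert pwm.weights[0, 1] == pytest.approx(math.log(0.25 / 11) - math.log(0.25))

    def test_pseudocount_shrinks_weights(self):
        pcm = random_pcm("S", 8, seed=5, concentration=0.2)
        small = pcm_to_pwm(pcm, pseudocount=0.5)
        large = pcm_to_pwm(pcm, pseudocount=50.0)
        assert np.all(np.abs(large.weights) <= np.abs(small.weights) + 1e-12)

    def test_invalid_background_rejected(self):
        pcm = random_pcm("B", 6, seed=1)
        with pytest.raises(ValueError):
            pcm_to_pwm(pcm, background=(0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ValueError):
            pcm_to_pwm(pcm, background=(0.4, 0.4, 0.4, 0.4))


class TestScoring:
    def test_zero_weights_score_zero(self, consensus_pcm):
        pwm = pcm_to_pwm(consensus_pcm)
        zero = pwm.__class__("Z", np.zeros((4, 4)), pwm.background, 1.0)
        assert score_window(zero, "ACGT") == 0.0

    def test_consensus_attains_max_score(self, consensus_pwm):
        assert score_window(consensus_pwm, "ACGTGA") == pytest.approx(
            consensus_pwm.max_score
        )

    def test_length_mismatch_rejected(self, consensus_pwm):
        with pytest.raises(ValueError, match="length"):
            score_window(consensus_pwm, "ACGT")

    def test_n_window_scores_minus_inf(self, consensus_pwm):
        assert score_window(consensus_pwm, "ACGNGA") == -np.inf

    def test_matches_positionwise_sum_oracle(self, random_pwm):
        rng = np.random.default_rng(8)
        for _ in range(20):
            window = "".join(rng.choice(list("ACGT"), size=random_pwm.length))
            expected = sum(
                random_pwm.weights[i, "ACGT".index(b)] for i, b in enumerate(window)
            )
            assert score_window(random_pwm, window) == pytest.approx(expected)


class TestScan:
    def test_threshold_above_max_gives_empty(self, consensus_pwm, promoter_factory):
        promoter = promoter_factory("g", "ACGTGA" * 5)
        assert scan_promoter(consensus_pwm, promoter, consensus_pwm.max_score + 1) == []

    def test_palindromic_motif_hits_both_strands(self, promoter_factory):
        # CACGTG E-box is its own reverse complement
        counts = np.full((6, 4), 1.0)
        for i, base in enumerate("CACGTG"):
            counts[i, "ACGT".index(base)] = 97.0
        pwm = pcm_to_pwm(PositionCountMatrix("EBOX", counts))
        promoter = promoter_factory("g", "TTTCACGTGTTT")
        hits = scan_promoter(pwm, promoter, pwm.max_score - 1e-9)
        assert [(h.offset, h.strand) for h in hits] == [(3, "+"), (3, "-")]

    def test_exhaustive_enumeration_oracle(self, random_pwm):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        L = random_pwm.length
        threshold = 0.0
        expected = []
        for offset in range(30 - L + 1):
            window = seq[offset : offset + L]
            for strand, w in (("+", window), ("-", w_rc(window))):
                s = score_window(random_pwm, w)
                if s >= threshold:
                    expected.append((offset, strand, pytest.approx(s)))
        hits = scan_promoter(random_pwm, ("g", seq), threshold)
        assert [(h.offset, h.strand, h.score) for h in hits] == expected

    def test_short_promoter_gives_empty(self, random_pwm):
        assert scan_promoter(random_pwm, ("g", "ACG"), -100.0) == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=40), st.integers(0, 10_000))
    def test_revcomp_strand_swap_preserves_scores(self, seq, seed):
        pwm = pcm_to_pwm(random_pcm("P", 6, seed=seed, concentration=0.3))
        fwd = scan_promoter(pwm, ("g", seq), -np.inf)
        rev = scan_promoter(pwm, ("g", w_rc(seq)), -np.inf)
        np.testing.assert_allclose(
            sorted(h.score for h in fwd), sorted(h.score for h in rev), atol=1e-9
        )

    def test_hit_count_non_increasing_in_threshold(self, random_pwm):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        counts = [
            len(scan_promoter(random_pwm, ("g", seq), t)) for t in (-5.0, 0.0, 3.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_score_exceeds_cached_max(self, random_pwm):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        hits = scan_promoter(random_pwm, ("g", seq), -np.inf)
        assert all(h.score <= random_pwm.max_score + 1e-12 for h in hits)


def w_rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def test_encode_sequence_codes():
    assert encode_sequence("ACGTNacgtX").tolist() == [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]


def test_motif_hit_fields():
    hit = MotifHit("g", 3, "+", 1.5, "M")
    assert (hit.gene_id, hit.offset, hit.strand) == ("g", 3, "+")
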
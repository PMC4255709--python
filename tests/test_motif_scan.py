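import re

import numpy as np
import pytest

from cgishield.io_intervals import SequenceRecord, reverse_complement
from cgishield.motif_scan import (
    IupacMotif,
    count_occurrences,
    density,
    local_density_control,
    per_sequence_counts,
    presence_fraction,
    scan,
    shuffle_reduction,
)
from conftest import random_dna


class TestIupac:
    def test_validation(self):
        with pytest.raises(ValueError):
            IupacMotif("")
        with pytest.raises(ValueError):
            IupacMotif("ACGX")

    def test_reverse_complement_degenerate(self):
        assert IupacMotif("MCGCGCS").reverse_complement.pattern == "SGCGCGK"
        assert IupacMotif("TGCCGC").reverse_complement.pattern == "GCGGCA"


class TestScan:
    def test_single_forward_occurrence(self):
        assert scan("ACGCGCA", "CGCGC", "both") == [(1, "+")]

    def test_overlapping_occurrences(self):
        assert scan("CGCGCGC", "CGCGC", "forward") == [(0, "+"), (2, "+")]

    def test_reverse_strand_only(self):
        hits = scan("GCGCG", "CGCGC", "both")
        assert [h for h in hits if h[1] == "+"] == []
        assert [h for h in hits if h[1] == "-"] == [(0, "-")]

    def test_n_never_matches(self):
        assert scan("TGCNGC", "TGCCGC", "both") == []
        assert scan("NNNNNN", "NNNN", "both") == []  # motif N = ACGT only

    def test_degenerate_letters(self):
        # M = A/C, S = C/G
        assert count_occurrences("ACGCGCC", "MCGCGCS", "forward") == 1
        assert count_occurrences("CCGCGCG", "MCGCGCS", "forward") == 1
        assert count_occurrences("TCGCGCC", "MCGCGCS", "forward") == 0

    def test_strand_sum_identity(self, rng):
        # both-strand count = forward(pattern) + forward(revcomp pattern)
        motif = IupacMotif("TGCCGC")
        for _ in range(10):
            s = random_dna(rng, 300, p=(0.2, 0.3, 0.3, 0.2))
            assert count_occurrences(s, motif, "both") == \
                count_occurrences(s, motif, "forward") + \
                count_occurrences(s, motif.reverse_complement, "forward")

    def test_counts_match_regex_oracle(self, rng):
        # independent scanner: plain regex with lookahead on both strands
        motif = "CGCGC"
        for _ in range(30):
            s = random_dna(rng, 150, p=(0.2, 0.3, 0.3, 0.2))
            oracle = len(re.findall("(?=CGCGC)", s)) + \
                len(re.findall("(?=CGCGC)", reverse_complement(s)))
            assert count_occurrences(s, motif, "both") == oracle


class TestPresenceDensity:
    def test_presence_fraction(self):
        assert presence_fraction(["ACGCGCA", "TTTTTTT"], "CGCGC") == 50.0
        assert presence_fraction(["ACGCGCA", "GCGCGAA"], "CGCGC") == 100.0

    def test_presence_invariant_to_duplication(self):
        seqs = ["ACGCGCA", "TTTTTTT", "GGGGGGG"]
        assert presence_fraction(seqs, "CGCGC") == \
            presence_fraction(seqs * 2, "CGCGC")

    def test_density_per_kbp(self):
        seq = "TGCCGC" + "A" * 994  # 1000 bp, 1 fwd occurrence + 0 rc
        stats = density([seq], "TGCCGC")
        assert stats.density == pytest.approx(1.0)

    def test_density_pools_not_averages(self):
        s1 = "TGCCGC" + "A" * 94   # 100 bp, 1 occurrence
        s2 = "A" * 900             # 900 bp, 0 occurrences
        stats = density([s1, s2], "TGCCGC")
        assert stats.density == pytest.approx(1.0)  # pooled 1 per 1000 bp

    def test_relative_density(self):
        seq = "TGCCGC" * 2 + "A" * 988
        stats = density([seq], "TGCCGC", background_density=0.5)
        assert stats.relative_density == pytest.approx(stats.density / 0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            presence_fraction([], "CG")


class TestShuffleControls:
    def test_dinucleotide_motif_reduction_zero(self, rng):
        seqs = [random_dna(rng, 200, p=(0.2, 0.3, 0.3, 0.2)) for _ in range(20)]
        red = shuffle_reduction(seqs, "CG", seed=0)
        assert red["reduction_pct"] == 0.0

    def test_embedded_motif_reduced(self, rng):
        # CGCGC embedded in CpG-poor background is mostly destroyed
        seqs = []
        for _ in range(50):
            s = list(random_dna(rng, 300, p=(0.4, 0.1, 0.1, 0.4)))
            s[100:105] = "CGCGC"
            seqs.append("".join(s))
        red = shuffle_reduction(seqs, "CGCGC", seed=1, replicates=5)
        assert red["reduction_pct"] > 50
        assert red["zero_seq_increase"] > 0

    def test_no_occurrence_flagged(self):
        red = shuffle_reduction(["AAAA", "TTTT"], "CGCGC", seed=0)
        assert np.isnan(red["reduction_pct"])

    def test_local_density_identical_distributions(self):
        # a sequence with a unique valid arrangement shuffles to itself, so
        # real and shuffled histograms coincide: min-overlap gives 100%
        out = local_density_control(["CGCGCGCG"], "CG", window=4, seed=0)
        assert out["explained_pct"] == pytest.approx(100.0)

    def test_local_density_no_shuffled_occurrences(self):
        # motif destroyed by shuffling -> 0% explained; the chosen seed's
        # shuffled counterpart provably has zero occurrences
        from cgishield.shuffle_null import child_seeds, dinucleotide_shuffle
        from cgishield.motif_scan import count_occurrences

        s = "CGCGC" + "AACAGATTAGCATCA" * 6
        (gen,) = child_seeds(0, 1)
        assert count_occurrences(dinucleotide_shuffle(s, gen), "CGCGC") == 0
        out = local_density_control([s], "CGCGC", window=20, seed=0)
        assert out["explained_pct"] == 0.0

    def test_window_smaller_than_motif_rejected(self):
        with pytest.raises(ValueError):
            local_density_control(["ACGT" * 10], "CGCGC", window=3)


def test_per_sequence_counts():
    recs = [SequenceRecord("a", "TGCCGC"), SequenceRecord("b", "TGCCGCTGCCGC"),
            SequenceRecord("c", "AAAAAA")]
    df = per_sequence_counts(recs, "TGCCGC", strands="forward")
    assert df.set_index("seq_id")["count"].to_dict() == {"a": 1, "b": 2, "c": 0}
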
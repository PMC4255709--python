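import math

import numpy as np
import pytest
from scipy.special import comb

from cgishield.io_intervals import SequenceRecord, reverse_complement
from cgishield.motif_discovery import (
    DiscoveryReport,
    MotifResult,
    characteristic_motif,
    discriminative_search,
    fisher_presence_test,
)
from cgishield.motif_scan import IupacMotif
from cgishield.synthetic import SimSpec, gen_cgi_like
from conftest import random_dna


def hypergeom_tail_oracle(a, b, c, d):
    """Brute-force one-sided Fisher p: sum of hypergeometric point masses
    over tables at least as enriched, margins fixed."""
    row1, col1, n = a + b, a + c, a + b + c + d
    total = 0.0
    for x in range(a, min(row1, col1) + 1):
        total += comb(col1, x, exact=True) * comb(n - col1, row1 - x, exact=True)
    return total / comb(n, row1, exact=True)


class TestFisher:
    @pytest.mark.parametrize("table", [(8, 2, 1, 9), (5, 5, 5, 5), (3, 0, 2, 7),
                                       (0, 5, 5, 0), (12, 4, 7, 9)])
    def test_matches_bruteforce_oracle(self, table):
        p, _ = fisher_presence_test(*table)
        assert p == pytest.approx(hypergeom_tail_oracle(*table), rel=1e-10)

    def test_balanced_table(self):
        p, orat = fisher_presence_test(5, 5, 5, 5)
        assert orat == 1.0 and p > 0.5

    def test_perfect_separation(self):
        p, orat = fisher_presence_test(10, 0, 0, 10)
        assert math.isinf(orat)
        assert p == pytest.approx(1 / comb(20, 10, exact=True))

    def test_all_zero_flagged(self):
        p, orat = fisher_presence_test(0, 0, 0, 0)
        assert math.isnan(p) and math.isnan(orat)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_presence_test(-1, 0, 0, 0)


def _embed(seqs, word, fraction, rng):
    out = []
    k = len(word)
    for i, s in enumerate(seqs):
        if i < fraction * len(seqs):
            pos = int(rng.integers(0, len(s) - k))
            s = s[:pos] + word + s[pos + k:]
        out.append(s)
    return out


class TestDiscriminativeSearch:
    def test_identical_sets_find_nothing(self, rng):
        seqs = [random_dna(rng, 200) for _ in range(30)]
        report = discriminative_search(seqs, list(seqs), 4, 6)
        assert report.results == []
        assert report.characteristic is None

    def test_embedded_word_ranks_first_with_hypergeometric_p(self, rng):
        word = "TGCCGC"
        pos = _embed([random_dna(rng, 300) for _ in range(100)], word, 0.9, rng)
        neg = [random_dna(rng, 300) for _ in range(100)]
        report = discriminative_search(pos, neg, 6, 6)
        top = report.results[0]
        assert top.motif.pattern in (word, reverse_complement(word))
        a, c = top.pos_present, top.neg_present
        expected_p = hypergeom_tail_oracle(a, 100 - a, c, 100 - c)
        assert top.p == pytest.approx(expected_p, rel=1e-9)
        assert top.E == pytest.approx(expected_p * report.n_candidates)

    def test_strand_symmetry(self, rng):
        pos = _embed([random_dna(rng, 200) for _ in range(40)], "TGACGTCA", 0.8, rng)
        neg = [random_dna(rng, 200) for _ in range(40)]
        fwd = discriminative_search(pos, neg, 5, 6)
        rc = discriminative_search([reverse_complement(s) for s in pos],
                                   [reverse_complement(s) for s in neg], 5, 6)
        assert [(r.motif.pattern, r.E) for r in fwd.results] == \
            [(r.motif.pattern, r.E) for r in rc.results]

    def test_order_invariance(self, rng):
        pos = _embed([random_dna(rng, 200) for _ in range(30)], "CGCGC", 0.9, rng)
        neg = [random_dna(rng, 200) for _ in range(30)]
        a = discriminative_search(pos, neg, 5, 5)
        b = discriminative_search(pos[::-1], neg[::-1], 5, 5)
        assert [(r.motif.pattern, r.E) for r in a.results] == \
            [(r.motif.pattern, r.E) for r in b.results]

    def test_sequence_record_inputs(self, rng):
        pos = [SequenceRecord(f"p{i}", "AT" * 50 + "TGCCGC" + "TA" * 50)
               for i in range(10)]
        neg = [SequenceRecord(f"n{i}", "AT" * 103) for i in range(10)]
        report = discriminative_search(pos, neg, 6, 6)
        assert report.results[0].pos_present == 10


def _result(pattern, E):
    return MotifResult(IupacMotif(pattern), 10, 10, 0, 10, E / 100, E)


class TestCharacteristicMotif:
    def test_large_gap_is_characteristic(self):
        report = DiscoveryReport([_result("TGCCGC", 1e-37),
                                  _result("AATTAA", 1e-28)], 100)
        got = characteristic_motif(report, gap_orders=5)
        assert got is not None and got.motif.pattern == "TGCCGC"

    def test_small_gap_is_not(self):
        report = DiscoveryReport([_result("TGCCGC", 1e-6),
                                  _result("AATTAA", 1e-5)], 100)
        assert characteristic_motif(report, gap_orders=5) is None

    def test_single_motif_characteristic_by_convention(self):
        report = DiscoveryReport([_result("TGCCGC", 1e-10)], 100)
        assert characteristic_motif(report).motif.pattern == "TGCCGC"

    def test_substring_runner_up_not_distinct(self):
        # runner-up contained in the top motif (or its RC) is not distinct
        report = DiscoveryReport([_result("TGCCGC", 1e-20),
                                  _result("GCCGC", 1e-19),
                                  _result("GCGGCA", 1e-18),  # RC of top
                                  _result("AATTAA", 1e-9)], 100)
        got = characteristic_motif(report, gap_orders=5)
        assert got is not None and got.motif.pattern == "TGCCGC"

    def test_insignificant_top_rejected(self):
        report = DiscoveryReport([_result("TGCCGC", 0.5)], 100)
        assert characteristic_motif(report, e_threshold=0.05) is None


def test_e_monotone_in_pos_present():
    # more positive presences can only strengthen enrichment
    ps = [fisher_presence_test(a, 20 - a, 5, 15)[0] for a in range(5, 21)]
    assert all(x >= y for x, y in zip(ps, ps[1:]))
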
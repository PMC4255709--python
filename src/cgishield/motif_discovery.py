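"""Discriminative exact-word motif discovery with a characteristic-motif call.

A deliberately simple DREME-style search: every exact word of length
k_min..k_max present in at least one positive sequence (on either strand) is
a candidate; each candidate gets a one-sided Fisher exact p-value on its
presence/absence 2x2 table (positives vs negatives) and an E-value equal to
p times the number of candidates evaluated (the multiple-testing analogue of
DREME's correction). Inference uses only ranks and order-of-magnitude gaps
between E-values, so presence statistics on exact words suffice.

A reported motif is *characteristic* of the positive set when it is
significant (E below threshold) and an extreme outlier: the next most
significant *distinct* motif — one that is not a substring or superstring of
the top motif or of its reverse complement — is at least ``gap_orders``
orders of magnitude less significant.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .io_intervals import SequenceRecord, reverse_complement
from .motif_scan import IupacMotif


@dataclasses.dataclass
class MotifResult:
    """One candidate word with its presence counts and significance."""

    motif: IupacMotif
    pos_present: int
    pos_total: int
    neg_present: int
    neg_total: int
    p: float
    E: float

    def __post_init__(self):
        if not (0 <= self.pos_present <= self.pos_total):
            raise ValueError("pos_present out of range")
        if not (0 <= self.neg_present <= self.neg_total):
            raise ValueError("neg_present out of range")


@dataclasses.dataclass
class DiscoveryReport:
    """Ranked discovery results; ranking is by E ascending, then pattern."""

    results: list[MotifResult]
    n_candidates: int
    characteristic: MotifResult | None = None


def fisher_presence_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided Fisher exact test on the presence table [[a, b], [c, d]].

    ``a``/``b`` are positives with/without the motif, ``c``/``d`` negatives
    with/without. Returns (upper-tail p for enrichment in positives, odds
    ratio a*d/(b*c), infinite when b*c = 0). An all-zero table is undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return float("nan"), float("nan")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    orat = math.inf if b * c == 0 else (a * d) / (b * c)
    if b * c == 0 and a * d == 0:
        orat = float("nan")
    return float(p), orat


def _seq_strings(seqs: Sequence[str | SequenceRecord]) -> list[str]:
    return [s.residues if isinstance(s, SequenceRecord) else s for s in seqs]


def _word_sets(seqs: list[str], k_min: int, k_max: int) -> list[set[str]]:
    """Per sequence: all clean k-mers present on either strand."""
    out = []
    for s in seqs:
        words: set[str] = set()
        for strand_seq in (s, reverse_complement(s)):
            n = len(strand_seq)
            for k in range(k_min, k_max + 1):
                for i in range(n - k + 1):
                    w = strand_seq[i : i + k]
                    if "N" not in w:
                        words.add(w)
        out.append(words)
    return out


def discriminative_search(
    pos_seqs: Sequence[str | SequenceRecord],
    neg_seqs: Sequence[str | SequenceRecord],
    k_min: int = 4,
    k_max: int = 8,
    e_threshold: float = 0.05,
    gap_orders: float = 5.0,
) -> DiscoveryReport:
    """Rank every word found in the positives by presence enrichment.

    The one-sided Fisher p equals the hypergeometric upper tail of the
    presence table with fixed margins and is computed vectorised over all
    candidates. Only results with E < ``e_threshold`` are reported; the
    characteristic-motif call is applied to the ranked report.
    """
    if not (3 <= k_min <= k_max <= 10):
        raise ValueError("require 3 <= k_min <= k_max <= 10")
    pos = _seq_strings(pos_seqs)
    neg = _seq_strings(neg_seqs)
    if not pos or not neg:
        raise ValueError("both sequence sets must be non-empty")

    pos_sets = _word_sets(pos, k_min, k_max)
    neg_sets = _word_sets(neg, k_min, k_max)

    candidates = sorted(set().union(*pos_sets))
    if not candidates:
        return DiscoveryReport([], 0, None)
    index = {w: i for i, w in enumerate(candidates)}
    pos_present = np.zeros(len(candidates), dtype=np.int64)
    neg_present = np.zeros(len(candidates), dtype=np.int64)
    for ws in pos_sets:
        for w in ws:
            pos_present[index[w]] += 1
    for ws in neg_sets:
        for w in ws:
            if w in index:
                neg_present[index[w]] += 1

    n_pos, n_neg = len(pos), len(neg)
    n_cand = len(candidates)
    # one-sided Fisher == hypergeometric upper tail with fixed margins
    present_total = pos_present + neg_present
    p = stats.hypergeom.sf(pos_present - 1, n_pos + n_neg, present_total, n_pos)
    p = np.clip(p, 0.0, 1.0)
    E = p * n_cand

    keep = np.flatnonzero(E < e_threshold)
    results = [
        MotifResult(IupacMotif(candidates[i]), int(pos_present[i]), n_pos,
                    int(neg_present[i]), n_neg, float(p[i]), float(E[i]))
        for i in keep
    ]
    results.sort(key=lambda r: (r.E, r.motif.pattern))
    report = DiscoveryReport(results, n_cand)
    report.characteristic = characteristic_motif(report, e_threshold, gap_orders)
    return report


def _is_distinct(pattern: str, top: str) -> bool:
    """Distinct = not a substring/superstring of the top word or its RC."""
    top_rc = reverse_complement(top)
    for ref in (top, top_rc):
        if pattern in ref or ref in pattern:
            return False
    return True


def distinct_gap(report: DiscoveryReport) -> tuple[MotifResult | None, float]:
    """The next distinct motif after the top hit and the log10 E-value gap.

    Returns (None, inf) when no distinct runner-up is reported.
    """
    if not report.results:
        return None, float("nan")
    top = report.results[0]
    nxt = next(
        (r for r in report.results[1:] if _is_distinct(r.motif.pattern, top.motif.pattern)),
        None,
    )
    if nxt is None:
        return None, math.inf
    if top.E <= 0:
        return nxt, math.inf
    return nxt, math.log10(nxt.E) - math.log10(top.E)


def characteristic_motif(
    report: DiscoveryReport,
    e_threshold: float = 0.05,
    gap_orders: float = 5.0,
) -> MotifResult | None:
    """The top motif, iff significant and an extreme outlier in E-value.

    Requires E_top < ``e_threshold`` and log10(E_next_distinct) -
    log10(E_top) >= ``gap_orders``. With no distinct runner-up the gap is
    infinite and the top motif qualifies by convention.
    """
    if not report.results:
        return None
    top = report.results[0]
    if top.E >= e_threshold:
        return None
    _, gap = distinct_gap(report)
    return top if gap >= gap_orders else None
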
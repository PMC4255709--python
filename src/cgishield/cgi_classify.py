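"""Classify CGIs by position relative to transcripts; call methylation state.

Position classes, accumulated over all transcripts:

* ``promoter_associated`` (PA): the CGI overlaps the 1 kbp region around a
  stranded transcript's TSS by at least 1 bp.
* ``intragenic``: the CGI lies within a stranded transcript, at least
  1 kbp distant from the TSS.
* ``distal_intragenic``: the CGI overlaps the 1 kbp region immediately
  downstream of a stranded transcript's end.
* ``end_associated``: the CGI overlaps the 1 kbp region around either end
  of a strand-unknown transcript.

``intragenic`` and ``distal_intragenic`` are compatible and collapse to the
final class ``intragenic_like``; PA or end_associated combined with any
other label makes the CGI ``ambiguous`` (excluded from contingency
outputs); no label at all is ``transcript_free``. Partial overlap of a
transcript body without touching any window yields no label and is recorded
separately as ``boundary_overlap``.

Methylation states come from percent-methylation values with a minimum
number of assayed CpGs: below ``low`` percent is unmethylated, above
``high`` is methylated, in between intermediate (hemimethylated), and too
few CpGs is no_call.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from .io_intervals import GenomicInterval, TranscriptRecord, interval_name, merge_intervals, overlaps

WINDOW = 1000  # bp; the promoter/end window half-width used throughout

FINAL_CLASSES = ("promoter_associated", "intragenic_like", "end_associated",
                 "ambiguous", "transcript_free")
METH_STATES = ("unmethylated", "methylated", "intermediate", "no_call")


@dataclasses.dataclass
class ClassifiedCgi:
    cgi_id: str
    labels: frozenset[str]
    final_class: str
    meth_state: str = "no_call"
    boundary_overlap: bool = False


def _tss_window(t: TranscriptRecord) -> GenomicInterval:
    tss = t.tss
    return GenomicInterval(t.interval.chrom, max(tss - WINDOW, 0), tss + WINDOW)


def _downstream_window(t: TranscriptRecord) -> GenomicInterval | None:
    tes = t.tes
    if t.interval.strand == "+":
        return GenomicInterval(t.interval.chrom, tes, tes + WINDOW)
    if tes <= 0:
        return None
    return GenomicInterval(t.interval.chrom, max(tes - WINDOW, 0), tes)


def _contained(inner: GenomicInterval, outer: GenomicInterval) -> bool:
    return (inner.chrom == outer.chrom and inner.start >= outer.start
            and inner.end <= outer.end)


def _min_distance_to(point: int, iv: GenomicInterval) -> int:
    if iv.start <= point < iv.end:
        return 0
    return point - (iv.end - 1) if point >= iv.end else iv.start - point


def classify_cgi(cgi: GenomicInterval, transcripts: Sequence[TranscriptRecord],
                 cgi_id: str | None = None) -> ClassifiedCgi:
    """Accumulate position labels over all transcripts and resolve the class."""
    labels: set[str] = set()
    boundary = False
    for t in transcripts:
        if t.interval.chrom != cgi.chrom:
            continue
        if t.strand_known:
            touched = False
            if overlaps(cgi, _tss_window(t)):
                labels.add("promoter_associated")
                touched = True
            if _contained(cgi, t.interval):
                # distance from the TSS to the nearest CGI base
                if _min_distance_to(t.tss, cgi) >= WINDOW:
                    labels.add("intragenic")
                    touched = True
            dw = _downstream_window(t)
            if dw is not None and overlaps(cgi, dw):
                labels.add("distal_intragenic")
                touched = True
            if not touched and overlaps(cgi, t.interval):
                boundary = True
        else:
            iv = t.interval
            start_win = GenomicInterval(iv.chrom, max(iv.start - WINDOW, 0), iv.start + WINDOW)
            end_win = GenomicInterval(iv.chrom, max(iv.end - WINDOW, 0), iv.end + WINDOW)
            if overlaps(cgi, start_win) or overlaps(cgi, end_win):
                labels.add("end_associated")
            elif overlaps(cgi, iv):
                boundary = True

    final = _resolve_final_class(labels)
    return ClassifiedCgi(cgi_id or interval_name(cgi), frozenset(labels), final,
                         boundary_overlap=boundary)


def _resolve_final_class(labels: set[str]) -> str:
    if not labels:
        return "transcript_free"
    if "promoter_associated" in labels and len(labels) > 1:
        return "ambiguous"
    if "end_associated" in labels and len(labels) > 1:
        return "ambiguous"
    if labels == {"promoter_associated"}:
        return "promoter_associated"
    if labels == {"end_associated"}:
        return "end_associated"
    # any combination of intragenic / distal_intragenic
    return "intragenic_like"


def define_promoters(
    transcripts: Sequence[TranscriptRecord],
    unmethylated_cgis: Sequence[GenomicInterval],
    h3k4me3_regions: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """TSS +/- 1 kbp windows overlapping both an unmethylated CGI and H3K4me3.

    Overlapping or abutting emitted windows are merged. Strand-unknown
    transcripts have no TSS and are skipped.
    """
    emitted: list[GenomicInterval] = []
    for t in transcripts:
        if not t.strand_known:
            continue
        win = _tss_window(t)
        if any(overlaps(win, c) for c in unmethylated_cgis) and \
           any(overlaps(win, h) for h in h3k4me3_regions):
            emitted.append(win)
    return merge_intervals(emitted) if emitted else []


def call_methylation_state(
    percent: float,
    n_cpgs_assayed: int,
    low: float = 20.0,
    high: float = 80.0,
    min_cpgs: int = 6,
) -> str:
    """Threshold a percent-methylation value into a discrete state."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent methylation out of [0, 100]: {percent}")
    if low >= high:
        raise ValueError("low threshold must be below high")
    if n_cpgs_assayed < min_cpgs:
        return "no_call"
    if percent < low:
        return "unmethylated"
    if percent > high:
        return "methylated"
    return "intermediate"


def class_state_crosstab(classified: Iterable[ClassifiedCgi]) -> pd.DataFrame:
    """Counts of final_class x meth_state, ambiguous CGIs excluded."""
    rows = [(c.final_class, c.meth_state) for c in classified
            if c.final_class != "ambiguous"]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["final_class", "meth_state"])
    return pd.crosstab(df["final_class"], df["meth_state"])
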
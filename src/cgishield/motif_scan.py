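"""IUPAC motif scanning and presence/density statistics with shuffle controls.

Occurrence counting follows the FIMO convention: overlapping matches are all
reported, both strands are scanned by default, and ``N`` in the sequence
never matches any motif letter. Presence is the percentage of sequences with
at least one occurrence on either strand; density is pooled occurrences per
1 kbp; relative density divides by a background density computed with the
same scan over a background sequence set.

Two controls address whether motif occurrences are a mere consequence of
CpG richness: ``shuffle_reduction`` recounts occurrences after a
dinucleotide-preserving shuffle of every sequence, and
``local_density_control`` bins occurrences by the CpG content of a window
centred on each occurrence and reports the fraction of real occurrences
matched, bin by bin, by the shuffled counterparts (the min-overlap of the
two histograms).
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_intervals import SequenceRecord, reverse_complement
from .shuffle_null import child_seeds, dinucleotide_shuffle

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclasses.dataclass(frozen=True)
class IupacMotif:
    """A degenerate DNA motif written in IUPAC one-letter codes."""

    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def reverse_complement(self) -> "IupacMotif":
        return IupacMotif(self.pattern.translate(_IUPAC_COMPLEMENT)[::-1])

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all found; N in the
        # sequence never matches because the classes exclude it
        body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.pattern)
        return re.compile(f"(?=({body}))")


@dataclasses.dataclass
class MotifStats:
    """Per-category motif summary: presence %, density per kbp, relative density."""

    category: str
    n_seqs: int
    presence_fraction: float
    density: float
    relative_density: float | None = None


def _residues(seq: str | SequenceRecord) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def _as_motif(motif: str | IupacMotif) -> IupacMotif:
    return motif if isinstance(motif, IupacMotif) else IupacMotif(motif)


def scan(seq: str | SequenceRecord, motif: str | IupacMotif,
         strands: str = "both") -> list[tuple[int, str]]:
    """All (offset, strand) occurrences of the motif in one sequence.

    Reverse-strand hits are reported at their offset on the forward
    sequence (the start of the matched window).
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    motif = _as_motif(motif)
    s = _residues(seq)
    hits = [(m.start(), "+") for m in motif.regex().finditer(s)]
    if strands == "both":
        hits += [(m.start(), "-") for m in motif.reverse_complement.regex().finditer(s)]
    return sorted(hits)


def count_occurrences(seq: str | SequenceRecord, motif: str | IupacMotif,
                      strands: str = "both") -> int:
    return len(scan(seq, motif, strands))


def presence_fraction(seqs: Sequence[str | SequenceRecord],
                      motif: str | IupacMotif, strands: str = "both") -> float:
    """Percentage of sequences with >= 1 occurrence on either strand."""
    if not seqs:
        raise ValueError("empty sequence set")
    hits = sum(1 for s in seqs if count_occurrences(s, motif, strands) > 0)
    return 100.0 * hits / len(seqs)


def density(
    seqs: Sequence[str | SequenceRecord],
    motif: str | IupacMotif,
    background_density: float | None = None,
    category: str = "",
    strands: str = "both",
) -> MotifStats:
    """Pooled occurrences per 1 kbp (both strands), optionally vs background.

    Density pools counts and lengths over all sequences (it is not a mean of
    per-sequence densities). ``relative_density`` is None when no background
    is supplied or the background density is zero.
    """
    total_bp = sum(len(_residues(s)) for s in seqs)
    if total_bp == 0:
        raise ValueError("total sequence length is zero")
    total = sum(count_occurrences(s, motif, strands) for s in seqs)
    dens = 1000.0 * total / total_bp
    rel = None
    if background_density is not None and background_density > 0:
        rel = dens / background_density
    return MotifStats(category, len(seqs), presence_fraction(seqs, motif, strands),
                      dens, rel)


def background_density(background_seqs: Sequence[str | SequenceRecord],
                       motif: str | IupacMotif, strands: str = "both") -> float:
    """Occurrences per 1 kbp over a background sequence set (same scan)."""
    return density(background_seqs, motif, strands=strands).density


def shuffle_reduction(
    seqs: Sequence[str | SequenceRecord],
    motif: str | IupacMotif,
    seed: int = 0,
    replicates: int = 1,
) -> dict[str, float]:
    """Occurrence loss under dinucleotide-preserving shuffling.

    Each sequence is shuffled once per replicate; results are averaged over
    replicates. Returns the percentage reduction in total occurrences, the
    percentage reduction in density (identical here since lengths are
    preserved), and the mean increase in the number of sequences with zero
    occurrences. A motif that is itself a dinucleotide (e.g. CG) reduces by
    exactly 0.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    motif = _as_motif(motif)
    originals = [_residues(s) for s in seqs]
    orig_counts = np.array([count_occurrences(s, motif) for s in originals])
    orig_total = int(orig_counts.sum())
    out = {
        "original_total": float(orig_total),
        "original_zero_seqs": float(np.sum(orig_counts == 0)),
    }
    shuf_totals, zero_gains = [], []
    for rng in child_seeds(seed, replicates):
        counts = np.array([count_occurrences(dinucleotide_shuffle(s, rng), motif)
                           for s in originals])
        shuf_totals.append(counts.sum())
        zero_gains.append(np.sum(counts == 0) - np.sum(orig_counts == 0))
    out["shuffled_total"] = float(np.mean(shuf_totals))
    out["zero_seq_increase"] = float(np.mean(zero_gains))
    if orig_total == 0:
        out["reduction_pct"] = float("nan")
        out["density_reduction_pct"] = float("nan")
    else:
        out["reduction_pct"] = 100.0 * (1.0 - out["shuffled_total"] / orig_total)
        out["density_reduction_pct"] = out["reduction_pct"]
    return out


def _window_cpg_count(seq: str, centre: int, window: int) -> int:
    half = window // 2
    lo = max(centre - half, 0)
    hi = min(centre + half, len(seq))
    from .cpg_spacing import cpg_positions

    return int(len(cpg_positions(seq[lo:hi])))


def local_density_control(
    seqs: Sequence[str | SequenceRecord],
    motif: str | IupacMotif,
    window: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of occurrences attributable to local CpG density (%).

    Real and shuffled occurrences are binned by the CpG count of the
    ``window`` bp centred on each occurrence; the explained fraction is
    100 x sum_bin min(real_bin, shuffled_bin) / sum_bin real_bin. Identical
    histograms give 100%; shuffles with no occurrences give 0%.
    """
    motif = _as_motif(motif)
    if window < len(motif):
        raise ValueError("window must be >= motif length")
    originals = [_residues(s) for s in seqs]
    real_bins: dict[int, int] = {}
    shuf_bins: dict[int, int] = {}
    rngs = child_seeds(seed, len(originals))
    for s, rng in zip(originals, rngs):
        for off, _ in scan(s, motif):
            c = _window_cpg_count(s, off + len(motif) // 2, window)
            real_bins[c] = real_bins.get(c, 0) + 1
        shuffled = dinucleotide_shuffle(s, rng)
        for off, _ in scan(shuffled, motif):
            c = _window_cpg_count(shuffled, off + len(motif) // 2, window)
            shuf_bins[c] = shuf_bins.get(c, 0) + 1
    n_real = sum(real_bins.values())
    if n_real == 0:
        return {"explained_pct": float("nan"), "n_real": 0.0,
                "n_shuffled": float(sum(shuf_bins.values()))}
    matched = sum(min(real_bins.get(b, 0), shuf_bins.get(b, 0))
                  for b in set(real_bins) | set(shuf_bins))
    return {"explained_pct": 100.0 * matched / n_real,
            "n_real": float(n_real), "n_shuffled": float(sum(shuf_bins.values()))}


def per_sequence_counts(seqs: Sequence[SequenceRecord | tuple[str, str]],
                        motif: str | IupacMotif, strands: str = "both") -> pd.DataFrame:
    """Table of (seq_id, length, occurrence count) for each sequence."""
    rows = []
    for i, s in enumerate(seqs):
        if isinstance(s, SequenceRecord):
            sid, res = s.id, s.residues
        else:
            sid, res = s
        rows.append({"seq_id": sid, "length": len(res),
                     "count": count_occurrences(res, motif, strands)})
    return pd.DataFrame(rows)
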
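#!/usr/bin/env python
"""Motif presence/density statistics with shuffle and local-CpG controls.

Computes, for CGCGC on the two Markov categories: the percentage of
sequences containing the motif, pooled density per 1 kbp, density relative
to the other category as background, the reduction in occurrences after a
dinucleotide-preserving shuffle of each sequence (does global dinucleotide
composition explain the occurrences?), and the fraction of occurrences
attributable to locally CpG-dense windows (min-overlap of the binned
occurrence histograms, real vs shuffled).
"""

from pathlib import Path

import pandas as pd

from cgishield.io_intervals import read_fasta
from cgishield.motif_scan import (
    background_density, density, local_density_control, per_sequence_counts,
    shuffle_reduction,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
OUT = ROOT / "motif"
OUT.mkdir(parents=True, exist_ok=True)
MOTIF = "CGCGC"
SEED = 13

unmeth = read_fasta(SIM / "unmeth.fasta")
meth = read_fasta(SIM / "meth.fasta")
bg = background_density(meth, MOTIF)

rows = []
for category, records in (("unmeth", unmeth), ("meth", meth)):
    stats = density(records, MOTIF, background_density=bg, category=category)
    red = shuffle_reduction(records, MOTIF, seed=SEED)
    ctrl = local_density_control(records, MOTIF, window=100, seed=SEED)
    rows.append({
        "category": category,
        "n_seqs": stats.n_seqs,
        "presence_pct": round(stats.presence_fraction, 1),
        "density_per_kbp": round(stats.density, 3),
        "relative_density": round(stats.relative_density, 2),
        "shuffle_reduction_pct": round(red["reduction_pct"], 1),
        "zero_seq_increase": red["zero_seq_increase"],
        "local_cpg_explained_pct": round(ctrl["explained_pct"], 1),
    })
    per_sequence_counts(records, MOTIF).to_csv(
        OUT / f"per_seq_{category}.tsv", sep="\t", index=False)

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "motif_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))
print("\nShuffling removes the embedded excess in the enriched category "
      "(positive reduction) but not the composition-driven occurrences of "
      "the background (reduction near or below zero); the local-CpG control "
      "attributes the CpG-dense-window share of occurrences, so the "
      "unexplained remainder is the embedded signal.")
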
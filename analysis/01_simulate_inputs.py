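#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Three CGI-like categories are emulated with known ground truth:

* ``unmeth`` — CpG-rich 1-kbp sequences carrying two embedded CGCGC
  instances each (CGIs that resist de novo methylation);
* ``meth`` — matched background without embedding (methylated CGIs);
* ``dmr`` — 500-bp sequences with CpGs planted at a 9 +/- 1 bp period
  (gDMR-like periodic spacing), plus matched shuffled controls.

Also writes a transcript/CGI interval layout and a five-factor table drawn
from a known logistic model. Everything under results/sim/.
"""

import json
from pathlib import Path

from cgishield.factor_model import FACTORS
from cgishield.io_intervals import to_bed6, write_bed, write_fasta
from cgishield.synthetic import (
    SimSpec, gen_cgi_like, gen_factor_table, gen_layout, gen_periodic,
)

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

unmeth, unmeth_truth = gen_cgi_like(SimSpec(
    seed=SEED, n_seqs=150, length=1000, cpg_density=80.0,
    motifs=(("CGCGC", 2, "uniform"),), id_prefix="unmeth"))
meth, meth_truth = gen_cgi_like(SimSpec(
    seed=SEED + 1, n_seqs=150, length=1000, cpg_density=55.0,
    id_prefix="meth"))
dmr, dmr_truth = gen_periodic(50, length=500, period=9, jitter=1,
                              seed=SEED + 2, id_prefix="dmr")
dmr_ctrl, _ = gen_periodic(50, length=500, period=9, jitter=1,
                           seed=SEED + 3, periodic=False, id_prefix="dmrctl")

write_fasta(unmeth, OUT / "unmeth.fasta")
write_fasta(meth, OUT / "meth.fasta")
write_fasta(dmr, OUT / "dmr.fasta")
write_fasta(dmr_ctrl, OUT / "dmr_control.fasta")
unmeth_truth.to_csv(OUT / "unmeth_truth.tsv", sep="\t", index=False)
meth_truth.to_csv(OUT / "meth_truth.tsv", sep="\t", index=False)
dmr_truth.to_csv(OUT / "dmr_truth.tsv", sep="\t", index=False)

transcripts, cgis, layout_truth = gen_layout(n_per_class=10, seed=SEED + 4)
write_bed([to_bed6(t.interval, f"tx_{i:03d}") for i, t in enumerate(transcripts)],
          OUT / "transcripts.bed")
write_bed(cgis, OUT / "cgis.bed")
layout_truth.to_csv(OUT / "layout_truth.tsv", sep="\t", index=False)

coef = {"Intercept": 0.5, "PA": -2.0, "Rloop": -0.4, "Cfp1": -0.9,
        "H3K4me3": -1.5, "Motif": -1.1}
table, truth = gen_factor_table(8567, coef, {f: 0.4 for f in FACTORS},
                                seed=SEED + 5,
                                correlated_pair=("PA", "H3K4me3", 0.3))
table.to_csv(OUT / "factors.tsv", sep="\t", index=False)
with open(OUT / "factors_truth.json", "w") as fh:
    json.dump(truth, fh, indent=2)

print(f"wrote synthetic inputs to {OUT}")
print(f"  unmeth/meth CGIs: {len(unmeth)}/{len(meth)} x 1 kbp")
print(f"  periodic gDMR-like: {len(dmr)} + {len(dmr_ctrl)} controls x 500 bp")
print(f"  layout: {len(cgis)} CGIs vs {len(transcripts)} transcripts")
print(f"  factor table: {len(table)} CGIs, truth in factors_truth.json")
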
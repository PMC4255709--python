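# cgishield

Sequence-feature analyses relating CpG-island (CGI) DNA sequence to DNA
methylation state, for epigenomics researchers asking which sequence
signals mark CGIs that acquire — or resist — de novo methylation in the
oocyte. The package provides, as a tested library plus a `cgishield` CLI:

* **Dinucleotide-preserving shuffling** (Altschul–Erickson Eulerian-path
  construction) and generic empirical-null machinery. A shuffle keeps the
  exact multiset of overlapping dinucleotides, so CpG count, composition
  and endpoints are invariant; empirical p-values use the add-one rule
  `p = (1 + #{null >= obs}) / (N + 1)`.
* **CpG-spacing periodicity tests**: observed vs shuffle-expected counts
  of CpG pairs at each distance `D <= L - 2` (all pairs), obs/exp profiles
  averaged per CGI category, and upper-tail permutation tests for summed
  counts in distance ranges — by default 8–10 bp (the spacing the
  Dnmt3a/Dnmt3l tetramer can methylate simultaneously) and the 12–14 bp
  control range.
* **IUPAC motif statistics**: overlap-counting both-strand scanning,
  presence percentage, pooled density per kbp, relative density vs a
  background set, occurrence loss under dinucleotide shuffling, and a
  local-CpG-density control (min-overlap of occurrence histograms binned
  by window CpG content).
* **Discriminative motif discovery**: every exact 3–10 bp word present in
  the positive set is scored by a one-sided Fisher exact test on its
  presence 2×2 table, with `E = p × n_candidates`. A reported motif is
  *characteristic* iff `E < 0.05` and the next distinct motif (not a
  substring/superstring of it or its reverse complement) is ≥ 5 orders of
  magnitude less significant.
* **CGI classification** relative to transcripts (promoter-associated via
  the TSS ± 1 kbp window, intragenic, distal intragenic, end-associated;
  incompatible combinations are ambiguous) and methylation-state calling
  from percent-methylation with coverage filters (`< 20%` unmethylated,
  `> 80%` methylated, ≥ 6 assayed CpGs).
* **Factor modelling**: logistic regression of the binary methylation
  state `M` on the binary factors PA, Rloop (G-skew of the transcribed
  strand), Cfp1, H3K4me3 and Motif — isolated deviance reductions,
  added-value and interaction likelihood-ratio tests with Bonferroni
  correction, stratified odds ratios, and the continuous
  promoter-activity × binding model
  `M ~ logit⁻¹(β₀ + β_P·P + β_E·E2F1 + β_PE·P·E2F1)`.
* **Synthetic data generators** for all of the above with known ground
  truth: Markov CGI-like sequences with calibrated CpG density and
  embedded motifs, periodically spaced CpGs with matched shuffled
  controls, factor tables from known logistic coefficients, and
  transcript/CGI layouts realising every class.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
inputs with known truth (`python analysis/01_simulate_inputs.py` first;
outputs land under `results/`). The spacing analysis prints:

```
   category range  fraction_significant  n_seqs
        dmr  8-10              1.000000      50
        dmr 12-14              0.000000      50
dmr_control  8-10              0.060000      50
dmr_control 12-14              0.060000      50
     unmeth  8-10              0.013333     150
       meth  8-10              0.040000     150
```

Sequences built with a 9 ± 1 bp CpG period are all significantly enriched
for CpG pairs at 8–10 bp and never at 12–14 bp, while their shuffled
controls and the Markov categories sit at the nominal 5% level in both
ranges — periodicity is detected specifically where it was planted. The
discovery analysis contrasts two regimes:

```
--- planted_hexamer (k = 6..6) ---
top motif: GCGGCA (100/100 vs 33/100, E = 8.3e-25)
next distinct motif: GCCGCC (E = 0.0203); gap 22.4 orders of magnitude
characteristic motif: GCGGCA
```

A hexamer planted where it is otherwise rare is recovered (as its reverse
complement) 22 orders of magnitude ahead of everything else and is called
characteristic; a short CGCGC core embedded in CpG-rich background instead
yields a family of overlapping variants within two orders of each other —
highly significant, but not an extreme outlier, so no characteristic call.
The factor-model analysis recovers every generating coefficient within
about one standard error and finds 0/10 spurious Bonferroni-corrected
interactions under a no-interaction generator.

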
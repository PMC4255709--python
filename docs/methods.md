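# Methods

## Scope and model of the data

The package analyses CpG islands (CGIs) as DNA sequences over
{A, C, G, T, N} with optional genomic coordinates (0-based half-open
everywhere internally; 1-based only in human-readable reports). A CGI's
methylation state is treated as binary (methylated/unmethylated) once
called from percent-methylation values; everything else — spacing
statistics, motif occurrence, position classes, binary factors — is
derived from the sequence and from interval arithmetic against
transcripts. `N` bases never match any IUPAC letter and never count as G
or C in skew or density computations; soft-masked genome bases are kept
as uppercase by default, with a `mask_mode="remove"` option that replaces
them with `N` for repeat-masked analyses. How `N`s inside CGI sequences
are treated is a declared convention of this package, as is the rejection
of sequences shorter than 2 bp.

## Dinucleotide-preserving shuffling

The composition null for every per-sequence statistic is the uniform
distribution over sequences with the same multiset of overlapping
dinucleotides (hence identical length, mononucleotide counts, CpG count
and endpoints). Sampling uses the Altschul–Erickson Eulerian-path
construction: the sequence is an Eulerian path in the multigraph with one
edge per dinucleotide; a random last-edge per vertex is drawn and
accepted when the last edges form a spanning arborescence towards the
final vertex, after which the remaining out-edges are permuted uniformly
and the path is walked. This samples uniformly over valid arrangements;
naive swap-based shuffling does not and is not offered. Correctness is
tested against a brute-force enumeration oracle (all valid arrangements
of short sequences) both for membership and for uniformity (chi-square
goodness of fit over 10,000 draws).

Empirical p-values are upper-tail with add-one correction,
`p = (1 + #{null >= obs}) / (N + 1)`, so p is never 0 and ties count
towards significance of the null. Per-permutation seeds are spawned from
the master seed (`numpy.random.SeedSequence`), making every null
distribution reproducible from `(sequence, statistic, n_perm, seed)`.
For a discrete statistic this p is conservative (mean above 0.5 by about
half the tie probability); the calibration check in `validation`
quantifies this.

## CpG spacing

CpG positions are the start offsets of every `CG`; pair counts at
distance `D` use **all** pairs (not adjacent-only), so the counts at all
distances sum to `n(n-1)/2` and the largest realisable distance in a
sequence of length `L` is `L - 2`. Expectations are means over `n_perm`
shuffles (default 1,000; the suite uses 199–499 where power permits);
obs/exp ratios are undefined (and excluded from category averages) where
the expectation is zero, and category averages at distance `D` include
only sequences with `L - 2 >= D`. Range tests sum counts over
`D = d_lo..d_hi` and compare against the same shuffle set; defaults 8–10
and 12–14 bp. The per-category headline number is the fraction of
sequences with `p < 0.05`, alongside the full cumulative distribution of
p-values. Default `max_d` is 200 for profile tables and 1,000 for the
p-value machinery.

## Motif statistics and discovery

Scanning compiles an IUPAC pattern to a lookahead regex so overlapping
occurrences are all reported; both strands are scanned by default
(reverse-strand hits are reported at their forward-strand offset).
Presence is the percentage of sequences with at least one occurrence;
density pools occurrences and lengths (occurrences per 1 kbp), never
averaging per-sequence densities; relative density divides by a
background density computed with the same scan over a background set.

Two controls separate motif signal from CpG composition. The shuffle
control recounts occurrences after one dinucleotide-preserving shuffle
per sequence (a `replicates` option averages over several) and reports
the percentage reduction and the gain in zero-occurrence sequences — a
motif that is itself a dinucleotide reduces by exactly 0. The local
control bins occurrences by the CpG count of the 100-bp window centred
on each occurrence, for the real sequences and their shuffled
counterparts, and reports
`100 × Σ_bin min(real, shuffled) / Σ_bin real` as the fraction of
occurrences attributable to local CpG density. The window size and the
min-overlap formula are this package's operationalisation of that
control and are configuration-exposed.

Discovery is deliberately simple: every exact word of length
`k_min..k_max` present in at least one positive sequence (either strand)
is a candidate; each candidate's presence 2×2 table gets a one-sided
Fisher exact p (the hypergeometric upper tail, computed vectorised), and
`E = p × n_candidates` with `n_candidates` the number of words evaluated
in the run — the analogue of DREME's multiple-testing correction.
Byte-compatibility with DREME E-values is not a goal; the downstream
inferences use only ranks and order-of-magnitude gaps. Ranking is by E
ascending with lexicographic tie-break. The characteristic-motif call
returns the top motif iff `E_top < 0.05` and
`log10(E_next_distinct) - log10(E_top) >= 5`, where *distinct* means not
a substring or superstring of the top word or of its reverse complement
(a declared convention; with no distinct runner-up the gap is infinite
and the call fires). The 5-order default is a conservative bound below
the 6–9-order gaps that motivate the criterion, and is exposed as
configuration. A consequence of exact-word enumeration, demonstrated in
`analysis/04`, is that a short core embedded in a compositionally
favourable background produces a family of overlapping variants with
comparable E-values: the top word is then significant but deliberately
not called characteristic.

## CGI classification and methylation states

Labels accumulate over all transcripts: promoter-associated (PA) if the
CGI overlaps the TSS ± 1 kbp window of a stranded transcript by ≥ 1 bp;
intragenic if fully contained in the transcript at ≥ 1 kbp from the TSS;
distal intragenic if overlapping the 1 kbp immediately downstream of the
transcript end; end-associated if overlapping a 1 kbp window around
either end of a strand-unknown transcript. Intragenic and distal
intragenic are compatible and collapse to `intragenic_like`; PA or
end-associated combined with any other label is `ambiguous` (excluded
from contingency tables); no label is `transcript_free`. Partial overlap
of a transcript body without window contact yields no label and is
recorded separately as `boundary_overlap` — with stranded transcripts
this cannot occur (any body contact touches a window), so it marks
mid-body contact with strand-unknown transcripts; such CGIs fall into
`transcript_free` with the flag set. "Within a transcript" means full
containment; partial-containment handling was genuinely open and this is
the package's choice.

Methylation states from percent values: `no_call` below the minimum
assayed-CpG count (default 6), `unmethylated` strictly below the low
threshold (default 20%), `methylated` strictly above the high threshold
(default 80%), otherwise `intermediate`. Thresholds are configuration,
not constants, because different upstream datasets call states
differently; precomputed states may also be supplied directly.
Promoter definition for expression-aware analyses: TSS ± 1 kbp windows
of stranded transcripts that overlap both an unmethylated CGI and an
H3K4me3-enriched region, merged when overlapping or abutting.

## Factor model

R-loop formation potential is G-skew: the CGI sequence is oriented to
the transcript's sense strand (a `strand_convention="template"` switch
covers the opposite reading, since "transcribed strand" is ambiguous in
the field) and the factor is 1 iff G strictly outnumbers C; ties give 0.

Logistic fits are maximum likelihood via IRLS (statsmodels GLM, binomial
family, logit link; tolerance 1e-8, 100 iterations), with Wald standard
errors from the final weights. All reported tests are likelihood-ratio
tests — the deviance-difference companions of the deviance-reduction
effect size: isolated factor screening (null vs single-factor, 1 df,
ranked by reduction), added-value tests (base vs base+added), and the
interaction sweep (main effects vs + product term for every unordered
pair, Bonferroni m = number of pairs tested in the run, 10 for five
factors). Rank-deficient designs raise an error naming the columns;
complete separation is flagged and the affected pair reported
non-estimable rather than silently returned. Stratified odds ratios are
reported in both orientations, with the protective orientation
(OR > 1 ⇔ exposure reduces the outcome odds) primary, plus the
percentage-point change in the outcome fraction and a Fisher p per
stratum. Factor correlations are Pearson on 0/1 columns (phi); constant
columns yield undefined entries. The continuous model
`M ~ P + E2F1 + P:E2F1` is evaluated either from a fresh fit or from a
supplied coefficient vector (`methylation_probability`), whose default is
the published MCF7 set (−1.31, −1.63, −3.49, +0.60).

## Synthetic data

Generators are seed-deterministic and emit truth tables sufficient to
score every downstream stage. CGI-like sequences come from a first-order
Markov chain — first-order so that dinucleotide-preserving shuffles are
non-trivial and, importantly, so that the CpG arrangement is exchangeable
with its shuffles (sequences with equal transition counts and start
state are equally likely), making the generator a genuine null for the
permutation machinery. The C→G transition probability is calibrated
iteratively against the chain's stationary distribution to hit the
target CpG density (default 80 per kbp at GC fraction 0.6, a typical CGI
core; the generator verifies ±10%). Motif embedding replaces background
residues in place, instantiates degenerate letters uniformly, and
re-draws any placement that creates an unintended extra occurrence at
the junctions (at most 100 attempts); `cpg_dense` placement biases
positions towards CpG-rich 100-bp windows.

Periodic sequences plant `CG`s at successive offsets `period ± jitter`
(default 9 ± 1 bp, 500 bp length) in CG-free filler; matched
non-periodic controls are dinucleotide-preserving shuffles of the
periodic sequences — identical composition, no periodic structure.
Uniform-at-random CpG placement was rejected as a control because
minimum-gap uniform placement is over-dispersed relative to the shuffle
null and registers as spurious "enrichment" at all mid-range distances.

Factor tables draw independent Bernoulli factors at stated prevalences
(optionally one pair correlated through a Gaussian copula whose latent
correlation is solved numerically so the realised phi matches the
target) and the outcome from the stated logistic model. Interval layouts
plant CGIs realising every final class, including ambiguous
(PA-for-one-transcript, intragenic-for-another) and transcript-free.

What the generators do **not** emulate: real chromosome-scale base
composition, repeat families, mutation-driven CpG depletion gradients,
linked factor biology, or measurement noise in methylation calls.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated null and power under planted signal — not
that real oocyte data would reproduce any particular percentage.

## Problem sizes and numerical choices

The test suite and reproduction script run at: 1,000 sequences for exact
shuffle preservation and 10,000 draws per enumeration panel sequence;
200 null CGIs × 499 permutations for p-value calibration; 100 periodic
plus 100 control sequences × 499 permutations for power; 20 discovery
replicates at 100 + 100 × 500 bp; all 2×2 tables with row margins ≤ 30
for the Fisher oracle; 100 replicates at n = 10,000 (coefficient
recovery) and n = 3,000 (interaction family-wise error). These sizes
give stable estimates at interactive runtimes on one CPU.

Two calibration checks carry intrinsic statistical ceilings worth
knowing about: the one-sample KS distance of 200 p-values has null
median ≈ 0.83/√200 ≈ 0.059 even for perfectly uniform p (and the
conservative discrete empirical p adds a systematic shift), and the
joint event "all six coefficients within 2 SE" has probability
≈ 0.954⁶ ≈ 0.75 per replicate for a correctly calibrated estimator. The
corresponding checks report the measured values; thresholds tighter than
these ceilings cannot be met reliably by correct code.

Other numerical conventions: obs/exp at zero expectation is missing, not
infinite; range tests on sequences too short for the range are flagged
undefined; empirical p is never 0 by construction; odds ratios with a
zero cross-product are infinite (or undefined for all-zero tables) and
flagged; Bonferroni-corrected p-values are capped at 1.
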
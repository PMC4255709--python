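"""Seed-deterministic generators for every input the pipeline consumes.

These stand in for genome-scale data with known ground truth:

* CGI-like sequences from a first-order Markov chain calibrated to a target
  CpG density and GC fraction (first-order, so dinucleotide-preserving
  shuffles are non-trivial), with optional embedded IUPAC motifs;
* periodically CpG-spaced sequences (period 8-10 bp with jitter) and
  matched non-periodic controls;
* binary factor tables drawn from a known logistic model, optionally with a
  target pairwise phi correlation realised through a Gaussian copula;
* transcript/CGI interval layouts realising every position class.

Every generator takes an integer seed and emits truth tables sufficient to
score the downstream analysis without re-deriving labels.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_intervals import GenomicInterval, SequenceRecord, TranscriptRecord
from .motif_scan import IUPAC, IupacMotif, count_occurrences, scan

BASES = "ACGT"


@dataclasses.dataclass
class SimSpec:
    """Parameters for CGI-like sequence generation.

    ``cpg_density`` is CpGs per kbp; ``motifs`` is a list of
    (pattern, per_sequence_count, placement) with placement one of
    ``uniform`` (anywhere), ``cpg_dense`` (biased to CpG-rich windows) or
    ``independent`` (uniform, alias kept for clarity in controls).
    """

    seed: int
    n_seqs: int = 100
    length: int = 1000
    length_jitter: int = 0
    cpg_density: float = 80.0
    gc_fraction: float = 0.6
    motifs: tuple = ()
    id_prefix: str = "cgi"

    def __post_init__(self):
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.cpg_density < 0:
            raise ValueError("cpg_density must be >= 0")
        # an upper bound: every C followed by G cannot exceed the C supply
        if self.cpg_density / 1000.0 > self.gc_fraction / 2:
            raise ValueError("CpG density target exceeds the GC-content bound")
        if self.length < 10:
            raise ValueError("length too short")


def _calibrated_transition(cpg_per_bp: float, gc: float) -> np.ndarray:
    """First-order transition matrix hitting a target CpG rate.

    Rows/cols are A,C,G,T. The base distribution follows the GC fraction;
    the C->G transition probability is tuned so the stationary CpG rate
    (pi_C * P(G|C)) matches the target, iterating because boosting C->G
    perturbs the stationary distribution slightly.
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_cg = min(cpg_per_bp / pi[1], 0.95) if cpg_per_bp > 0 else pi[2]
    T = np.tile(pi, (4, 1))
    for _ in range(40):
        row_c = pi.copy()
        row_c[2] = 0.0
        row_c = row_c / row_c.sum() * (1 - p_cg)
        row_c[2] = p_cg
        T[1] = row_c
        # stationary distribution of T
        w, v = np.linalg.eig(T.T)
        stat = np.real(v[:, np.argmax(np.real(w))])
        stat = np.abs(stat) / np.abs(stat).sum()
        realised = stat[1] * p_cg
        if cpg_per_bp <= 0 or realised <= 0:
            break
        adjust = cpg_per_bp / realised
        p_cg = float(np.clip(p_cg * adjust, 1e-6, 0.95))
    return T


def _markov_sequence(rng: np.random.Generator, length: int, T: np.ndarray,
                     pi: np.ndarray) -> str:
    cum = np.cumsum(T, axis=1)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.choice(4, p=pi)
    u = rng.random(length)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return "".join(BASES[i] for i in out)


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
                   for c in pattern)


def _embed_motif(seq: str, pattern: str, count: int, placement: str,
                 rng: np.random.Generator, max_attempts: int = 100) -> str:
    """Place `count` concrete motif instances, re-drawing any placement that
    creates an unintended extra occurrence at the junctions."""
    motif = IupacMotif(pattern)
    k = len(motif)
    s = list(seq)
    taken: list[tuple[int, int]] = []
    for _ in range(count):
        for _attempt in range(max_attempts):
            if placement == "cpg_dense":
                # bias towards CpG-rich 100-bp windows
                cand = rng.integers(0, len(seq) - k + 1, size=8)
                scores = [seq.count("CG", max(p - 50, 0), p + 50) for p in cand]
                pos = int(cand[int(np.argmax(scores))])
            else:  # uniform / independent
                pos = int(rng.integers(0, len(seq) - k + 1))
            if any(pos < t_end and t_start < pos + k for t_start, t_end in taken):
                continue
            instance = _instantiate_iupac(pattern, rng)
            lo, hi = max(pos - k + 1, 0), min(pos + 2 * k - 1, len(s))
            before = {off for off, _ in scan("".join(s[lo:hi]), motif)}
            trial = s.copy()
            trial[pos : pos + k] = instance
            after = {off for off, _ in scan("".join(trial[lo:hi]), motif)}
            placed_local = pos - lo
            extra = after - before - {placed_local}
            # occurrences destroyed by the overwrite are fine; new ones at
            # the junctions are not
            if extra:
                continue
            s = trial
            taken.append((pos, pos + k))
            break
        else:
            raise RuntimeError(f"could not place motif {pattern} after {max_attempts} tries")
    return "".join(s)


def gen_cgi_like(spec: SimSpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """CGI-like sequences plus a truth table of embedded-motif counts."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = _calibrated_transition(spec.cpg_density / 1000.0, gc)
    records, rows = [], []
    for i in range(spec.n_seqs):
        length = spec.length
        if spec.length_jitter:
            length += int(rng.integers(-spec.length_jitter, spec.length_jitter + 1))
        seq = _markov_sequence(rng, length, T, pi)
        embedded = {}
        for pattern, count, placement in spec.motifs:
            seq = _embed_motif(seq, pattern, count, placement, rng)
            embedded[pattern] = count
        sid = f"{spec.id_prefix}_{i:04d}"
        records.append(SequenceRecord(sid, seq))
        row = {"seq_id": sid, "length": length, "cpg_count": seq.count("CG"),
               "periodic": False}
        for pattern, count, _ in spec.motifs:
            row[f"embedded_{pattern}"] = count
        rows.append(row)
    return records, pd.DataFrame(rows)


def gen_periodic(
    n_seqs: int,
    length: int = 500,
    period: int = 9,
    jitter: int = 1,
    seed: int = 0,
    periodic: bool = True,
    id_prefix: str = "per",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Sequences with periodically spaced CpGs and CpG-free filler.

    With ``periodic=False`` the matched non-periodic control is emitted
    instead: a dinucleotide-preserving shuffle of the periodic sequence, so
    the control has byte-identical dinucleotide composition (hence the same
    CpG count) but no periodic structure. Filler bases are drawn so that no
    unplanned CG dinucleotide arises.
    """
    from .shuffle_null import dinucleotide_shuffle

    if period < 2:
        raise ValueError("period must be >= 2")
    if jitter >= period - 1:
        raise ValueError("jitter too large for the period")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n_seqs):
        positions = []
        pos = int(rng.integers(0, period))
        while pos <= length - 2:
            positions.append(pos)
            pos += period + int(rng.integers(-jitter, jitter + 1))
        seq = _cpg_free_filler(rng, length)
        s = list(seq)
        for p in positions:
            s[p], s[p + 1] = "C", "G"
        seq = _repair_extra_cpgs(s, set(positions))
        if not periodic:
            seq = dinucleotide_shuffle(seq, rng)
        sid = f"{id_prefix}_{i:04d}"
        records.append(SequenceRecord(sid, seq))
        rows.append({"seq_id": sid, "length": length, "cpg_count": seq.count("CG"),
                     "periodic": periodic, "n_planted": len(positions)})
    return records, pd.DataFrame(rows)


def _cpg_free_filler(rng: np.random.Generator, length: int) -> str:
    out = []
    prev = ""
    for _ in range(length):
        choices = "ACT" if prev == "C" else "ACGT"
        c = choices[rng.integers(len(choices))]
        out.append(c)
        prev = c
    return "".join(out)


def _repair_extra_cpgs(s: list[str], planted: set[int]) -> str:
    # the filler is CG-free and the planted C/G overwrites cannot pair with
    # filler into a CG, so this pass is a guard for the invariant only; an
    # unplanned CG always starts at a filler C, safe to mutate
    for i in range(len(s) - 1):
        if s[i] == "C" and s[i + 1] == "G" and i not in planted:
            s[i] = "T"
    return "".join(s)


def _phi_for_latent_rho(rho: float, q1: float, q2: float) -> float:
    """Phi coefficient of two thresholded standard normals."""
    t1, t2 = stats.norm.ppf(1 - q1), stats.norm.ppf(1 - q2)
    p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf(
        [-t1, -t2])
    # P(X>t1, Y>t2) by symmetry of the bivariate normal
    p11 = float(p11)
    num = p11 - q1 * q2
    den = np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))
    return num / den


def gen_factor_table(
    n: int,
    coefficients: dict[str, float],
    prevalences: dict[str, float],
    seed: int = 0,
    correlated_pair: tuple[str, str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Binary factor table with outcome drawn from a known logistic model.

    ``coefficients`` maps ``Intercept`` and factor names (``"A:B"`` for an
    interaction) to logit-scale effects. Factors are independent Bernoulli
    at the stated prevalences, except an optional ``(f1, f2, phi)`` pair
    correlated via a Gaussian copula whose latent correlation is solved so
    the realised phi matches the target.
    """
    if "Intercept" not in coefficients:
        raise ValueError("coefficients must include 'Intercept'")
    rng = np.random.default_rng(seed)
    factors = list(prevalences)
    table = pd.DataFrame(index=range(n))
    corr_pair = set()
    if correlated_pair is not None:
        f1, f2, phi = correlated_pair
        q1, q2 = prevalences[f1], prevalences[f2]
        hi = _phi_for_latent_rho(0.999, q1, q2)
        if abs(phi) > hi:
            raise ValueError(f"target phi {phi} infeasible for prevalences")
        rho = optimize.brentq(lambda r: _phi_for_latent_rho(r, q1, q2) - phi,
                              -0.999, 0.999, xtol=1e-6)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        table[f1] = (z[:, 0] > stats.norm.ppf(1 - q1)).astype(int)
        table[f2] = (z[:, 1] > stats.norm.ppf(1 - q2)).astype(int)
        corr_pair = {f1, f2}
    for f in factors:
        if f not in corr_pair:
            table[f] = (rng.random(n) < prevalences[f]).astype(int)
    eta = np.full(n, coefficients["Intercept"], dtype=float)
    for term, beta in coefficients.items():
        if term == "Intercept":
            continue
        if ":" in term:
            a, b = term.split(":")
            eta += beta * table[a].to_numpy() * table[b].to_numpy()
        else:
            eta += beta * table[term].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    table["M"] = (rng.random(n) < prob).astype(int)
    return table, dict(coefficients)


def gen_activity_binding_table(
    n: int,
    coef: Sequence[float],
    e2f1_prevalence: float = 0.3,
    p_range: tuple[float, float] = (-1.0, 2.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Table with continuous promoter activity P, binary binding, outcome M.

    ``coef`` is (intercept, beta_P, beta_E2F1, beta_interaction); P is
    uniform over ``p_range``.
    """
    rng = np.random.default_rng(seed)
    P = rng.uniform(*p_range, size=n)
    E = (rng.random(n) < e2f1_prevalence).astype(int)
    b0, bP, bE, bPE = coef
    prob = 1.0 / (1.0 + np.exp(-(b0 + bP * P + bE * E + bPE * P * E)))
    M = (rng.random(n) < prob).astype(int)
    return pd.DataFrame({"P": P, "E2F1": E, "M": M})


def gen_layout(
    n_per_class: int = 5,
    seed: int = 0,
    chrom: str = "chrSim",
) -> tuple[list[TranscriptRecord], list[GenomicInterval], pd.DataFrame]:
    """Transcript/CGI layouts realising every final class, with truth labels.

    Each planted CGI is annotated with its intended final class, including
    ambiguous cases (promoter-associated in one transcript while intragenic
    in another) and transcript-free CGIs.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptRecord] = []
    cgis: list[GenomicInterval] = []
    truth = []
    cursor = 10_000
    spacing = 60_000

    def new_transcript(start: int, length: int, strand: str) -> TranscriptRecord:
        t = TranscriptRecord(GenomicInterval(chrom, start, start + length, strand))
        transcripts.append(t)
        return t

    def add_cgi(start: int, end: int, label: str) -> None:
        cid = f"cgi_{len(cgis):03d}"
        cgis.append(GenomicInterval(chrom, start, end, ".", annotations=(cid,)))
        truth.append({"cgi_id": cid, "true_class": label})

    for _ in range(n_per_class):
        jit = int(rng.integers(0, 200))

        # promoter_associated: CGI overlapping TSS window of a + transcript
        t = new_transcript(cursor, 20_000, "+")
        add_cgi(t.tss - 300 + jit, t.tss + 200 + jit, "promoter_associated")
        cursor += spacing

        # intragenic_like: CGI inside transcript body, >= 1 kbp from TSS
        t = new_transcript(cursor, 20_000, "+")
        add_cgi(t.tss + 5_000 + jit, t.tss + 5_600 + jit, "intragenic_like")
        cursor += spacing

        # intragenic_like via the downstream window of a - transcript
        t = new_transcript(cursor, 15_000, "-")
        add_cgi(t.tes - 800 - jit, t.tes - 200 - jit, "intragenic_like")
        cursor += spacing

        # end_associated: strand-unknown transcript end window
        t = new_transcript(cursor, 12_000, ".")
        add_cgi(t.interval.end - 300 + jit, t.interval.end + 400 + jit,
                "end_associated")
        cursor += spacing

        # ambiguous: PA for transcript A, intragenic for overlapping B
        ta = new_transcript(cursor, 10_000, "+")
        new_transcript(cursor - 8_000, 30_000, "+")
        add_cgi(ta.tss - 200, ta.tss + 300, "ambiguous")
        cursor += spacing

        # transcript_free: far from everything
        add_cgi(cursor + 30_000, cursor + 30_500, "transcript_free")
        cursor += spacing + 40_000

    return transcripts, cgis, pd.DataFrame(truth)
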
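"""Dinucleotide-frequency-invariant shuffling and empirical-null machinery.

The shuffle preserves the exact multiset of overlapping dinucleotides (hence
also sequence length, mononucleotide counts, and the first and last residue)
and samples uniformly over all valid arrangements. It is the Eulerian-path
construction of Altschul & Erickson: the sequence is viewed as an Eulerian
path in the multigraph whose vertices are the distinct residues and whose
edges are the overlapping dinucleotides; a uniformly random valid arrangement
is obtained by drawing a random last-edge spanning arborescence towards the
final vertex and then permuting the remaining out-edges of every vertex.

Empirical p-values use the add-one rule ``(1 + r) / (N + 1)`` with ties
counted in the upper tail (``>=`` the observed value), so p is never zero and
a statistic equal to every permuted value yields p = 1.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np


@dataclasses.dataclass
class NullDistribution:
    """An empirical null: one statistic value per permutation."""

    statistic_name: str
    values: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_perm < 1 or len(self.values) != self.n_perm:
            raise ValueError("values length must equal n_perm >= 1")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def dinucleotide_shuffle(sequence: str, seed: int | np.random.Generator) -> str:
    """Return a uniform random arrangement with identical dinucleotide counts.

    Parameters
    ----------
    sequence : str
        DNA string of length >= 2 (any alphabet; typically A/C/G/T/N).
    seed : int or numpy Generator
        Source of randomness; an int gives a reproducible draw.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = _as_rng(seed)
    alphabet = sorted(set(sequence))
    if len(alphabet) == 1:
        return sequence
    index = {c: i for i, c in enumerate(alphabet)}
    n = len(alphabet)
    codes = np.fromiter((index[c] for c in sequence), dtype=np.int64, count=len(sequence))

    # out-edge target lists per vertex
    adj: list[np.ndarray] = []
    src, dst = codes[:-1], codes[1:]
    order = np.argsort(src, kind="stable")
    bounds = np.searchsorted(src[order], np.arange(n + 1))
    sorted_dst = dst[order]
    for u in range(n):
        adj.append(sorted_dst[bounds[u] : bounds[u + 1]].copy())

    first, last = int(codes[0]), int(codes[-1])

    # random last edges forming a spanning arborescence towards `last`
    while True:
        last_edge = np.full(n, -1, dtype=np.int64)
        for u in range(n):
            if u != last and len(adj[u]):
                last_edge[u] = adj[u][rng.integers(len(adj[u]))]
        ok = True
        for u in range(n):
            if u == last or last_edge[u] < 0:
                continue
            seen = set()
            v = u
            while v != last:
                if v in seen or last_edge[v] < 0:
                    ok = False
                    break
                seen.add(v)
                v = int(last_edge[v])
            if not ok:
                break
        if ok:
            break

    # permute non-last out-edges; append the arborescence edge last
    ordered: list[list[int]] = []
    for u in range(n):
        edges = list(adj[u])
        if last_edge[u] >= 0:
            edges.remove(int(last_edge[u]))
        perm = [edges[i] for i in rng.permutation(len(edges))]
        if last_edge[u] >= 0:
            perm.append(int(last_edge[u]))
        ordered.append(perm)

    # walk the Euler path
    out = [first]
    ptr = [0] * n
    v = first
    for _ in range(len(sequence) - 1):
        nxt = ordered[v][ptr[v]]
        ptr[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(alphabet[i] for i in out)


def child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """Reproducible per-permutation generators derived from a master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def empirical_null(
    sequence: str,
    statistic: Callable[[str], float],
    n_perm: int,
    seed: int,
    statistic_name: str = "statistic",
) -> NullDistribution:
    """Null distribution of a per-sequence statistic under dinucleotide shuffling.

    Each permutation uses a child generator spawned reproducibly from
    ``seed``; the same ``(sequence, statistic, n_perm, seed)`` always yields
    an identical distribution.
    """
    values = np.empty(n_perm, dtype=float)
    for i, rng in enumerate(child_seeds(seed, n_perm)):
        try:
            values[i] = statistic(dinucleotide_shuffle(sequence, rng))
        except Exception as exc:
            raise RuntimeError(f"statistic failed at permutation {i}") from exc
    return NullDistribution(statistic_name, values, n_perm, seed)


def empirical_p(observed: float, null: NullDistribution | Sequence[float]) -> float:
    """Upper-tail empirical p-value, add-one corrected: (1 + #{>= obs})/(N + 1)."""
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, float)
    if len(values) == 0:
        raise ValueError("null distribution is empty")
    r = int(np.sum(values >= observed))
    return (1 + r) / (len(values) + 1)


def dinucleotide_counts(sequence: str) -> dict[str, int]:
    """Counts of all overlapping dinucleotides (the shuffle invariant)."""
    counts: dict[str, int] = {}
    for a, b in zip(sequence, sequence[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts
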
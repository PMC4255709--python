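import numpy as np
import pytest


def enumerate_dinucleotide_arrangements(s: str) -> set[str]:
    """Brute-force oracle: all sequences with the same overlapping
    dinucleotide multiset, first and last residue as ``s``."""
    from cgishield.shuffle_null import dinucleotide_counts

    target = dinucleotide_counts(s)
    found: set[str] = set()

    def rec(prefix: str, remaining: dict[str, int]) -> None:
        if not remaining:
            if prefix[-1] == s[-1]:
                found.add(prefix)
            return
        last = prefix[-1]
        nexts = {k[1] for k, v in remaining.items() if k[0] == last and v > 0}
        for nxt in nexts:
            key = last + nxt
            d = dict(remaining)
            d[key] -= 1
            if d[key] == 0:
                del d[key]
            rec(prefix + nxt, d)

    rec(s[0], dict(target))
    return found


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def random_dna(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), p=list(p), size=length))
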
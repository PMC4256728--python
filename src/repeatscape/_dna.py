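"""Small shared sequence helpers used across the package."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform DNA of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability `rate`.

    Substitutions are drawn uniformly from the three alternative bases;
    no indels are introduced.
    """
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return seq
    alts = {ord(b): [ord(c) for c in BASES if c != b] for b in BASES}
    choices = rng.integers(0, 3, size=idx.size)
    for j, i in enumerate(idx):
        base = arr[i]
        if base in alts:
            arr[i] = alts[base][choices[j]]
    return arr.tobytes().decode()


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (display convention for proportions and Mb)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def canonical_monomer(mono: str) -> str:
    """Canonical representative of a tandem monomer.

    Rotation- and strand-invariant: the smaller of the minimal rotations of
    the monomer and of its reverse complement.
    """
    return min(min_rotation(mono), min_rotation(revcomp(mono)))
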
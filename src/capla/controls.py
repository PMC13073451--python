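"""Controlled inputs isolating what makes genome spectra special.

A genome's 21-mer multiset differs from a uniform random multiset of the
same size in at least two measurable ways: its k-mers overlap (consecutive
k-mers share k-1 bases), it contains repeats, and its keys are non-uniformly
distributed over the universe.  The generators here tease those factors
apart:

* ``random_multiset`` — i.i.d. uniform k-mers, the fully unstructured
  reference point (pinch point around 1.86 at the 10^6 scale);
* ``random_string`` — overlapping k-mers but no evolved structure;
* ``clip_repeats`` — a genome-like string made nearly repeat-free by a
  single left-to-right scan that drops any base completing a previously
  seen k-mer;
* ``hash_spectrum`` — the same multiset re-based through a seeded bijective
  mixing permutation of the universe, which uniformizes the key
  distribution while preserving n, N and all multiplicities;
* ``analytic_table`` — the exact best-case (b = 1) and worst-case
  (b = N / (2 eps)) PLA-size tables, the two ends of the approximability
  spectrum.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .pla import PLASizeTable
from .spectrum import Spectrum, spectrum_from_values

__all__ = [
    "random_multiset",
    "random_string",
    "clip_repeats",
    "hash_spectrum",
    "unhash_spectrum",
    "analytic_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_multiset(count: int, k: int, seed: int) -> Spectrum:
    """``count`` i.i.d. uniform draws from [0, 4**k), as a spectrum."""
    if count < 1:
        raise ValueError("count must be positive")
    rng = np.random.default_rng(seed)
    u = 4**k
    vals = rng.integers(0, u, size=count, dtype=np.int64)
    return spectrum_from_values(vals, u, k=k)


def random_string(length: int, seed: int) -> str:
    """i.i.d. uniform DNA string of the given length."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def clip_repeats(seq: str, k: int) -> str:
    """Make a sequence nearly repeat-free at k-mer scale.

    Single left-to-right pass appending one base at a time: whenever the
    trailing k bases of the output form a k-mer that has been seen before,
    the just-appended base is dropped; otherwise the k-mer is recorded.
    Output is "nearly" repeat-free rather than exactly so: dropping a base
    splices the sequence, and the spliced junctions can still reproduce an
    already-seen k-mer later.
    """
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    mask = 4**k
    seen: set[int] = set()
    out: list[str] = []
    h = 0  # rolling code of the trailing min(len(out), k) bases
    for ch in seq:
        h2 = (h * 4 + code[ch]) % (mask * 4)
        if len(out) + 1 >= k:
            kmer = h2 % mask
            if kmer in seen:
                continue  # drop this base; h unchanged
            seen.add(kmer)
        out.append(ch)
        h = h2
    return "".join(out)


def _mix_params(k: int, seed: int) -> tuple[int, int, int, int]:
    rng = np.random.default_rng(seed)
    bits = 2 * k
    # odd multipliers are invertible mod 2**bits; shifts in [1, bits-1]
    m1 = (int(rng.integers(0, 2**63)) * 2 + 1) % (1 << bits)
    m2 = (int(rng.integers(0, 2**63)) * 2 + 1) % (1 << bits)
    s1 = int(rng.integers(1, max(2, bits)))
    s2 = int(rng.integers(1, max(2, bits)))
    return m1, m2, s1, s2


def _mix(x: np.ndarray, k: int, seed: int, inverse: bool = False) -> np.ndarray:
    """Seeded bijection on [0, 4**k): xor-shift and odd-multiply rounds.

    Odd multiplication and right-xor-shift are both invertible on the 2k-bit
    ring, so the composition is a permutation of the universe; ``inverse``
    applies the exact inverse.  Arithmetic is done in uint64: wraparound
    multiplication followed by masking to 2k bits equals multiplication
    modulo 2**2k exactly.
    """
    bits = 2 * k
    mask = np.uint64((1 << bits) - 1)
    m1, m2, s1, s2 = _mix_params(k, seed)
    v = x.astype(np.uint64)

    def unshift(w: np.ndarray, s: int) -> np.ndarray:
        # invert w -> w ^ (w >> s) by fixed-point iteration
        r = w.copy()
        for _ in range(-(-bits // s)):
            r = w ^ (r >> np.uint64(s))
        return r

    with np.errstate(over="ignore"):
        if not inverse:
            v = (v * np.uint64(m1)) & mask
            v = v ^ (v >> np.uint64(s1))
            v = (v * np.uint64(m2)) & mask
            v = v ^ (v >> np.uint64(s2))
        else:
            v = unshift(v, s2)
            v = (v * np.uint64(pow(m2, -1, 1 << bits))) & mask
            v = unshift(v, s1)
            v = (v * np.uint64(pow(m1, -1, 1 << bits))) & mask
    return v.astype(np.int64)


def hash_spectrum(spectrum: Spectrum, seed: int) -> Spectrum:
    """Re-base a spectrum through a seeded bijective universe permutation.

    Each key is passed through an invertible 2k-bit mixing permutation
    (xor-shift / odd-multiply rounds) and the multiset is re-sorted; n, N
    and the multiset of multiplicities are preserved exactly, while any
    positional structure of the keys is destroyed — the distribution over
    the universe becomes effectively uniform.
    """
    if spectrum.k < 1:
        raise ValueError("hashing requires a genomic universe (k >= 1)")
    mixed = _mix(spectrum.keys, spectrum.k, seed)
    order = np.argsort(mixed)
    return Spectrum(
        k=spectrum.k,
        u=spectrum.u,
        keys=mixed[order],
        counts=spectrum.counts[order],
    )


def unhash_spectrum(spectrum: Spectrum, seed: int) -> Spectrum:
    """Exact inverse of `hash_spectrum` with the same seed."""
    unmixed = _mix(spectrum.keys, spectrum.k, seed, inverse=True)
    order = np.argsort(unmixed)
    return Spectrum(
        k=spectrum.k,
        u=spectrum.u,
        keys=unmixed[order],
        counts=spectrum.counts[order],
    )


def analytic_table(
    kind: Literal["best", "worst"],
    n_or_N: int,
    eps_set,
) -> PLASizeTable:
    """Exact extremal PLA-size tables.

    ``best``: b = 1 everywhere with n distinct elements (a perfectly linear
    rank curve; pinch point 0 with beta = n).  ``worst``: b(eps) = N/(2 eps),
    stored real-valued, with n = N (pinch point 1 with beta = 2).
    """
    eps = np.asarray(sorted(int(e) for e in eps_set), dtype=np.float64)
    if n_or_N < 1:
        raise ValueError("size parameter must be positive")
    if kind == "best":
        return PLASizeTable(
            eps_values=eps, b_values=np.ones_like(eps), n=n_or_N, N=n_or_N
        )
    if kind == "worst":
        b = n_or_N / (2.0 * eps)
        if np.any(b < 1):
            raise ValueError("worst-case table needs N >= 2*max(eps)")
        return PLASizeTable(eps_values=eps, b_values=b, n=n_or_N, N=n_or_N)
    raise ValueError(f"unknown analytic table kind: {kind!r}")
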
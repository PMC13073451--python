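"""k-mer spectra and their rank functions.

A *spectrum* is the multiset of all k-mers appearing in a string, stored as a
sorted run-length encoding over the integer universe ``[0, u)`` with the usual
2-bit encoding A=0, C=1, G=2, T=3 (most significant base first), so that
``u = 4**k`` for genomic input.  The object of study is the rank function

    RANK(x) = |{ y in S : y <= x }|   (counted with multiplicity),

a nondecreasing step function whose piecewise-linear approximability the rest
of the package measures.  The data model allows an arbitrary positive universe
``u`` so that tiny synthetic universes can be used in tests and experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "Spectrum",
    "preprocess",
    "build_spectrum",
    "rank",
    "spectrum_from_values",
    "read_fasta",
    "spectrum_from_fasta",
    "write_spectrum_tsv",
    "read_spectrum_tsv",
    "write_spectrum_npz",
    "read_spectrum_npz",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# translation table: uppercase, then delete anything that is not ACGT
_UPPER = str.maketrans(
    "abcdefghijklmnopqrstuvwxyz", "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)
_KEEP = frozenset("ACGT")


class EmptySequenceError(ValueError):
    """Raised when preprocessing leaves no usable sequence."""


@dataclass(frozen=True)
class Spectrum:
    """Run-length encoded sorted multiset over an integer universe.

    Attributes
    ----------
    k : int
        k-mer length in bases (0 for non-genomic synthetic multisets).
    u : int
        Universe size; keys live in ``[0, u)``.
    keys : ndarray of int64
        Strictly increasing distinct elements.
    counts : ndarray of int64
        Positive multiplicities aligned with ``keys``.
    """

    k: int
    u: int
    keys: np.ndarray
    counts: np.ndarray
    # cumulative counts, cached for rank queries
    _cum: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        keys = np.asarray(self.keys, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "keys", keys)
        object.__setattr__(self, "counts", counts)
        if self.u < 1:
            raise ValueError("universe size must be positive")
        if keys.size == 0:
            raise ValueError("a spectrum must contain at least one element")
        if keys.size != counts.size:
            raise ValueError("keys and counts must be aligned")
        if np.any(counts < 1):
            raise ValueError("all multiplicities must be >= 1")
        if keys[0] < 0 or keys[-1] >= self.u:
            raise ValueError("keys must lie in [0, u)")
        if keys.size > 1 and np.any(np.diff(keys) <= 0):
            raise ValueError("keys must be strictly increasing")
        object.__setattr__(self, "_cum", np.cumsum(counts))

    @property
    def n(self) -> int:
        """Number of distinct elements."""
        return int(self.keys.size)

    @property
    def N(self) -> int:
        """Total number of elements, with multiplicity."""
        return int(self._cum[-1])

    def rank(self, x: int) -> int:
        return rank(self, x)


def preprocess(records: Iterable[str]) -> str:
    """Clean raw sequence records into a single ACGT string.

    Each record is uppercased, characters outside {A, C, G, T} are removed,
    and the cleaned records are concatenated in input order.  Note that the
    concatenation introduces artificial junction k-mers between records; no
    separator is inserted.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one sequence record is required")
    parts = []
    for rec in records:
        up = rec.translate(_UPPER)
        parts.append("".join(ch for ch in up if ch in _KEEP))
    out = "".join(parts)
    if not out:
        raise EmptySequenceError("no A/C/G/T characters left after cleaning")
    return out


def _encode_bases(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if np.any(codes < 0):
        raise ValueError("sequence contains non-ACGT characters; run preprocess first")
    return codes


def build_spectrum(seq: str, k: int) -> Spectrum:
    """Build the k-mer spectrum of a cleaned sequence.

    Every one of the ``len(seq) - k + 1`` substrings of length ``k`` is
    encoded as a base-4 integer (A=0 < C=1 < G=2 < T=3, most significant base
    first); the sorted multiset is returned run-length encoded with
    ``u = 4**k``.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if 2 * k > 62:
        raise ValueError("k too large for 64-bit encoding (k <= 31)")
    if len(seq) < k:
        raise ValueError("sequence shorter than k")
    codes = _encode_bases(seq)
    m = len(seq) - k + 1
    kmers = np.zeros(m, dtype=np.int64)
    for j in range(k):
        kmers = (kmers << 2) | codes[j : j + m]
    kmers.sort()
    keys, counts = _run_length(kmers)
    return Spectrum(k=k, u=4**k, keys=keys, counts=counts)


def spectrum_from_values(values: Sequence[int], u: int, k: int = 0) -> Spectrum:
    """Spectrum from an unsorted multiset of integers in ``[0, u)``."""
    arr = np.sort(np.asarray(values, dtype=np.int64))
    if arr.size and (arr[0] < 0 or arr[-1] >= u):
        raise ValueError("values must lie in [0, u)")
    keys, counts = _run_length(arr)
    return Spectrum(k=k, u=u, keys=keys, counts=counts)


def _run_length(sorted_vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keys, counts = np.unique(sorted_vals, return_counts=True)
    return keys.astype(np.int64), counts.astype(np.int64)


def rank(spectrum: Spectrum, x: int) -> int:
    """Number of multiset elements <= x, with multiplicity."""
    if x < 0 or x >= spectrum.u:
        raise ValueError("rank query outside [0, u)")
    idx = int(np.searchsorted(spectrum.keys, x, side="right"))
    return 0 if idx == 0 else int(spectrum._cum[idx - 1])


def rank_array(spectrum: Spectrum, xs: np.ndarray) -> np.ndarray:
    """Vectorized rank over an array of query points."""
    xs = np.asarray(xs, dtype=np.int64)
    if xs.size and (xs.min() < 0 or xs.max() >= spectrum.u):
        raise ValueError("rank query outside [0, u)")
    idx = np.searchsorted(spectrum.keys, xs, side="right")
    cum = np.concatenate(([0], spectrum._cum))
    return cum[idx]


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: Union[str, Path]) -> list[str]:
    """Raw record strings from a (possibly multi-record, wrapped) FASTA file."""
    records = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def spectrum_from_fasta(path: Union[str, Path], k: int) -> Spectrum:
    """FASTA -> preprocess -> k-mer spectrum, in one step."""
    return build_spectrum(preprocess(read_fasta(path)), k)


def write_spectrum_tsv(spectrum: Spectrum, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# capla spectrum\tk={spectrum.k}\tu={spectrum.u}\n")
        fh.write("key\tcount\n")
        for key, cnt in zip(spectrum.keys, spectrum.counts):
            fh.write(f"{key}\t{cnt}\n")


def read_spectrum_tsv(path: Union[str, Path]) -> Spectrum:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# capla spectrum"):
            raise ValueError("not a capla spectrum TSV")
        meta = dict(tok.split("=", 1) for tok in header.split("\t")[1:])
        fh.readline()  # column header
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    return Spectrum(
        k=int(meta["k"]), u=int(meta["u"]), keys=data[:, 0], counts=data[:, 1]
    )


def write_spectrum_npz(spectrum: Spectrum, path: Union[str, Path]) -> None:
    """Compact binary dump (NumPy .npz) for reuse across runs."""
    np.savez_compressed(
        path,
        k=np.int64(spectrum.k),
        u=np.int64(spectrum.u),
        keys=spectrum.keys,
        counts=spectrum.counts,
    )


def read_spectrum_npz(path: Union[str, Path]) -> Spectrum:
    with np.load(path) as data:
        return Spectrum(
            k=int(data["k"]), u=int(data["u"]),
            keys=data["keys"], counts=data["counts"],
        )
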
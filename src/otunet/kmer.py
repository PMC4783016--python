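"""k-mer coding and the shared-k-mer distance used as an alignment prefilter.

Every distinct A/C/G/T word of length k observed in the input is assigned a
small integer code the first time it is encountered (a dynamically grown
dictionary, scanning sequences in order and positions left to right).
Sequences are then held as sorted code/count vectors so that the distance
kernel compares integers instead of strings. The coding is a pure change of
representation: distances computed on codes must equal distances computed on
the raw strings, and a string-path implementation is kept alongside as a
cross-check.

The distance between two sequences is one minus the number of shared k-mers
(counted with multiplicity) normalized by the number of k-mer positions in
the shorter sequence::

    d(x, y) = 1 - sum_w min(c_x(w), c_y(w)) / (min(|x|, |y|) - k + 1)

clamped to [0, 1]. Words containing characters outside {A, C, G, T} are
skipped entirely (not coded, not counted); the denominator is unaffected.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_ACGT = frozenset("ACGT")


@dataclass
class KmerCodebook:
    """Injective k-mer -> integer code dictionary; codes are 0..len-1."""

    k: int
    mapping: dict[str, int] = field(default_factory=dict)

    @property
    def next_code(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path) -> Path:
        """Dump the dictionary as a two-column TSV (debugging aid)."""
        path = Path(path)
        with open(path, "w", newline="\n") as fh:
            for word, code in self.mapping.items():
                fh.write(f"{word}\t{code}\n")
        return path


@dataclass(frozen=True)
class KmerProfile:
    """Sorted integer k-mer codes with occurrence counts for one sequence."""

    codes: np.ndarray  # strictly increasing int64
    counts: np.ndarray  # >= 1, same length as codes
    n_kmers: int
    seq_length: int
    k: int


def _valid_words(seq: str, k: int):
    for p in range(len(seq) - k + 1):
        w = seq[p : p + k]
        if set(w) <= _ACGT:
            yield w


def build_codebook(sequences, k: int) -> KmerCodebook:
    """Assign codes to every unambiguous k-mer, in first-encounter order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sequences = list(sequences)
    if sequences and all(len(getattr(s, "seq", s)) < k for s in sequences):
        raise ValueError(f"k={k} is larger than every input sequence")
    book = KmerCodebook(k=k)
    mapping = book.mapping
    for s in sequences:
        seq = getattr(s, "seq", s)
        for w in _valid_words(seq, k):
            if w not in mapping:
                mapping[w] = len(mapping)
    return book


def encode(record, codebook: KmerCodebook) -> KmerProfile:
    """Replace a sequence's k-mers by their codes; the codebook must be complete."""
    seq = getattr(record, "seq", record)
    k = codebook.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter ({len(seq)} bp) than k={k}")
    mapping = codebook.mapping
    codes_list = []
    for w in _valid_words(seq, k):
        code = mapping.get(w)
        if code is None:
            raise KeyError(f"k-mer {w!r} missing from codebook (codebook incomplete)")
        codes_list.append(code)
    codes, counts = np.unique(np.asarray(codes_list, dtype=np.int64), return_counts=True)
    return KmerProfile(codes, counts, int(counts.sum()), len(seq), k)


def build_profiles(records, codebook: KmerCodebook) -> list[KmerProfile]:
    return [encode(r, codebook) for r in records]


def kmer_distance(px: KmerProfile, py: KmerProfile) -> float:
    """Shared-k-mer distance between two coded profiles (same codebook/k)."""
    if px.k != py.k:
        raise ValueError(f"profiles built with different k: {px.k} vs {py.k}")
    _, ia, ib = np.intersect1d(px.codes, py.codes, assume_unique=True, return_indices=True)
    shared = int(np.minimum(px.counts[ia], py.counts[ib]).sum())
    denom = min(px.seq_length, py.seq_length) - px.k + 1
    d = 1.0 - shared / denom
    return min(max(d, 0.0), 1.0)


def kmer_distance_strings(x: str, y: str, k: int) -> float:
    """Same distance computed directly on k-mer strings, bypassing the codebook.

    Exists as an independent code path: the codebook transformation must not
    change any distance, and tests hold the two implementations to exact
    agreement.
    """
    if len(x) < k or len(y) < k:
        raise ValueError(f"both sequences must be at least k={k} long")
    cx = Counter(_valid_words(x, k))
    cy = Counter(_valid_words(y, k))
    shared = sum(min(n, cy[w]) for w, n in cx.items() if w in cy)
    denom = min(len(x), len(y)) - k + 1
    d = 1.0 - shared / denom
    return min(max(d, 0.0), 1.0)


def profile_pair_fn(profiles: list[KmerProfile]):
    """Adapt a profile list to the (i, j) -> distance signature of the scheduler."""

    def fn(i: int, j: int) -> float:
        return kmer_distance(profiles[i], profiles[j])

    return fn
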
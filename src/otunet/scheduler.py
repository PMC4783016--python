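"""Chunked evaluation of the triangular all-pairs distance space.

For n sequences there are n(n-1)/2 pairs to compare. The pair space is
linearized column by column -- index(i, j) = j(j-1)/2 + i for 0 <= i < j --
cut into fixed-size chunks (the *granularity*), and the chunks are executed
on a local worker pool. Each chunk's results are merged into the global edge
store as the task completes, never all at once at the end, and only pairs at
or below the distance threshold are kept (a sparse network, never the dense
matrix).

The correctness contract is that the retained edge set, in canonical (i, j)
order, is identical for every worker count and every granularity; the tests
enforce it. Distributing chunks across machines rather than threads is out
of scope -- the single-host pool honors the same deterministic-merge
semantics.
"""
from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor, as_completed
from dataclasses import dataclass
from math import isqrt
from typing import Callable


@dataclass(frozen=True)
class PairChunk:
    """Half-open [start, stop) range of linear pair indices."""

    start: int
    stop: int
    chunk_id: int

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class DistanceEdge:
    """A retained pair (i < j) with its distance."""

    i: int
    j: int
    d: float


class PairTaskError(RuntimeError):
    """Raised when the distance function fails; names the originating pair."""

    def __init__(self, i: int, j: int, chunk_id: int):
        super().__init__(f"distance evaluation failed for pair ({i}, {j}) in chunk {chunk_id}")
        self.pair = (i, j)
        self.chunk_id = chunk_id


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items: n(n-1)/2."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return n * (n - 1) // 2


def pair_index_to_ij(t: int, n: int) -> tuple[int, int]:
    """Invert the column-major linearization index(i, j) = j(j-1)/2 + i.

    Pairs are ordered (0,1), (0,2), (1,2), (0,3), ... -- the triangle filled
    top to bottom, left to right.
    """
    total = pair_count(n)
    if not 0 <= t < total:
        raise ValueError(f"pair index {t} out of range [0, {total}) for n={n}")
    j = (1 + isqrt(1 + 8 * t)) // 2
    while j * (j - 1) // 2 > t:
        j -= 1
    while (j + 1) * j // 2 <= t:
        j += 1
    i = t - j * (j - 1) // 2
    return i, j


def ij_to_pair_index(i: int, j: int) -> int:
    if not 0 <= i < j:
        raise ValueError(f"need 0 <= i < j, got ({i}, {j})")
    return j * (j - 1) // 2 + i


def chunk_pairs(n: int, granularity: int) -> list[PairChunk]:
    """Cut [0, n(n-1)/2) into fixed-size chunks; only the last may be short."""
    if granularity < 1:
        raise ValueError(f"granularity must be >= 1, got {granularity}")
    total = pair_count(n)
    return [
        PairChunk(start, min(start + granularity, total), cid)
        for cid, start in enumerate(range(0, total, granularity))
    ]


def _run_chunk(
    chunk: PairChunk,
    n: int,
    distance_fn: Callable[[int, int], float],
    threshold: float,
) -> list[DistanceEdge]:
    out: list[DistanceEdge] = []
    i, j = pair_index_to_ij(chunk.start, n) if chunk.start < pair_count(n) else (0, 1)
    for _ in range(chunk.start, chunk.stop):
        try:
            d = distance_fn(i, j)
        except Exception as exc:
            raise PairTaskError(i, j, chunk.chunk_id) from exc
        if d <= threshold:
            out.append(DistanceEdge(i, j, d))
        i += 1
        if i == j:  # next column of the triangle
            i, j = 0, j + 1
    return out


def run_pair_tasks(
    n: int,
    granularity: int,
    distance_fn: Callable[[int, int], float],
    threshold: float,
    n_workers: int = 1,
    progress: Callable[[int, int], None] | None = None,
) -> list[DistanceEdge]:
    """Evaluate every pair exactly once; keep edges with d <= threshold.

    Chunks run on a pool of ``n_workers`` threads; each completed chunk is
    merged into the edge store immediately. The returned list is sorted by
    (i, j) and is independent of both ``n_workers`` and ``granularity``.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    chunks = chunk_pairs(n, granularity)
    edges: list[DistanceEdge] = []
    if n_workers == 1:
        for done, chunk in enumerate(chunks, 1):
            edges.extend(_run_chunk(chunk, n, distance_fn, threshold))
            if progress is not None:
                progress(done, len(chunks))
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            futures = [
                pool.submit(_run_chunk, chunk, n, distance_fn, threshold)
                for chunk in chunks
            ]
            for done, fut in enumerate(as_completed(futures), 1):
                edges.extend(fut.result())
                if progress is not None:
                    progress(done, len(chunks))
    edges.sort(key=lambda e: (e.i, e.j))
    return edges
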
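"""Needleman-Wunsch global alignment and the percent-dissimilarity it defines.

The aligner is a classic dynamic program with linear (per-base) gap costs.
Because amplicon reads differ in length, terminal gaps are free by default
(end-gap-free "glocal" semantics): leading gaps cost nothing through a zero
first row/column, trailing gaps cost nothing by taking the best cell on the
last row or column. The dissimilarity of a pair is::

    distance = 1 - identical_cols / counted_cols

where a column is identical only when both characters are equal *and*
unambiguous (A/C/G/T) -- an ambiguity code against anything, including N-N,
counts as non-identical -- and ``counted_cols`` excludes terminal-gap columns
unless ``count_terminal_gaps_in_distance`` is set. Interior gap columns count
as non-identical, so indels contribute to percent dissimilarity.

Traceback ties are broken in fixed operator order (diagonal > up > left), and
among equally scoring end cells the one closest to the matrix corner is used,
so aligned strings are deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-9
_ACGT_BYTES = frozenset(b"ACGT")


@dataclass(frozen=True)
class NWParams:
    """Alignment scoring and distance-counting policy.

    match/mismatch are per-column scores; gap is the per-base penalty of a
    linear gap. N or any IUPAC ambiguity code scores as a mismatch against
    everything (itself included).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    terminal_gaps_free: bool = True
    count_terminal_gaps_in_distance: bool = False

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise ValueError(f"match ({self.match}) must exceed mismatch ({self.mismatch})")
        if not self.gap < 0:
            raise ValueError(f"gap penalty must be negative, got {self.gap}")


@dataclass(frozen=True)
class NWResult:
    aligned_x: str
    aligned_y: str
    score: float
    identical_cols: int
    counted_cols: int
    distance: float


def _fill_matrix(x: str, y: str, params: NWParams):
    """Score matrix H and per-cell substitution scores S.

    The within-row dependency of the linear-gap recurrence is resolved with a
    running prefix maximum: H[i,j] = max_{k<=j} (c_k + gap*(j-k)) where c_k is
    the best diagonal/vertical entry into column k. This keeps the fill at one
    Python loop over rows with vectorized columns.
    """
    n, m = len(x), len(y)
    xa = np.frombuffer(x.encode("ascii"), dtype=np.uint8)
    ya = np.frombuffer(y.encode("ascii"), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    unamb_x = np.isin(xa, acgt)
    unamb_y = np.isin(ya, acgt)
    eq = (xa[:, None] == ya[None, :]) & unamb_x[:, None] & unamb_y[None, :]
    S = np.where(eq, params.match, params.mismatch)

    g = params.gap
    gj = g * np.arange(m + 1)
    H = np.empty((n + 1, m + 1))
    H[0] = 0.0 if params.terminal_gaps_free else gj
    run = np.empty(m + 1)
    for i in range(1, n + 1):
        prev = H[i - 1]
        run[0] = 0.0 if params.terminal_gaps_free else g * i
        np.maximum(prev[:-1] + S[i - 1], prev[1:] + g, out=run[1:])
        run -= gj
        np.maximum.accumulate(run, out=run)
        H[i] = run + gj
    return H, S


def _end_cell(H: np.ndarray, n: int, m: int, free: bool) -> tuple[int, int]:
    if not free:
        return n, m
    best_score = -np.inf
    best = (n, m)
    cells = [(i, m) for i in range(n + 1)] + [(n, j) for j in range(m + 1)]
    for cell in sorted(set(cells)):
        s = H[cell]
        if s >= best_score - _EPS:
            # ties resolved toward the corner (largest i, then j)
            if s > best_score + _EPS or cell >= best:
                best_score = s
                best = cell
    return best


def needleman_wunsch(x: str, y: str, params: NWParams = NWParams()) -> NWResult:
    """Optimal global alignment of two sequences under ``params``."""
    if not x or not y:
        raise ValueError("cannot align an empty sequence")
    H, S = _fill_matrix(x, y, params)
    n, m = len(x), len(y)
    g = params.gap
    ei, ej = _end_cell(H, n, m, params.terminal_gaps_free)
    score = float(H[ei, ej])

    ax: list[str] = []
    ay: list[str] = []
    # trailing terminal gaps (at most one of the two loops runs)
    for j in range(m, ej, -1):
        ax.append("-")
        ay.append(y[j - 1])
    for i in range(n, ei, -1):
        ax.append(x[i - 1])
        ay.append("-")

    i, j = ei, ej
    while i > 0 and j > 0:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= _EPS:
            ax.append(x[i - 1])
            ay.append(y[j - 1])
            i -= 1
            j -= 1
        elif abs(h - (H[i - 1, j] + g)) <= _EPS:
            ax.append(x[i - 1])
            ay.append("-")
            i -= 1
        elif abs(h - (H[i, j - 1] + g)) <= _EPS:
            ax.append("-")
            ay.append(y[j - 1])
            j -= 1
        else:  # pragma: no cover - recurrence guarantees one branch
            raise AssertionError("traceback lost the optimal path")
    while i > 0:
        ax.append(x[i - 1])
        ay.append("-")
        i -= 1
    while j > 0:
        ax.append("-")
        ay.append(y[j - 1])
        j -= 1

    sx = "".join(reversed(ax))
    sy = "".join(reversed(ay))
    identical, counted = _column_stats(sx, sy, params)
    if counted > 0:
        distance = 1.0 - identical / counted
    else:
        distance = 1.0  # degenerate: nothing aligned at all
    distance = min(max(distance, 0.0), 1.0)
    return NWResult(sx, sy, score, identical, counted, distance)


def alignment_columns(ax: str, ay: str) -> tuple[int, int, int, int]:
    """(leading_terminal, trailing_terminal, identical, total) column counts.

    Terminal gap columns are the maximal run of gaps at either end of either
    aligned string; at most one string can carry each run since gap-gap
    columns never occur.
    """
    L = len(ax)
    lead = 0
    for s in (ax, ay):
        r = 0
        while r < L and s[r] == "-":
            r += 1
        lead += r
    trail = 0
    for s in (ax, ay):
        r = 0
        while r < L - lead and s[L - 1 - r] == "-":
            r += 1
        trail += r
    identical = sum(
        1
        for a, b in zip(ax, ay)
        if a == b and a.encode("ascii")[0] in _ACGT_BYTES
    )
    return lead, trail, identical, L


def _column_stats(ax: str, ay: str, params: NWParams) -> tuple[int, int]:
    lead, trail, _, L = alignment_columns(ax, ay)
    if params.count_terminal_gaps_in_distance:
        lo, hi = 0, L
    else:
        lo, hi = lead, L - trail
    identical = sum(
        1
        for a, b in zip(ax[lo:hi], ay[lo:hi])
        if a == b and a in "ACGT"
    )
    return identical, hi - lo


def nw_distance(x: str, y: str, params: NWParams = NWParams()) -> float:
    """Percent dissimilarity of the optimal global alignment, in [0, 1].

    Arguments are ordered canonically before aligning: distinct optimal
    alignments can differ in their counted columns, and the deterministic
    traceback tie-break depends on argument order, so canonical ordering is
    what makes the distance exactly symmetric.
    """
    if y < x:
        x, y = y, x
    return needleman_wunsch(x, y, params).distance
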
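"""Independent brute-force oracles used only by the test suite."""
from __future__ import annotations

from itertools import combinations


def enumerate_alignments(x: str, y: str):
    """Yield every global alignment of x and y (no gap-gap columns)."""
    if not x and not y:
        yield "", ""
        return
    if x and y:
        for ax, ay in enumerate_alignments(x[1:], y[1:]):
            yield x[0] + ax, y[0] + ay
    if x:
        for ax, ay in enumerate_alignments(x[1:], y):
            yield x[0] + ax, "-" + ay
    if y:
        for ax, ay in enumerate_alignments(x, y[1:]):
            yield "-" + ax, y[0] + ay


def _terminal_runs(ax: str, ay: str) -> tuple[int, int]:
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
    return lead, trail


def score_alignment(ax: str, ay: str, params) -> float:
    """Score one alignment under the same policy as the implementation."""
    lead, trail = _terminal_runs(ax, ay)
    L = len(ax)
    score = 0.0
    for idx, (a, b) in enumerate(zip(ax, ay)):
        if a == "-" or b == "-":
            terminal = idx < lead or idx >= L - trail
            if not (terminal and params.terminal_gaps_free):
                score += params.gap
        else:
            score += params.match if (a == b and a in "ACGT") else params.mismatch
    return score


def distance_of_alignment(ax: str, ay: str, params) -> float:
    lead, trail = _terminal_runs(ax, ay)
    L = len(ax)
    if params.count_terminal_gaps_in_distance:
        lo, hi = 0, L
    else:
        lo, hi = lead, L - trail
    counted = hi - lo
    if counted == 0:
        return 1.0
    identical = sum(
        1 for a, b in zip(ax[lo:hi], ay[lo:hi]) if a == b and a in "ACGT"
    )
    return min(max(1.0 - identical / counted, 0.0), 1.0)


def oracle_nw(x: str, y: str, params) -> tuple[float, set[float]]:
    """(optimal score, set of distances achieved by optimal alignments)."""
    best = float("-inf")
    dists: set[float] = set()
    for ax, ay in enumerate_alignments(x, y):
        s = score_alignment(ax, ay, params)
        if s > best + 1e-9:
            best = s
            dists = {distance_of_alignment(ax, ay, params)}
        elif s >= best - 1e-9:
            dists.add(distance_of_alignment(ax, ay, params))
    return best, dists


def brute_force_confusion(clusters: dict, truth: dict) -> tuple[int, int, int, int]:
    """TP/FP/TN/FN by explicit enumeration of all labeled read pairs."""
    reads = [r for r in clusters if r in truth]
    tp = fp = tn = fn = 0
    for a, b in combinations(reads, 2):
        same_otu = clusters[a] == clusters[b]
        same_strain = truth[a] == truth[b]
        if same_otu and same_strain:
            tp += 1
        elif same_otu:
            fp += 1
        elif same_strain:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn
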
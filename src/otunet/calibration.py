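"""Mapping the user's alignment threshold onto a k-mer distance threshold.

The clustering prefilter operates in k-mer distance space, but users think
in alignment (NW) dissimilarity -- 3% for species-like OTUs. To connect the
two scales, a random subset of the unique sequences is drawn, both distances
are computed for every sampled pair, and the k-mer threshold is set to a
high quantile of the k-mer distances observed among pairs whose NW
dissimilarity is within the user threshold. A high quantile (default 0.99)
trades a few extra candidate pairs passed to the aligner for a near-zero
rate of false prefilter rejections.

If too few sampled pairs qualify (sparse data or a tight threshold), a
least-squares line of k-mer distance on NW distance over *all* sampled pairs
is evaluated at the user threshold instead; if even that is degenerate the
caller is told to supply a k-mer threshold manually rather than silently
mis-calibrating.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .alignment import NWParams, nw_distance
from .kmer import build_codebook, build_profiles, kmer_distance


@dataclass(frozen=True)
class CalibrationResult:
    nw_threshold: float
    kmer_threshold: float
    n_sampled_seqs: int
    n_pairs: int
    n_qualifying_pairs: int
    quantile_used: float
    rng_seed: int
    used_fallback: bool = False

    def to_tsv(self, path) -> Path:
        path = Path(path)
        fields = [
            ("nw_threshold", self.nw_threshold),
            ("kmer_threshold", self.kmer_threshold),
            ("n_sampled_seqs", self.n_sampled_seqs),
            ("n_pairs", self.n_pairs),
            ("n_qualifying_pairs", self.n_qualifying_pairs),
            ("quantile_used", self.quantile_used),
            ("rng_seed", self.rng_seed),
            ("used_fallback", int(self.used_fallback)),
        ]
        with open(path, "w", newline="\n") as fh:
            for name, value in fields:
                fh.write(f"{name}\t{value}\n")
        return path


def pairwise_distance_table(
    sample, params: NWParams, k: int
) -> list[tuple[int, int, float, float]]:
    """(i, j, kmer_d, nw_d) for all n(n-1)/2 pairs of the sample, i < j."""
    sample = list(sample)
    if len(sample) < 2:
        raise ValueError("need at least two sequences for a pairwise table")
    codebook = build_codebook(sample, k)
    profiles = build_profiles(sample, codebook)
    rows = []
    for j in range(1, len(sample)):
        for i in range(j):
            kd = kmer_distance(profiles[i], profiles[j])
            nd = nw_distance(
                getattr(sample[i], "seq", sample[i]),
                getattr(sample[j], "seq", sample[j]),
                params,
            )
            rows.append((i, j, kd, nd))
    return rows


def determine_kmer_threshold(
    uniques,
    nw_threshold: float,
    sample_size: int = 1000,
    quantile: float = 0.99,
    params: NWParams = NWParams(),
    k: int = 6,
    rng_seed: int = 42,
    min_qualifying: int = 50,
) -> CalibrationResult:
    """Calibrate the k-mer prefilter threshold against the NW threshold.

    Runs on dereplicated sequences (duplicate pairs sit at distance zero on
    both axes and carry no information). Fully reproducible for a fixed
    ``rng_seed``.
    """
    if not 0 < nw_threshold < 1:
        raise ValueError(f"nw_threshold must be in (0, 1), got {nw_threshold}")
    if sample_size < 2:
        raise ValueError(f"sample_size must be >= 2, got {sample_size}")
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    uniques = list(uniques)
    if len(uniques) < 2:
        raise ValueError("need at least two unique sequences to calibrate")

    rng = np.random.default_rng(rng_seed)
    n_sampled = min(sample_size, len(uniques))
    idx = sorted(rng.choice(len(uniques), size=n_sampled, replace=False).tolist())
    sample = [uniques[i] for i in idx]

    table = pairwise_distance_table(sample, params, k)
    kmer_d = np.array([r[2] for r in table])
    nw_d = np.array([r[3] for r in table])
    qualifying = kmer_d[nw_d <= nw_threshold]

    if qualifying.size >= min_qualifying:
        kmer_threshold = float(np.quantile(qualifying, quantile))
        used_fallback = False
    else:
        if np.ptp(nw_d) == 0.0:
            raise ValueError(
                "calibration failed: fewer than "
                f"{min_qualifying} sampled pairs fall within the NW threshold and "
                "all sampled NW distances are equal; set the k-mer threshold manually"
            )
        fit = stats.linregress(nw_d, kmer_d)
        kmer_threshold = float(fit.intercept + fit.slope * nw_threshold)
        used_fallback = True
        if kmer_threshold <= 0:
            raise ValueError(
                "calibration failed: the regression fallback predicts a "
                f"non-positive k-mer threshold ({kmer_threshold:.4f}); "
                "set the k-mer threshold manually"
            )
    kmer_threshold = min(kmer_threshold, 1.0)

    return CalibrationResult(
        nw_threshold=nw_threshold,
        kmer_threshold=kmer_threshold,
        n_sampled_seqs=n_sampled,
        n_pairs=len(table),
        n_qualifying_pairs=int(qualifying.size),
        quantile_used=quantile,
        rng_seed=rng_seed,
        used_fallback=used_fallback,
    )
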
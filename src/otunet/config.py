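"""Run-level configuration shared by the pipeline, the CLI, and scripts."""
from __future__ import annotations

import os
from dataclasses import dataclass, field

from .alignment import NWParams


@dataclass
class RunConfig:
    """All knobs of an end-to-end clustering run.

    ``nw_threshold`` is the dissimilarity at which two reads belong to the
    same OTU (0.03 resolves species-like units, 0.05 genus-like).
    ``kmer_threshold``, when given, bypasses calibration entirely.
    ``granularity`` is the number of sequence pairs per scheduler task;
    2000 is the default. ``workers`` defaults to the available cores.
    """

    nw_threshold: float = 0.03
    kmer_threshold: float | None = None
    k: int = 6
    granularity: int = 2000
    workers: int | None = None
    sample_size: int = 1000
    quantile: float = 0.99
    min_qualifying: int = 50
    nw_params: NWParams = field(default_factory=NWParams)
    rng_seed: int = 42

    def __post_init__(self):
        if not 0 < self.nw_threshold < 1:
            raise ValueError(f"nw_threshold must be in (0, 1), got {self.nw_threshold}")
        if self.kmer_threshold is not None and not 0 < self.kmer_threshold <= 1:
            raise ValueError(f"kmer_threshold must be in (0, 1], got {self.kmer_threshold}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.granularity < 1:
            raise ValueError(f"granularity must be >= 1, got {self.granularity}")
        if self.workers is not None and self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        if not 0 < self.quantile <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {self.quantile}")

    @property
    def effective_workers(self) -> int:
        if self.workers is not None:
            return self.workers
        return os.cpu_count() or 1
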
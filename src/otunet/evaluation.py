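"""Pair-counting clustering accuracy against ground-truth strain labels.

Every unordered pair of labeled reads falls into one of four categories:
same strain and same OTU (TP), different strain but same OTU (FP), same
strain but different OTUs (FN), different strain and different OTUs (TN).
Precision is TP/(TP+FP), recall TP/(TP+FN), and the combined score is the
weighted F-measure

    F_beta = (1 + beta^2) P R / (beta^2 P + R)

with beta = 2 by default, weighting recall over precision; beta = 1 gives
the plain harmonic mean. Counts are computed from a per-(OTU, strain)
contingency table with pair-count binomials, which is algebraically equal
to enumerating all m(m-1)/2 pairs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_reads: int
    n_unlabeled: int = 0

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AccuracyReport:
    precision: float
    recall: float
    f_beta: float
    beta: float
    counts: ConfusionCounts


def _comb2(a: np.ndarray) -> np.ndarray:
    return a * (a - 1) // 2


def confusion_counts(
    clusters: Mapping[str, str], truth: Mapping[str, str]
) -> ConfusionCounts:
    """Count TP/FP/TN/FN read pairs for a clustering against strain labels.

    Reads present in ``clusters`` but missing from ``truth`` are excluded
    with a warning; an empty intersection is an error.
    """
    common = [rid for rid in clusters if rid in truth]
    n_unlabeled = len(clusters) - len(common)
    if n_unlabeled:
        warnings.warn(
            f"{n_unlabeled} clustered reads have no truth label and are excluded",
            stacklevel=2,
        )
    if not common:
        raise ValueError("no clustered read has a ground-truth label")

    df = pd.DataFrame(
        {"otu": [clusters[r] for r in common], "strain": [truth[r] for r in common]}
    )
    table = pd.crosstab(df["otu"], df["strain"]).to_numpy(dtype=np.int64)
    m = len(common)
    total = m * (m - 1) // 2
    tp = int(_comb2(table).sum())
    same_otu = int(_comb2(table.sum(axis=1)).sum())
    same_strain = int(_comb2(table.sum(axis=0)).sum())
    fp = same_otu - tp
    fn = same_strain - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_reads=m, n_unlabeled=n_unlabeled)


def accuracy_report(counts: ConfusionCounts, beta: float = 2.0) -> AccuracyReport:
    """Precision, recall, and F_beta from pair counts (empty denominators -> 1)."""
    precision = 1.0 if counts.tp + counts.fp == 0 else counts.tp / (counts.tp + counts.fp)
    recall = 1.0 if counts.tp + counts.fn == 0 else counts.tp / (counts.tp + counts.fn)
    if precision == 0.0 and recall == 0.0:
        f_beta = 0.0
    else:
        b2 = beta * beta
        f_beta = (1 + b2) * precision * recall / (b2 * precision + recall)
    return AccuracyReport(precision=precision, recall=recall, f_beta=f_beta, beta=beta, counts=counts)


def count_otus(clusters) -> int:
    """Number of non-empty OTUs in an assignment map or an OTU collection."""
    if isinstance(clusters, Mapping):
        names = set(clusters.values())
    else:
        names = {getattr(o, "name", o) for o in clusters}
    if not names:
        raise ValueError("no OTUs: empty clustering")
    return len(names)


def read_truth_tsv(path) -> dict[str, str]:
    """Two-column TSV (read_id, strain_label) -> dict."""
    path = Path(path)
    truth: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            truth[parts[0]] = parts[1]
    if not truth:
        raise ValueError(f"no labels found in {path}")
    return truth


def read_assignment(path) -> dict[str, str]:
    """read_id -> OTU map from a members FASTA or a two-column TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from .seqio import read_members_fasta

        return read_members_fasta(path)
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            assignment[parts[0]] = parts[1]
    if not assignment:
        raise ValueError(f"no assignments found in {path}")
    return assignment


def write_report_tsv(report: AccuracyReport, n_otus: int, path) -> Path:
    path = Path(path)
    c = report.counts
    with open(path, "w", newline="\n") as fh:
        fh.write("metric\tvalue\n")
        for name, value in [
            ("n_reads", c.n_reads),
            ("n_otus", n_otus),
            ("TP", c.tp),
            ("FP", c.fp),
            ("TN", c.tn),
            ("FN", c.fn),
            ("precision", f"{report.precision:.6f}"),
            ("recall", f"{report.recall:.6f}"),
            (f"F{report.beta:g}", f"{report.f_beta:.6f}"),
        ]:
            fh.write(f"{name}\t{value}\n")
    return path
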
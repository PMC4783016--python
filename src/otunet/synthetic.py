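"""Mock-community generator with known OTU structure.

Emulates the kind of even-concentration mock community used to benchmark
16S clustering: a small number of divergent "strain" center sequences, an
equal number of reads per strain derived from each center by independent
point substitutions and single-base indels, and a configurable fraction of
reads that are byte-identical copies of earlier reads of the same strain
(real pyrosequencing datasets carry on the order of 20-37% duplicates).
Every read carries a ground-truth strain label, so clustering accuracy can
be scored exactly.

Strain centers are homologous variants of one random ancestral template,
each derived by substituting a fraction of sites equal to the minimum
divergence (two such centers then differ at roughly twice that fraction of
sites). If any center pair still falls below the divergence floor, the
closer member of the closest pair is re-derived until all pairwise NW
dissimilarities clear it (bounded retries). Homology matters: real 16S
amplicons from different strains align end to end, and fully random center
strings would instead produce spurious short high-identity overlaps under
end-gap-free alignment.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import NWParams, nw_distance
from .seqio import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MockCommunitySpec:
    """Study conditions of one simulated community.

    Defaults model a 21-strain even mock community of ~450 bp amplicons with
    mild (sub-percent) read error and a quarter of the reads duplicated.
    """

    n_strains: int = 21
    reads_per_strain: int = 20
    center_length: int = 450
    min_center_divergence: float = 0.10
    read_mutation_rate: float = 0.005
    indel_rate: float = 0.0005
    duplicate_fraction: float = 0.25
    rng_seed: int = 42

    def __post_init__(self):
        if self.n_strains < 1:
            raise ValueError(f"n_strains must be >= 1, got {self.n_strains}")
        if self.reads_per_strain < 1:
            raise ValueError(f"reads_per_strain must be >= 1, got {self.reads_per_strain}")
        for name in ("read_mutation_rate", "indel_rate", "duplicate_fraction", "min_center_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class LabeledReadSet:
    records: list[SequenceRecord]
    truth: dict[str, str]  # read id -> strain label
    centers: dict[str, str]  # strain label -> center sequence
    n_duplicates: int  # reads that are planted exact copies


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    # substitutions: uniform over the three alternative bases
    hits = np.flatnonzero(rng.random(n) < sub_rate)
    for p in hits:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    # single-base indels, insertion or deletion with equal probability
    out = []
    indels = rng.random(n) < indel_rate
    ins_flags = rng.random(n) < 0.5
    for p in range(n):
        if indels[p]:
            if ins_flags[p]:
                out.append(int(rng.choice(_BASES)))
                out.append(int(arr[p]))
            # deletion: drop the base
        else:
            out.append(int(arr[p]))
    if not out:  # pathological all-deleted read; keep one base
        out.append(int(rng.choice(_BASES)))
    return bytes(out).decode("ascii")


def _diverge_centers(
    rng: np.random.Generator, spec: MockCommunitySpec, params: NWParams
) -> list[str]:
    ancestor = _random_seq(rng, spec.center_length)
    # substituting each center at the floor rate puts center *pairs* near
    # twice the floor in expectation, leaving slack above the minimum
    rate = max(spec.min_center_divergence, 0.01)

    def derive() -> str:
        return _mutate(rng, ancestor, sub_rate=rate, indel_rate=0.0)

    centers = [derive() for _ in range(spec.n_strains)]
    if spec.n_strains == 1:
        return centers
    max_tries = 50 * spec.n_strains
    for _ in range(max_tries):
        worst = None
        worst_d = np.inf
        for a in range(spec.n_strains):
            for b in range(a + 1, spec.n_strains):
                d = nw_distance(centers[a], centers[b], params)
                if d < worst_d:
                    worst_d = d
                    worst = b
        if worst_d >= spec.min_center_divergence:
            return centers
        centers[worst] = derive()
    raise RuntimeError(
        f"could not push all center pairs to >= {spec.min_center_divergence} "
        f"dissimilarity in {max_tries} tries; use longer centers or fewer strains"
    )


def generate_mock_community(
    spec: MockCommunitySpec, params: NWParams | None = None
) -> LabeledReadSet:
    """Draw a fully labeled community; reproducible for a fixed seed.

    Strain abundances are even. The duplicate quota round(duplicate_fraction
    * total_reads) is spread as evenly as possible across strains, and each
    duplicated slot is replaced by an exact copy of a randomly chosen earlier
    read of the same strain.
    """
    params = params or NWParams()
    rng = np.random.default_rng(spec.rng_seed)
    centers = _diverge_centers(rng, spec, params)
    labels = [f"strain_{s + 1:02d}" for s in range(spec.n_strains)]

    total = spec.n_strains * spec.reads_per_strain
    n_dup = round(spec.duplicate_fraction * total)
    if n_dup > spec.n_strains * (spec.reads_per_strain - 1):
        raise ValueError(
            f"duplicate_fraction {spec.duplicate_fraction} needs more duplicate "
            "slots than non-first reads exist; lower it or add reads per strain"
        )
    base_quota, extra = divmod(n_dup, spec.n_strains)
    quotas = [
        min(base_quota + (1 if s < extra else 0), spec.reads_per_strain - 1)
        for s in range(spec.n_strains)
    ]
    shortfall = n_dup - sum(quotas)
    for s in range(spec.n_strains):  # redistribute if some strain capped out
        if shortfall == 0:
            break
        room = (spec.reads_per_strain - 1) - quotas[s]
        take = min(room, shortfall)
        quotas[s] += take
        shortfall -= take

    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for s, label in enumerate(labels):
        n_mut = spec.reads_per_strain - quotas[s]
        strain_seqs: list[str] = []
        for r in range(spec.reads_per_strain):
            if r < n_mut:
                seq = _mutate(rng, centers[s], spec.read_mutation_rate, spec.indel_rate)
            else:
                seq = strain_seqs[int(rng.integers(0, r))]
            strain_seqs.append(seq)
            rid = f"S{s + 1:02d}_r{r + 1:04d}"
            records.append(SequenceRecord(rid, seq))
            truth[rid] = label
    return LabeledReadSet(
        records=records,
        truth=truth,
        centers=dict(zip(labels, centers)),
        n_duplicates=sum(quotas),
    )


def expected_within_divergence(spec: MockCommunitySpec) -> float:
    """Analytic expectation of read-to-center NW dissimilarity.

    Each substitution adds one mismatching column and each indel one gap
    column, so to first order the expectation is the sum of the two rates.
    """
    return spec.read_mutation_rate + spec.indel_rate


def write_mock_community(readset: LabeledReadSet, fasta_path, truth_path) -> tuple[Path, Path]:
    """Write the community as FASTA plus a two-column truth TSV."""
    fasta_path, truth_path = Path(fasta_path), Path(truth_path)
    with open(fasta_path, "w", newline="\n") as fh:
        for rec in readset.records:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(truth_path, "w", newline="\n") as fh:
        for rec in readset.records:
            fh.write(f"{rec.id}\t{readset.truth[rec.id]}\n")
    return fasta_path, truth_path
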
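"""FASTA input, dereplication, and the three standard OTU output files.

Reads are collapsed to unique sequences (exact full-length string identity)
before any distance work; each representative carries an abundance count and
the list of original read ids, which are folded back into the final clusters
so no read is ever lost. Output follows the common three-file convention of
OTU pipelines: a per-read members FASTA, a one-record-per-OTU representatives
FASTA, and a tab-separated table of OTU sizes.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord


@dataclass(frozen=True)
class SequenceRecord:
    """One read: a unique identifier and an uppercase nucleotide string."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class DereplicatedSet:
    """Unique sequences with abundances and the original-id recovery map.

    ``uniques`` keeps first-occurrence input order; ``members[i]`` lists the
    read ids collapsed onto representative ``i``, the representative's own id
    first; ``abundance[i] == len(members[i])``.
    """

    uniques: list[SequenceRecord]
    abundance: list[int]
    members: list[list[str]]

    @property
    def n_reads(self) -> int:
        return sum(self.abundance)

    def read_to_unique(self) -> dict[str, int]:
        return {rid: i for i, mem in enumerate(self.members) for rid in mem}


@dataclass(frozen=True)
class OTU:
    """A named final cluster expanded to original read ids."""

    name: str
    seed_id: str
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a plain or gzipped FASTA file into normalized records.

    Sequences are uppercased and U is mapped to T (RNA-style input). Raises
    ``ValueError`` for an empty file, a duplicated id, or an empty sequence.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"record {rec.id!r} has an empty sequence")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def dereplicate(records: Iterable[SequenceRecord]) -> DereplicatedSet:
    """Collapse exact-string duplicates onto their first occurrence."""
    records = list(records)
    if not records:
        raise ValueError("cannot dereplicate an empty record list")
    index: dict[str, int] = {}
    uniques: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in records:
        i = index.get(rec.seq)
        if i is None:
            index[rec.seq] = len(uniques)
            uniques.append(rec)
            members.append([rec.id])
        else:
            members[i].append(rec.id)
    return DereplicatedSet(uniques, [len(m) for m in members], members)


def rehydrate(result, derep: DereplicatedSet) -> list[OTU]:
    """Expand clusters over unique indices into named OTUs over read ids.

    Every unique index must appear in exactly one cluster. OTUs are named
    ``OTU_0001``, ... by decreasing size, ties broken by seed read id.
    """
    n = len(derep.uniques)
    assigned: set[int] = set()
    for c in result.clusters:
        for u in c.members:
            if u in assigned:
                raise ValueError(f"unique index {u} assigned to more than one cluster")
            assigned.add(u)
    missing = sorted(set(range(n)) - assigned)
    if missing:
        raise ValueError(f"unique indices left unassigned: {missing[:10]}")

    raw: list[tuple[str, tuple[str, ...]]] = []
    for c in result.clusters:
        seed_id = derep.uniques[c.seed].id
        ids = list(derep.members[c.seed])
        for u in sorted(c.members - {c.seed}):
            ids.extend(derep.members[u])
        raw.append((seed_id, tuple(ids)))
    raw.sort(key=lambda t: (-len(t[1]), t[0]))
    width = max(4, len(str(len(raw))))
    return [
        OTU(f"OTU_{i + 1:0{width}d}", seed_id, ids)
        for i, (seed_id, ids) in enumerate(raw)
    ]


def write_outputs(otus: list[OTU], derep: DereplicatedSet, outdir) -> tuple[Path, Path, Path]:
    """Write members FASTA, representatives FASTA, and the OTU size table.

    Members FASTA headers are ``<OTU_name>|<read_id>``; representatives FASTA
    headers are ``<OTU_name>|<seed_read_id>``; the counts file has one
    tab-separated ``<OTU_name>\\t<size>`` line per OTU, in decreasing size
    order (ties by OTU name).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    seq_of: dict[str, str] = {}
    for i, mem in enumerate(derep.members):
        s = derep.uniques[i].seq
        for rid in mem:
            seq_of[rid] = s

    members_path = outdir / "otu_members.fasta"
    reps_path = outdir / "otu_representatives.fasta"
    counts_path = outdir / "otu_counts.tsv"

    with open(members_path, "w", newline="\n") as fh:
        SeqIO.write(
            (
                _BioRecord(Seq(seq_of[rid]), id=f"{otu.name}|{rid}", description="")
                for otu in otus
                for rid in otu.member_ids
            ),
            fh,
            "fasta",
        )
    with open(reps_path, "w", newline="\n") as fh:
        SeqIO.write(
            (
                _BioRecord(Seq(seq_of[otu.seed_id]), id=f"{otu.name}|{otu.seed_id}", description="")
                for otu in otus
            ),
            fh,
            "fasta",
        )
    ordered = sorted(otus, key=lambda o: (-o.size, o.name))
    with open(counts_path, "w", newline="\n") as fh:
        for otu in ordered:
            fh.write(f"{otu.name}\t{otu.size}\n")
    return members_path, reps_path, counts_path


def read_members_fasta(path) -> dict[str, str]:
    """Re-parse a members FASTA into a read-id -> OTU-name assignment map."""
    path = Path(path)
    assignment: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            otu_name, _, read_id = rec.id.partition("|")
            if not read_id:
                raise ValueError(f"header {rec.id!r} is not of the form OTU|read_id")
            if read_id in assignment:
                raise ValueError(f"read id {read_id!r} listed twice")
            assignment[read_id] = otu_name
    if not assignment:
        raise ValueError(f"no records found in {path}")
    return assignment
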
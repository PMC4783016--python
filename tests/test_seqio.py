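"""FASTA parsing, dereplication, duplicate recovery, and output files."""
import gzip

import numpy as np
import pytest
from hypothesis import given, strategies as st

from otunet import SequenceRecord, dereplicate, read_fasta, rehydrate, write_outputs
from otunet.clustering import Cluster, ClusteringResult
from otunet.seqio import read_members_fasta


def write_fasta(path, entries):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
    return path


class TestReadFasta:
    def test_two_records_in_file_order(self, tmp_path):
        p = write_fasta(tmp_path / "a.fasta", [("r1", "ACGT"), ("r2", "GGTT")])
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["r1", "r2"]
        assert [r.seq for r in recs] == ["ACGT", "GGTT"]

    def test_lowercase_and_rna_normalized(self, tmp_path):
        p = write_fasta(tmp_path / "a.fasta", [("r1", "acgu")])
        assert read_fasta(p)[0].seq == "ACGT"

    def test_wrapped_sequence_lines_accepted(self, tmp_path):
        p = tmp_path / "w.fasta"
        p.write_text(">r1\nACGT\nACGT\n>r2\nTTTT\n")
        recs = read_fasta(p)
        assert recs[0].seq == "ACGTACGT" and recs[1].seq == "TTTT"

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "a.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">r1\nACGT\n")
        assert read_fasta(p)[0].seq == "ACGT"

    def test_duplicate_id_error_names_the_id(self, tmp_path):
        p = write_fasta(tmp_path / "a.fasta", [("dup", "ACGT"), ("dup", "GGTT")])
        with pytest.raises(ValueError, match="dup"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">r1\n\n>r2\nACGT\n")
        with pytest.raises(ValueError, match="empty sequence"):
            read_fasta(p)


class TestDereplicate:
    def test_exact_duplicates_collapse_to_first_occurrence(self):
        recs = [
            SequenceRecord("r1", "ACGT"),
            SequenceRecord("r2", "ACGT"),
            SequenceRecord("r3", "GGGG"),
            SequenceRecord("r4", "TTTT"),
            SequenceRecord("r5", "ACGT"),
        ]
        d = dereplicate(recs)
        assert [u.id for u in d.uniques] == ["r1", "r3", "r4"]
        assert d.abundance == [3, 1, 1]
        assert d.members[0] == ["r1", "r2", "r5"]

    def test_all_distinct_is_identity(self):
        recs = [SequenceRecord(f"r{i}", s) for i, s in enumerate(["AA", "CC", "GG"])]
        d = dereplicate(recs)
        assert d.uniques == recs and d.abundance == [1, 1, 1]

    def test_single_repeated_string(self):
        recs = [SequenceRecord(f"r{i}", "ACGT") for i in range(10)]
        d = dereplicate(recs)
        assert len(d.uniques) == 1 and d.abundance == [10]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dereplicate([])

    @given(st.lists(st.sampled_from(["ACGT", "AAAA", "CGCG", "TTAA"]), min_size=1, max_size=30))
    def test_abundance_sums_to_read_count(self, seqs):
        recs = [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        d = dereplicate(recs)
        assert sum(d.abundance) == len(recs)
        ids = [rid for mem in d.members for rid in mem]
        assert sorted(ids) == sorted(r.id for r in recs)
        assert all(d.abundance[i] == len(d.members[i]) for i in range(len(d.uniques)))


class TestRehydrate:
    def test_abundances_sum_into_otu_size(self):
        recs = [
            SequenceRecord("r1", "ACGT"),
            SequenceRecord("r2", "ACGT"),
            SequenceRecord("r3", "GGGG"),
        ]
        d = dereplicate(recs)
        result = ClusteringResult([Cluster(seed=0, members={0, 1})])
        otus = rehydrate(result, d)
        assert len(otus) == 1 and otus[0].size == 3
        assert otus[0].seed_id == "r1"

    def test_unit_abundances_preserve_cluster_shape(self):
        recs = [SequenceRecord(f"r{i}", s) for i, s in enumerate(["AA", "CC", "GG", "TT"])]
        d = dereplicate(recs)
        result = ClusteringResult(
            [Cluster(seed=0, members={0, 1}), Cluster(seed=2, members={2, 3})]
        )
        otus = rehydrate(result, d)
        assert sorted(o.size for o in otus) == [2, 2]
        assert sum(o.size for o in otus) == 4

    def test_total_reads_conserved(self):
        recs = (
            [SequenceRecord(f"a{i}", "AAAA") for i in range(3)]
            + [SequenceRecord("b", "CCCC")]
            + [SequenceRecord(f"c{i}", "GGGG") for i in range(2)]
            + [SequenceRecord("d", "TTTT")]
        )
        d = dereplicate(recs)
        result = ClusteringResult(
            [Cluster(seed=0, members={0, 1}), Cluster(seed=2, members={2, 3})]
        )
        assert sum(o.size for o in rehydrate(result, d)) == 7

    def test_unassigned_unique_is_an_error(self):
        recs = [SequenceRecord("r1", "AA"), SequenceRecord("r2", "CC")]
        d = dereplicate(recs)
        with pytest.raises(ValueError, match="unassigned"):
            rehydrate(ClusteringResult([Cluster(seed=0, members={0})]), d)

    def test_naming_by_decreasing_size(self):
        recs = [SequenceRecord(f"r{i}", s) for i, s in enumerate(["AA", "CC", "GG"])]
        d = dereplicate(recs)
        result = ClusteringResult(
            [Cluster(seed=2, members={2}), Cluster(seed=0, members={0, 1})]
        )
        otus = rehydrate(result, d)
        assert otus[0].name == "OTU_0001" and otus[0].size == 2
        assert otus[1].name == "OTU_0002" and otus[1].size == 1


class TestOutputs:
    @pytest.fixture()
    def small_result(self):
        recs = [
            SequenceRecord("r1", "ACGT"),
            SequenceRecord("r2", "ACGT"),
            SequenceRecord("r3", "GGGG"),
            SequenceRecord("r4", "TTTT"),
        ]
        d = dereplicate(recs)
        result = ClusteringResult(
            [Cluster(seed=0, members={0, 1}), Cluster(seed=2, members={2})]
        )
        return rehydrate(result, d), d

    def test_counts_file_sorted_by_decreasing_size(self, small_result, tmp_path):
        otus, d = small_result
        _, _, counts = write_outputs(otus, d, tmp_path)
        lines = counts.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == ["OTU_0001", "3"]

    def test_representative_count_equals_otu_count(self, small_result, tmp_path):
        otus, d = small_result
        _, reps, _ = write_outputs(otus, d, tmp_path)
        assert reps.read_text().count(">") == len(otus)

    def test_members_fasta_partitions_all_reads(self, small_result, tmp_path):
        otus, d = small_result
        members, _, _ = write_outputs(otus, d, tmp_path)
        assignment = read_members_fasta(members)
        assert sorted(assignment) == ["r1", "r2", "r3", "r4"]
        assert assignment["r2"] == assignment["r1"] == "OTU_0001"


def test_derep_rehydrate_round_trip_conserves_read_ids():
    rng = np.random.default_rng(7)
    pool = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(5)]
    recs = [
        SequenceRecord(f"r{i}", pool[int(rng.integers(0, len(pool)))])
        for i in range(60)
    ]
    d = dereplicate(recs)
    result = ClusteringResult(
        [Cluster(seed=i, members={i}) for i in range(len(d.uniques))]
    )
    otus = rehydrate(result, d)
    out_ids = sorted(rid for o in otus for rid in o.member_ids)
    assert out_ids == sorted(r.id for r in recs)
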
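"""Reading, writing and assembling aligned loci and sample panels."""

import numpy as np
import pytest

from flaxpopgen.errors import AlignmentError, ConsistencyError, FormatError
from flaxpopgen.seq_io import (
    GroupPanel,
    LocusAlignment,
    MultiLocusDataset,
    SequenceRecord,
    concatenate,
    load_sample_panel,
    read_fasta_alignment,
    write_fasta_alignment,
)
from flaxpopgen.datasets import LOCUS_LENGTHS


def make_aln(seqs, locus_id="test"):
    return LocusAlignment(
        locus_id, [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs, 1)]
    )


class TestFastaRoundTrip:
    def test_write_read_identity(self, tmp_path):
        aln = make_aln(["ACGTACGT" * 10, "ACGAACGT" * 10])
        path = tmp_path / "locus.fasta"
        write_fasta_alignment(aln, path)
        back = read_fasta_alignment(path, "test")
        assert [r.sample_id for r in back.records] == ["s1", "s2"]
        assert [r.residues for r in back.records] == [r.residues for r in aln.records]

    def test_wrapped_and_unwrapped_accepted(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a desc ignored\nACGT\nACGT\n>b\nACGTACGT\n")
        aln = read_fasta_alignment(path, "x")
        assert aln.length == 8
        assert aln.sample_ids == ["a", "b"]

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a\nacgt\n>b\nACGT\n")
        aln = read_fasta_alignment(path, "x")
        assert aln.records[0].residues == "ACGT"

    def test_ragged_lengths_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a\n" + "A" * 100 + "\n>b\n" + "A" * 99 + "\n")
        with pytest.raises(AlignmentError, match="b"):
            read_fasta_alignment(path, "x")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with pytest.raises(FormatError):
            read_fasta_alignment(path, "x")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta_alignment(path, "x")


def test_synthetic_study_locus_dimensions(default_study, tmp_path):
    """The generator's 031B/A locus reads back with n=48, L=346."""
    aln = default_study.loci["031B/A"]
    path = tmp_path / "locus.fasta"
    write_fasta_alignment(aln, path)
    back = read_fasta_alignment(path, "031B/A")
    assert back.n == 48
    assert back.length == 346


class TestSamplePanel:
    def _write(self, tmp_path, rows):
        path = tmp_path / "panel.tsv"
        path.write_text("sample_id\tgroup\n" + "".join(f"{s}\t{g}\n" for s, g in rows))
        return path

    def test_study_shaped_group_sizes(self, tmp_path):
        rows = (
            [(f"P{i}", "pale") for i in range(10)]
            + [(f"D{i}", "dehiscent") for i in range(8)]
            + [(f"F{i}", "fiber") for i in range(10)]
            + [(f"O{i}", "oil") for i in range(10)]
            + [(f"W{i}", "winter") for i in range(10)]
        )
        panel = load_sample_panel(self._write(tmp_path, rows))
        assert panel.group_sizes == {
            "pale": 10, "dehiscent": 8, "fiber": 10, "oil": 10, "winter": 10
        }

    def test_duplicate_sample_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="duplicate"):
            load_sample_panel(self._write(tmp_path, [("a", "x"), ("a", "y")]))

    def test_empty_group_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="empty group"):
            load_sample_panel(self._write(tmp_path, [("a", "")]))

    def test_mismatched_ids_rejected_on_assembly(self):
        aln = make_aln(["ACGT", "ACGA"])
        panel = GroupPanel({"s1": "a", "other": "b"})
        with pytest.raises(ConsistencyError):
            MultiLocusDataset({"x": aln}, panel)


class TestConcatenate:
    def test_total_length_matches_study(self, default_study):
        concat, offsets = concatenate(default_study)
        assert concat.length == 6886 == sum(LOCUS_LENGTHS.values())
        assert offsets["031B/A"] == (0, 346)
        ends = [e for _, e in offsets.values()]
        assert max(ends) == 6886

    def test_single_locus_identity(self):
        aln = make_aln(["ACGT", "ACGA"])
        ds = MultiLocusDataset({"x": aln})
        concat, offsets = concatenate(ds)
        assert [r.residues for r in concat.records] == ["ACGT", "ACGA"]
        assert offsets == {"x": (0, 4)}

    def test_order_permutation_preserves_column_multisets(self, small_study):
        c1, _ = concatenate(small_study, ["L1", "L2", "L3", "L4"])
        c2, _ = concatenate(small_study, ["L4", "L2", "L1", "L3"])
        for r1, r2 in zip(c1.records, c2.records):
            assert r1.sample_id == r2.sample_id
            assert sorted(r1.residues) == sorted(r2.residues)

    def test_missing_sample_rejected(self):
        a = make_aln(["ACGT", "ACGA"])
        b = LocusAlignment("y", [SequenceRecord("s1", "ACGT"), SequenceRecord("s3", "ACGT")])
        with pytest.raises(ConsistencyError):
            MultiLocusDataset({"x": a, "y": b})


def test_statistics_invariant_to_record_order(small_study):
    from flaxpopgen.diversity import nucleotide_diversity, segregating_sites

    aln = small_study.loci["L1"]
    rev = LocusAlignment("L1", list(reversed(aln.records)))
    assert segregating_sites(aln) == segregating_sites(rev)
    assert nucleotide_diversity(aln) == pytest.approx(nucleotide_diversity(rev))
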
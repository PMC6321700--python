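"""I/O round-trips, the whole-read filter, ORF extraction, redundancy
collapse and assembly statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given, settings
from hypothesis import strategies as st

from avirescue import seqio_qc as sq
from oracles import n50_oracle


def _rec(rid, seq, quals=None):
    r = SeqRecord(Seq(seq), id=rid, description="")
    if quals is not None:
        r.letter_annotations["phred_quality"] = quals
    return r


class TestFastaFastqIO:
    def test_fasta_round_trip(self, tmp_path):
        recs = [_rec("a", "ACGT"), _rec("b", "GGCC" * 40), _rec("c", "T")]
        path = tmp_path / "x.fa"
        sq.write_fasta(recs, path)
        back = sq.read_fasta(path, alphabet="nucleotide")
        assert [(r.id, str(r.seq)) for r in back] == [(r.id, str(r.seq)) for r in recs]

    def test_wrapped_equals_unwrapped(self, tmp_path):
        seq = "ACGT" * 50
        (tmp_path / "wrapped.fa").write_text(
            ">x\n" + "\n".join(seq[i : i + 30] for i in range(0, len(seq), 30)) + "\n"
        )
        (tmp_path / "flat.fa").write_text(f">x\n{seq}\n")
        a = sq.read_fasta(tmp_path / "wrapped.fa")
        b = sq.read_fasta(tmp_path / "flat.fa")
        assert str(a[0].seq) == str(b[0].seq)

    def test_empty_file_is_empty_set(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert sq.read_fasta(p) == []

    def test_malformed_fasta_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>x\nACGT\n")
        with pytest.raises(sq.SeqFormatError, match="line 1"):
            sq.read_fasta(p)

    def test_alphabet_validation(self, tmp_path):
        p = tmp_path / "x.fa"
        sq.write_fasta([_rec("a", "MKVLLL")], p)
        with pytest.raises(sq.SeqFormatError):
            sq.read_fasta(p, alphabet="nucleotide")
        assert len(sq.read_fasta(p, alphabet="protein")) == 1

    def test_fastq_quality_length_mismatch(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r1\nACGTACGT\n+\nIIII\n")
        with pytest.raises(sq.SeqFormatError):
            sq.read_fastq(p)

    def test_fastq_round_trip(self, tmp_path):
        recs = [_rec("r1", "ACGT", [40, 40, 20, 40])]
        p = tmp_path / "x.fq"
        sq.write_fastq(recs, p)
        back = sq.read_fastq(p)
        assert str(back[0].seq) == "ACGT"
        assert back[0].letter_annotations["phred_quality"] == [40, 40, 20, 40]


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,n_q20,expect_kept,expect_reason",
        [
            (69, 0, False, "length"),  # below the 70 bp floor
            (150, 10, False, "quality"),  # 6.7% of bases below Q30
            (150, 5, True, ""),  # 3.3% below Q30: allowed
            (70, 0, True, ""),
        ],
    )
    def test_filter_rule(self, length, n_q20, expect_kept, expect_reason):
        quals = [20] * n_q20 + [40] * (length - n_q20)
        reads = [_rec("r", "A" * length, quals)]
        kept, log = sq.filter_reads(reads)
        assert (len(kept) == 1) is expect_kept
        if not expect_kept:
            assert log[0]["reason"] == expect_reason

    def test_idempotent(self, rng):
        reads = [
            _rec(f"r{i}", "A" * int(n), [int(q)] * int(n))
            for i, (n, q) in enumerate(zip(rng.integers(50, 200, 50), rng.integers(10, 41, 50)))
        ]
        kept, _ = sq.filter_reads(reads)
        kept2, log2 = sq.filter_reads(kept)
        assert len(kept2) == len(kept)
        assert all(row["verdict"] == "kept" for row in log2)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,pep", [("ATGAAACCC", "MKP"), ("ATGTAA", "M*"), ("TTTGGG", "FG")]
    )
    def test_examples(self, cds, pep):
        assert sq.translate(cds) == pep

    def test_length_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            sq.translate("ATGAA")

    def test_internal_stop_strict(self):
        with pytest.raises(ValueError, match="internal stop"):
            sq.translate("ATGTAAAAA")
        assert sq.translate("ATGTAAAAA", strict=False) == "M*K"


class TestFindLongestOrf:
    def test_hand_scanned_example(self):
        orf = sq.find_longest_orf("AAATGAAACCCTAGAA", min_length_aa=1)
        assert orf.peptide == "MKP"
        assert orf.strand == "+"
        assert (orf.orf_start, orf.orf_end) == (2, 14)
        assert orf.orf_sequence == "ATGAAACCCTAG"

    def test_reverse_complement_reports_minus_strand(self):
        rc = str(Seq("AAATGAAACCCTAGAA").reverse_complement())
        orf = sq.find_longest_orf(rc, min_length_aa=1)
        assert orf.peptide == "MKP"
        assert orf.strand == "-"

    def test_no_start_codon(self):
        assert sq.find_longest_orf("CCCCCC", min_length_aa=1, require_start=True) is None

    def test_truncated_span_without_start(self):
        orf = sq.find_longest_orf("AAACCCGGG", min_length_aa=1, require_start=False)
        assert orf is not None and len(orf.peptide) == 3

    def test_min_length_filter(self):
        assert sq.find_longest_orf("AAATGAAACCCTAGAA", min_length_aa=10) is None

    def test_invalid_characters(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            sq.find_longest_orf("ACGT!!")

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=80))
    def test_strand_symmetric_peptides(self, seq):
        rc = str(Seq(seq).reverse_complement())
        a = sq.find_longest_orf(seq, min_length_aa=1, require_start=False)
        b = sq.find_longest_orf(rc, min_length_aa=1, require_start=False)
        assert (a is None) == (b is None)
        if a is not None:
            # both scans see the same six frames; the winning length is
            # strand-symmetric (the winning peptide itself can differ only
            # when two strands tie, since + is preferred on ties)
            assert len(a.peptide) == len(b.peptide)
            if a.strand != b.strand:  # same region, flipped label: identical
                assert a.peptide == b.peptide


class TestCollapseRedundancy:
    def test_identical_pair_collapses(self):
        recs = [_rec("a", "ACGT" * 30), _rec("b", "ACGT" * 30)]
        reps, cmap = sq.collapse_redundancy(recs)
        assert len(reps) == 1
        assert cmap == {"a": "a", "b": "a"}

    def test_substring_clusters_under_longer(self):
        a = "ATGCGTACGTTAGCATCGATCGATCGGATTACA" * 3
        recs = [_rec("A", a), _rec("B", a[10:50])]
        reps, cmap = sq.collapse_redundancy(recs)
        assert [r.id for r in reps] == ["A"]
        assert cmap["B"] == "A"

    def test_90_percent_identity_stays_separate(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        mutated = list(base)
        for pos in rng.choice(100, 10, replace=False):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        reps, _ = sq.collapse_redundancy([_rec("a", base), _rec("b", "".join(mutated))])
        assert len(reps) == 2

    def test_idempotent_and_total(self, rng):
        recs = [
            _rec(f"t{i}", "".join(rng.choice(list("ACGT"), int(n))))
            for i, n in enumerate(rng.integers(40, 200, 30))
        ]
        reps, cmap = sq.collapse_redundancy(recs)
        assert set(cmap) == {r.id for r in recs}  # every input mapped
        reps2, cmap2 = sq.collapse_redundancy(reps)
        assert len(reps2) == len(reps)
        assert all(cmap2[r.id] == r.id for r in reps)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            sq.collapse_redundancy([])


class TestAssemblyStats:
    @pytest.mark.parametrize(
        "lengths,n50",
        [([500], 500), ([6, 5, 4, 3, 2], 5), ([7, 7, 7], 7)],
    )
    def test_known_n50(self, lengths, n50):
        recs = [_rec(f"s{i}", "A" * n) for i, n in enumerate(lengths)]
        stats = sq.assembly_stats(recs)
        assert stats.n50 == n50
        assert stats.total_bp == sum(lengths)

    def test_n50_matches_brute_force(self, rng):
        for _ in range(25):
            lengths = rng.integers(1, 500, size=int(rng.integers(1, 100))).tolist()
            recs = [_rec(f"s{i}", "A" * n) for i, n in enumerate(lengths)]
            assert sq.assembly_stats(recs).n50 == n50_oracle(lengths)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            sq.assembly_stats([])
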
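"""Sequence concepts, SBS96 indexing, position bins, genes, reading frame."""

import numpy as np
import pytest

from mutmil.concepts import (
    PAD,
    GeneVocabulary,
    GenomicBins,
    encode_reading_frames,
    extract_sequence_concept,
    one_hot_sequences,
    reading_frame,
    sbs96_index,
    sbs96_label,
    SBS96_OUTGROUP,
    sequence_concept_from_strings,
)
from mutmil.variant_io import VariantRecord

from conftest import make_record


def seq_str(arr):
    return "".join("ACGTN"[i] for i in arr)


class TestSequenceConcept:
    def test_sbs_flanks_and_alleles(self, toy_genome, sbs):
        c = extract_sequence_concept(sbs, toy_genome, W=6)
        assert seq_str(c.five_prime) == "AAAAAA"
        assert seq_str(c.three_prime) == "GGGGGG"
        assert seq_str(c.ref_seq) == "C" + "N" * 5
        assert seq_str(c.alt_seq) == "T" + "N" * 5

    def test_reverse_complement_view(self, toy_genome, sbs):
        rc = extract_sequence_concept(sbs, toy_genome, W=6).reverse_complement()
        assert seq_str(rc.five_prime) == "CCCCCC"
        assert seq_str(rc.three_prime) == "TTTTTT"
        assert seq_str(rc.ref_seq) == "G" + "N" * 5
        assert seq_str(rc.alt_seq) == "A" + "N" * 5

    def test_double_reverse_complement_is_identity(self, toy_genome):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = int(rng.integers(2, 20))
            ref = toy_genome["chr2"][pos - 1]
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            v = make_record(chrom="chr2", pos=pos, ref=ref, alt=alt)
            c = extract_sequence_concept(v, toy_genome, W=4)
            back = c.reverse_complement().reverse_complement()
            for a, b in [
                (c.five_prime, back.five_prime),
                (c.three_prime, back.three_prime),
                (c.ref_seq, back.ref_seq),
                (c.alt_seq, back.alt_seq),
            ]:
                np.testing.assert_array_equal(a, b)

    def test_insertion_ref_is_all_pad(self, toy_genome):
        v = make_record(pos=10, ref="-", alt="AC")
        c = extract_sequence_concept(v, toy_genome, W=6)
        assert np.all(c.ref_seq == PAD)
        assert seq_str(c.alt_seq) == "AC" + "N" * 4
        # insertion anchors after pos: 5' flank ends at pos 10
        assert seq_str(c.five_prime) == "AAAAAA"
        assert seq_str(c.three_prime) == "CGGGGG"

    def test_contig_end_pads_distally(self, toy_genome):
        v = make_record(pos=2, ref="A", alt="T")
        c = extract_sequence_concept(v, toy_genome, W=6)
        assert seq_str(c.five_prime) == "N" * 5 + "A"  # PAD away from variant
        assert c.five_prime[0] == PAD

    def test_deletion_three_prime_flank_skips_ref_span(self, toy_genome):
        v = make_record(chrom="chr2", pos=5, ref="ACG", alt="-")
        c = extract_sequence_concept(v, toy_genome, W=4)
        assert seq_str(c.five_prime) == "ACGT"
        assert seq_str(c.three_prime) == "TACG"  # resumes after the deleted bases


class TestSbs96:
    def test_all_96_contexts_enumerate_distinctly(self):
        # brute force: build a genome per pyrimidine context, collect indices
        seen = {}
        for five in "ACGT":
            for ref in "CT":
                for three in "ACGT":
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        genome = {"c": f"{five}{ref}{three}"}
                        v = VariantRecord(
                            chrom="c", pos=2, ref=ref, alt=alt,
                            ref_count=1, alt_count=1, sample_id="s",
                        )
                        idx = sbs96_index(v, genome)
                        assert 0 <= idx <= 95
                        seen.setdefault(idx, set()).add((five, ref, alt, three))
        assert len(seen) == 96
        # each index corresponds to exactly one pyrimidine-centred context
        assert all(len(v) == 1 for v in seen.values())

    def test_purine_maps_to_reverse_complement_index(self):
        fwd = VariantRecord(chrom="c", pos=2, ref="C", alt="T",
                            ref_count=1, alt_count=1, sample_id="s")
        # A[C>T]G reverse complement is C[G>A]T
        rev = VariantRecord(chrom="c", pos=2, ref="G", alt="A",
                            ref_count=1, alt_count=1, sample_id="s")
        assert sbs96_index(fwd, {"c": "ACG"}) == sbs96_index(rev, {"c": "CGT"})

    def test_exhaustive_strand_symmetry(self):
        comp = str.maketrans("ACGT", "TGCA")
        for five in "ACGT":
            for ref in "CT":
                for three in "ACGT":
                    for alt in "ACGT":
                        if alt == ref:
                            continue
                        v1 = VariantRecord(chrom="c", pos=2, ref=ref, alt=alt,
                                           ref_count=1, alt_count=1, sample_id="s")
                        rc_ctx = f"{five}{ref}{three}".translate(comp)[::-1]
                        v2 = VariantRecord(
                            chrom="c", pos=2,
                            ref=ref.translate(comp), alt=alt.translate(comp),
                            ref_count=1, alt_count=1, sample_id="s",
                        )
                        assert sbs96_index(v1, {"c": f"{five}{ref}{three}"}) == \
                            sbs96_index(v2, {"c": rc_ctx})

    def test_non_sbs_and_ambiguous_map_to_outgroup(self, toy_genome):
        assert sbs96_index(make_record(ref="ACG", alt="-"), toy_genome) == SBS96_OUTGROUP
        assert sbs96_index(make_record(ref="-", alt="A"), toy_genome) == SBS96_OUTGROUP
        v = make_record(chrom="c", pos=2, ref="C", alt="T")
        assert sbs96_index(v, {"c": "NCG"}) == SBS96_OUTGROUP

    def test_labels_follow_signature_ordering(self):
        assert sbs96_label(0) == "A[C>A]A"
        assert sbs96_label(95) == "T[T>G]T"
        assert sbs96_label(SBS96_OUTGROUP) == "outgroup"


class TestGenomicBins:
    def test_first_position_is_bin_zero(self):
        bins = GenomicBins({"chr1": 1_500_000}, bin_size=1_000_000)
        assert bins.index("chr1", 1) == 0

    def test_bin_boundary_arithmetic(self):
        bins = GenomicBins({"chr1": 2_000_000}, bin_size=1_000_000)
        assert bins.index("chr1", 1_000_000) == 0
        assert bins.index("chr1", 1_000_001) == 1

    def test_concatenated_genome_offsets(self):
        bins = GenomicBins({"chr1": 1_500_000, "chr2": 700_000}, bin_size=1_000_000)
        assert bins.n_bins == 3
        assert bins.index("chr2", 700_000) == 2  # last base of the genome

    def test_monotone_in_genome_order(self):
        bins = GenomicBins({"a": 1000, "b": 1000}, bin_size=300)
        coords = [("a", p) for p in range(1, 1001, 97)] + [
            ("b", p) for p in range(1, 1001, 97)
        ]
        vals = [bins.index(c, p) for c, p in coords]
        assert vals == sorted(vals)

    def test_unknown_chromosome_named_in_error(self):
        bins = GenomicBins({"chr1": 100}, bin_size=10)
        with pytest.raises(ValueError, match="chrX"):
            bins.index("chrX", 5)


class TestGeneVocabulary:
    def test_known_and_other(self):
        vocab = GeneVocabulary(["TP53", "KRAS", "TP53"])
        assert vocab.index("KRAS") == 0  # sorted order
        assert vocab.index("TP53") == 1
        assert vocab.index("BRAF") == vocab.other_index
        assert vocab.n_genes == 3

    def test_order_independent_construction(self):
        a = GeneVocabulary(["B", "A", "C"])
        b = GeneVocabulary(["C", "B", "A", "B"])
        assert all(a.index(g) == b.index(g) for g in "ABC")


class TestReadingFrame:
    def test_coding_frames(self):
        rf = reading_frame(make_record(strand="+", cds_pos=10))
        assert (rf.frame, rf.is_coding) == (1, True)
        np.testing.assert_array_equal(rf.vector(), [1, 0, 0, 1, 0])
        rf = reading_frame(make_record(strand="-", cds_pos=3))
        assert rf.frame == 0 and rf.strand == "-"
        np.testing.assert_array_equal(rf.vector(), [0, 1, 1, 0, 0])

    def test_noncoding_is_zero_vector(self):
        rf = reading_frame(make_record())
        assert not rf.is_coding
        np.testing.assert_array_equal(rf.vector(), np.zeros(5))

    def test_bulk_encoding(self):
        recs = [make_record(strand="+", cds_pos=1), make_record()]
        enc = encode_reading_frames(recs)
        assert enc.shape == (2, 5)
        assert enc[1].sum() == 0


def test_one_hot_pad_is_zero_row():
    arr = np.array([[0, 3, PAD]])
    oh = one_hot_sequences(arr)
    np.testing.assert_array_equal(oh[0, 0], [1, 0, 0, 0])
    np.testing.assert_array_equal(oh[0, 2], [0, 0, 0, 0])


def test_concept_from_strings_round_trip():
    c = sequence_concept_from_strings("AAC", "GTT", "C", "-", W=3)
    assert seq_str(c.five_prime) == "AAC"
    assert np.all(c.alt_seq == PAD)
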
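import pytest

from mutmil.variant_io import VariantRecord


@pytest.fixture
def toy_genome():
    """Two small contigs with known content around position 11 of chr1."""
    return {
        "chr1": "AAAAAAAAAACGGGGGGGGGG",  # C at 1-based position 11
        "chr2": "ACGTACGTACGTACGTACGT",
    }


@pytest.fixture
def sbs(toy_genome):
    return VariantRecord(
        chrom="chr1", pos=11, ref="C", alt="T", ref_count=70, alt_count=30,
        sample_id="s1",
    )


def make_record(pos=11, ref="C", alt="T", chrom="chr1", sample="s1",
                ref_count=70, alt_count=30, **kw):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        ref_count=ref_count, alt_count=alt_count, sample_id=sample, **kw,
    )


@pytest.fixture
def maf_text_minimal():
    """Three rows: one SBS, one insertion, one deletion (minimal dialect)."""
    return (
        "chrom\tpos\tref\talt\tref_count\talt_count\tfilter\tsample\n"
        "chr1\t11\tC\tT\t70\t30\tPASS\ts1\n"
        "chr1\t15\t-\tAC\t50\t10\tPASS\ts1\n"
        "chr2\t5\tACG\t-\t40\t20\tPASS,wga\ts2\n"
    )


@pytest.fixture
def maf_text_mc3():
    """Same content in MC3-style column names."""
    return (
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tt_ref_count\tt_alt_count\tFILTER\t"
        "Tumor_Sample_Barcode\n"
        "GENE1\tchr1\t11\tC\tT\t70\t30\tPASS\ts1\n"
        "GENE2\tchr1\t15\t-\tAC\t50\t10\tPASS\ts1\n"
        "GENE3\tchr2\t5\tACG\t-\t40\t20\tPASS,wga\ts2\n"
    )
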
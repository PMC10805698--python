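"""Generator determinism, construction guarantees and independent oracles."""

import numpy as np
import pytest

from mutmil.concepts import PAD
from mutmil.simulate import (
    CONSEQUENCE_CLASSES,
    KEY_CODE,
    MARKER_CODE,
    Orf,
    TaskSpec,
    consequence_oracle,
    count_labels_oracle,
    gen_consequence_task,
    gen_context_task,
    gen_count_task,
    gen_fraction_task,
    gen_presence_task,
    gen_repeat_indel_task,
    make_toy_genome,
    singleton_bags,
    write_task_dir,
)
from mutmil.variant_io import VariantRecord


SMALL = dict(n_bags=30, bag_size=(5, 15), seed=7)


@pytest.mark.parametrize(
    "gen,task",
    [
        (gen_presence_task, "presence"),
        (gen_count_task, "count"),
        (gen_fraction_task, "fraction"),
        (gen_context_task, "context"),
        (gen_repeat_indel_task, "repeat_indel"),
    ],
)
def test_generators_bitwise_reproducible(gen, task):
    spec = TaskSpec(task=task, witness_rate=0.3, **SMALL)
    bags1, labels1 = gen(spec)
    bags2, labels2 = gen(spec)
    np.testing.assert_array_equal(labels1, labels2)
    for a, b in zip(bags1, bags2):
        for k in a.instances:
            np.testing.assert_array_equal(a.instances[k], b.instances[k])


class TestPresence:
    def test_key_only_in_positive_bags(self):
        bags, labels = gen_presence_task(TaskSpec(witness_rate=0.2, **SMALL))
        for bag, y in zip(bags, labels):
            has_key = (bag.instances["code"] == KEY_CODE).any()
            assert has_key == bool(y)
            assert has_key == bag.key_flags.any()

    def test_degenerate_witness_one_bag_one(self):
        spec = TaskSpec(witness_rate=1.0, n_bags=20, bag_size=(1, 1), seed=0)
        bags, labels = gen_presence_task(spec)
        for bag, y in zip(bags, labels):
            assert bag.n_instances == 1
            assert (bag.instances["code"][0] == KEY_CODE) == bool(y)

    def test_infeasible_witness_warns(self, caplog):
        with caplog.at_level("WARNING"):
            gen_presence_task(TaskSpec(witness_rate=0.01, n_bags=5,
                                       bag_size=(5, 9), seed=0))
        assert "witness" in caplog.text

    def test_label_noise_flips_expected_fraction(self):
        spec = TaskSpec(witness_rate=0.3, noise=0.2, n_bags=400,
                        bag_size=(5, 10), seed=1)
        bags, labels = gen_presence_task(spec)
        truth = np.array(
            [int((b.instances["code"] == KEY_CODE).any()) for b in bags]
        )
        flip_rate = (labels != truth).mean()
        assert flip_rate == pytest.approx(0.2, abs=0.05)


class TestCount:
    def test_oracle_recount_matches_labels(self):
        spec = TaskSpec(task="count", count_threshold=5, **SMALL)
        bags, labels = gen_count_task(spec)
        np.testing.assert_array_equal(count_labels_oracle(bags, 5), labels)

    def test_threshold_zero_any_key_is_positive(self):
        spec = TaskSpec(task="count", count_threshold=0, **SMALL)
        bags, labels = gen_count_task(spec)
        for bag, y in zip(bags, labels):
            assert y == int((bag.instances["code"] == KEY_CODE).sum() > 0)


class TestContext:
    def test_label_is_conjunction(self):
        spec = TaskSpec(task="context", witness_rate=0.25, **SMALL)
        bags, labels = gen_context_task(spec)
        for bag, y in zip(bags, labels):
            codes = bag.instances["code"]
            both = (codes == KEY_CODE).any() and (codes == MARKER_CODE).any()
            assert bool(y) == both


class TestRepeatIndel:
    def test_key_instances_have_spanning_homopolymer(self):
        spec = TaskSpec(task="repeat_indel", witness_rate=0.4, W=20, **SMALL)
        bags, labels = gen_repeat_indel_task(spec)
        assert any(labels == 1)
        for bag in bags:
            seqs = bag.instances["sequence"]
            for i in np.flatnonzero(bag.key_flags):
                five, three, ref = seqs[i, 0], seqs[i, 1], seqs[i, 2]
                base = ref[0]
                assert np.all(seqs[i, 3] == PAD)  # deletion: alt all PAD
                run = 1
                for b in five[::-1]:
                    if b != base:
                        break
                    run += 1
                for b in three:
                    if b != base:
                        break
                    run += 1
                assert run >= 5

    def test_negative_bags_have_no_keys(self):
        spec = TaskSpec(task="repeat_indel", witness_rate=0.4, W=20, **SMALL)
        bags, labels = gen_repeat_indel_task(spec)
        for bag, y in zip(bags, labels):
            if y == 0:
                assert not bag.key_flags.any()


class TestConsequence:
    def test_oracle_agrees_with_hand_worked_fixtures(self):
        # a fixed toy contig: one + strand ORF at 11..31 (ATG GAA TGT TAT
        # CCC TAA), one - strand ORF at 41..55 whose coding strand reads
        # ATG CAT AGA TGA (revcomp planted)
        plus_cds = "ATGGAATGTTATCCCTAA"
        minus_cds = "ATGCATAGATGA"
        minus_planted = "TCATCTATGCAT"  # revcomp(minus_cds)
        genome = {
            "toy": "AAAAACCCCC" + plus_cds + "GGGGGTTTTT"
            + minus_planted + "ACGTACGTAA"
        }
        orfs = [
            Orf("P", 11, 28, "+"),
            Orf("M", 39, 50, "-"),
        ]

        def v(pos, ref, alt):
            return VariantRecord(chrom="toy", pos=pos, ref=ref, alt=alt,
                                 ref_count=9, alt_count=9, sample_id="s")

        cases = [
            (v(5, "A", "C"), "noncoding"),          # intergenic SBS
            (v(14, "G", "A"), "missense"),          # GAA(E) -> AAA(K)
            (v(16, "A", "G"), "silent"),            # GAA(E) -> GAG(E)
            (v(19, "T", "A"), "nonsense"),          # TGT(C) -> TGA(*)
            (v(20, "T", "A"), "missense"),          # TAT(Y) -> AAT(N)
            (v(14, "GAA", "-"), "inframe_del"),     # whole codon removed
            (v(14, "GA", "-"), "frameshift_del"),   # 2-bp deletion
            (v(14, "-", "C"), "frameshift_ins"),    # 1-bp insertion
            (v(14, "-", "CGG"), "inframe_ins"),     # 3-bp insertion
            (v(44, "T", "C"), "missense"),          # - strand ORF SBS
        ]
        for variant, expected in cases:
            got = consequence_oracle(variant, orfs, genome)
            assert got == expected, (variant.pos, variant.ref, variant.alt, got)

    def test_generated_labels_come_from_oracle(self):
        spec = TaskSpec(task="consequence", n_instances=160, genome_length=6000,
                        n_orfs=8, seed=5)
        records, labels, genome, orfs = gen_consequence_task(spec)
        for r, y in zip(records[:100], labels[:100]):
            assert consequence_oracle(r, orfs, genome) == CONSEQUENCE_CLASSES[y]

    def test_toy_genome_orfs_translate_cleanly(self):
        from Bio.Seq import Seq

        spec = TaskSpec(task="consequence", genome_length=6000, n_orfs=6, seed=2)
        genome, orfs = make_toy_genome(spec)
        assert len(orfs) >= 4
        strands = {o.strand for o in orfs}
        assert strands == {"+", "-"}
        for orf in orfs:
            raw = genome["toy"][orf.start - 1 : orf.end]
            cds = raw if orf.strand == "+" else str(Seq(raw).reverse_complement())
            prot = str(Seq(cds).translate())
            assert prot.startswith("M") and prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_singleton_bags_wrap_instances(self):
        labels = np.array([0, 1, 2])
        bags = singleton_bags({"x": np.arange(6).reshape(3, 2)}, labels)
        assert [b.label for b in bags] == [0, 1, 2]
        assert all(b.n_instances == 1 for b in bags)


class TestTaskDir:
    def test_repeat_indel_round_trip(self, tmp_path):
        from mutmil.cli import _read_fasta
        from mutmil.variant_io import MINIMAL_DIALECT, read_maf

        spec = TaskSpec(task="repeat_indel", n_bags=6, bag_size=(3, 6),
                        witness_rate=0.5, genome_length=20000, seed=3)
        outdir = write_task_dir(spec, tmp_path / "task")
        genome = _read_fasta(outdir / "genome.fa")
        records = read_maf(outdir / "variants.maf", MINIMAL_DIALECT)
        assert len(genome["toy"]) >= 20000
        assert {r.sample_id for r in records} == {f"bag{i:04d}" for i in range(6)}
        # key deletions sit inside genome homopolymers
        truth = (outdir / "truth.tsv").read_text().splitlines()[1:]
        for line in truth:
            sid, pos, is_key = line.split("\t")
            if is_key == "1":
                p = int(pos)
                base = genome["toy"][p - 1]
                s = genome["toy"]
                run = 1
                q = p - 2
                while q >= 0 and s[q] == base:
                    run += 1
                    q -= 1
                q = p
                while q < len(s) and s[q] == base:
                    run += 1
                    q += 1
                assert run >= 5

    def test_unsupported_task_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_task_dir(TaskSpec(task="presence"), tmp_path / "x")
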
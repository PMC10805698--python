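"""Synthetic-task generators: a desk-scale test surface for the MIL stack.

Every generator is a pure function of a :class:`TaskSpec` (bit-reproducible
given the seed) and emulates one axis of the real problem:

``presence``
    the classic MIL witness-rate benchmark: positive bags contain at
    least one key instance at the witness rate, negative bags none;
``count``
    the label is whether the absolute number of key instances exceeds a
    threshold, with bag size drawn independently so the key *fraction* is
    uninformative — the reason a weighted sum can beat a weighted mean;
``fraction``
    the complement of ``count``: the label depends on the key fraction;
``context``
    a key instance only counts when a marker instance co-occurs in the
    bag (label = key AND marker), probing bag-dependent (dynamic)
    attention;
``repeat_indel``
    positive bags are enriched for single-base deletions inside planted
    mononucleotide runs (length 5-15) rendered as 20-nt sequence
    concepts — a microsatellite-instability analog;
``consequence``
    a per-instance (not bagged) task over a toy genome of random open
    reading frames on both strands, labelling variants by functional
    consequence via an independent translation-based oracle.

Generators can also write their output as a MAF + FASTA task directory so
the real-data path (variant IO -> featurization -> model) is exercised
end to end on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .concepts import (
    NUC_ORDER,
    extract_sequence_concept,
    sequence_concept_from_strings,
)
from .mil import Bag
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "Orf",
    "CONSEQUENCE_CLASSES",
    "gen_presence_task",
    "gen_count_task",
    "gen_fraction_task",
    "gen_context_task",
    "gen_repeat_indel_task",
    "gen_consequence_task",
    "consequence_oracle",
    "count_labels_oracle",
    "singleton_bags",
    "write_fasta",
    "write_maf",
    "write_task_dir",
]


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of one synthetic task; defaults are the study conditions."""

    task: str = "presence"
    n_bags: int = 500
    bag_size: tuple = (50, 100)
    witness_rate: float = 0.05
    n_codes: int = 20
    count_threshold: int = 5
    fraction_threshold: float = 0.2
    noise: float = 0.0
    W: int = 20
    n_instances: int = 4000
    genome_length: int = 9000
    n_orfs: int = 12
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.bag_size[0] < 1 or self.bag_size[0] > self.bag_size[1]:
            raise ValueError("bag_size must be (min, max) with 1 <= min <= max")


def _bag_sizes(spec: TaskSpec, rng) -> np.ndarray:
    lo, hi = spec.bag_size
    return rng.integers(lo, hi + 1, size=spec.n_bags)


def _flip(labels: np.ndarray, noise: float, rng) -> np.ndarray:
    if noise <= 0:
        return labels
    flip = rng.random(len(labels)) < noise
    return np.where(flip, 1 - labels, labels)


def _code_bag(sample_id, codes, n_codes, label, key_flags) -> Bag:
    onehot = np.eye(n_codes)[codes]
    return Bag(
        sample_id=sample_id,
        instances={"code": codes.astype(np.int64), "onehot": onehot},
        label=int(label),
        key_flags=key_flags,
    )


# ---------------------------------------------------------------------------
# categorical-code bag tasks

KEY_CODE = 0
MARKER_CODE = 1


def gen_presence_task(spec: TaskSpec):
    """Witness-rate presence task; key code appears only in positive bags."""
    rng = np.random.default_rng(spec.seed)
    if spec.witness_rate * spec.bag_size[0] < 1:
        logger.warning(
            "expected key instances per positive bag < 1 "
            "(witness %.3f x min bag %d); positives still get >= 1 key",
            spec.witness_rate,
            spec.bag_size[0],
        )
    sizes = _bag_sizes(spec, rng)
    labels = rng.integers(0, 2, size=spec.n_bags)
    bags = []
    for i, (n, y) in enumerate(zip(sizes, labels)):
        codes = rng.integers(1, spec.n_codes, size=n)
        flags = np.zeros(n, dtype=bool)
        if y == 1:
            k = max(1, rng.binomial(n, spec.witness_rate))
            pos = rng.choice(n, size=min(k, n), replace=False)
            codes[pos] = KEY_CODE
            flags[pos] = True
        bags.append(_code_bag(f"bag{i:04d}", codes, spec.n_codes, y, flags))
    noisy = _flip(labels, spec.noise, rng)
    for b, y in zip(bags, noisy):
        b.label = int(y)
    return bags, noisy


def gen_count_task(spec: TaskSpec):
    """Label = (number of key instances > threshold); fraction uninformative.

    Key counts are drawn uniformly on 0..2*threshold+2 independently of
    the (independently drawn) bag size, so the key fraction overlaps
    heavily between classes while the absolute count separates them.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _bag_sizes(spec, rng)
    bags = []
    labels = []
    for i, n in enumerate(sizes):
        k = int(rng.integers(0, 2 * spec.count_threshold + 3))
        k = min(k, int(n))
        y = int(k > spec.count_threshold)
        codes = rng.integers(1, spec.n_codes, size=n)
        flags = np.zeros(n, dtype=bool)
        if k:
            pos = rng.choice(n, size=k, replace=False)
            codes[pos] = KEY_CODE
            flags[pos] = True
        labels.append(y)
        bags.append(_code_bag(f"bag{i:04d}", codes, spec.n_codes, y, flags))
    labels = _flip(np.array(labels), spec.noise, rng)
    for b, y in zip(bags, labels):
        b.label = int(y)
    return bags, labels


def count_labels_oracle(bags: Sequence[Bag], threshold: int) -> np.ndarray:
    """Brute-force relabelling of a count task from the raw codes."""
    return np.array(
        [int((b.instances["code"] == KEY_CODE).sum() > threshold) for b in bags]
    )


def gen_fraction_task(spec: TaskSpec):
    """Label = (key fraction > threshold); the absolute count is uninformative."""
    rng = np.random.default_rng(spec.seed)
    sizes = _bag_sizes(spec, rng)
    bags, labels = [], []
    for i, n in enumerate(sizes):
        frac = rng.uniform(0, 2 * spec.fraction_threshold)
        k = int(round(frac * n))
        y = int(k / n > spec.fraction_threshold)
        codes = rng.integers(1, spec.n_codes, size=n)
        flags = np.zeros(n, dtype=bool)
        if k:
            pos = rng.choice(n, size=k, replace=False)
            codes[pos] = KEY_CODE
            flags[pos] = True
        labels.append(y)
        bags.append(_code_bag(f"bag{i:04d}", codes, spec.n_codes, y, flags))
    labels = _flip(np.array(labels), spec.noise, rng)
    for b, y in zip(bags, labels):
        b.label = int(y)
    return bags, labels


def gen_context_task(spec: TaskSpec):
    """Key-AND-marker task: positive iff key and marker codes co-occur.

    The per-bag witness rate is jittered over (0.3x, 1.7x) the nominal
    rate, so the marginal fraction of either code alone overlaps heavily
    between classes and only their co-occurrence carries the label.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _bag_sizes(spec, rng)
    bags, labels = [], []
    for i, n in enumerate(sizes):
        has_key, has_marker = rng.integers(0, 2, size=2)
        y = int(has_key and has_marker)
        codes = rng.integers(2, spec.n_codes, size=n)
        flags = np.zeros(n, dtype=bool)
        free = rng.permutation(n)  # disjoint slots so neither overwrites the other
        for present, code in ((has_key, KEY_CODE), (has_marker, MARKER_CODE)):
            if present:
                rate = spec.witness_rate * rng.uniform(0.3, 1.7)
                k = min(max(1, rng.binomial(n, rate)), len(free))
                pos, free = free[:k], free[k:]
                codes[pos] = code
                if code == KEY_CODE:
                    flags[pos] = True
        labels.append(y)
        bags.append(_code_bag(f"bag{i:04d}", codes, spec.n_codes, y, flags))
    labels = _flip(np.array(labels), spec.noise, rng)
    for b, y in zip(bags, labels):
        b.label = int(y)
    return bags, labels


# ---------------------------------------------------------------------------
# repeat-indel (microsatellite analog) task


def _random_seq(rng, n: int) -> str:
    return "".join(NUC_ORDER[i] for i in rng.integers(0, 4, size=n))


def _spanning_run(five: str, ref: str, three: str) -> int:
    """Longest homopolymer run through the first ref base."""
    base = ref[0]
    run = 1
    for c in reversed(five):
        if c != base:
            break
        run += 1
    for c in three:
        if c != base:
            break
        run += 1
    return run


def _key_indel_concept(rng, W: int) -> np.ndarray:
    """1-bp deletion inside a mononucleotide T run of length 5-15.

    Mismatch-repair-deficient tumours accumulate slippage deletions at
    poly-T/poly-A tracts; fixing the run base keeps the planted motif
    logo-visible (the reverse-complement orientation carries the A run).
    """
    base = "T"
    run_len = int(rng.integers(5, 16))
    left = int(rng.integers(0, run_len))  # bases of the run 5' of the deletion
    right = run_len - 1 - left
    five = _random_seq(rng, W - left) + base * left
    three = base * right + _random_seq(rng, W - right)
    # keep the run bounded so its length is exactly run_len
    if left < W and five[W - left - 1] == base:
        five = five[: W - left - 1] + _other_base(rng, base) + five[W - left:]
    if right < W and three[right] == base:
        three = three[:right] + _other_base(rng, base) + three[right + 1:]
    return sequence_concept_from_strings(five, three, base, "-", W).stack()


def _other_base(rng, base: str) -> str:
    choices = [c for c in NUC_ORDER if c != base]
    return choices[rng.integers(0, 3)]


def _background_concept(rng, W: int) -> np.ndarray:
    """An SBS, or a 1-bp deletion not inside a homopolymer run >= 5."""
    if rng.random() < 0.7:  # SBS
        five, three = _random_seq(rng, W), _random_seq(rng, W)
        ref = NUC_ORDER[rng.integers(0, 4)]
        alt = _other_base(rng, ref)
        return sequence_concept_from_strings(five, three, ref, alt, W).stack()
    while True:
        five, three = _random_seq(rng, W), _random_seq(rng, W)
        ref = NUC_ORDER[rng.integers(0, 4)]
        if _spanning_run(five, ref, three) < 5:
            return sequence_concept_from_strings(five, three, ref, "-", W).stack()


def gen_repeat_indel_task(spec: TaskSpec):
    """Bags of 20-nt sequence concepts; positives carry homopolymer deletions."""
    rng = np.random.default_rng(spec.seed)
    sizes = _bag_sizes(spec, rng)
    labels = rng.integers(0, 2, size=spec.n_bags)
    bags = []
    for i, (n, y) in enumerate(zip(sizes, labels)):
        k = max(1, rng.binomial(n, spec.witness_rate)) if y == 1 else 0
        k = min(k, int(n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        seqs = np.stack(
            [_key_indel_concept(rng, spec.W) for _ in range(k)]
            + [_background_concept(rng, spec.W) for _ in range(n - k)]
        )
        perm = rng.permutation(n)
        bags.append(
            Bag(
                sample_id=f"bag{i:04d}",
                instances={"sequence": seqs[perm]},
                label=int(y),
                key_flags=flags[perm],
            )
        )
    noisy = _flip(labels, spec.noise, rng)
    for b, y in zip(bags, noisy):
        b.label = int(y)
    return bags, noisy


# ---------------------------------------------------------------------------
# consequence task (toy coding genome, per-instance labels)

CONSEQUENCE_CLASSES = [
    "frameshift_del",
    "frameshift_ins",
    "inframe_del",
    "inframe_ins",
    "missense",
    "nonsense",
    "silent",
    "noncoding",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """One planted open reading frame (1-based inclusive genome span)."""

    name: str
    start: int
    end: int
    strand: str


def _random_orf_seq(rng, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(0, 3)])
    return "".join(codons)


def make_toy_genome(spec: TaskSpec):
    """Random contig with non-overlapping ORFs planted on both strands."""
    rng = np.random.default_rng(spec.seed)
    seq = list(_random_seq(rng, spec.genome_length))
    orfs: list[Orf] = []
    occupied = np.zeros(spec.genome_length, dtype=bool)
    attempts = 0
    while len(orfs) < spec.n_orfs and attempts < 200:
        attempts += 1
        n_codons = int(rng.integers(20, 61))
        length = 3 * n_codons
        start0 = int(rng.integers(50, spec.genome_length - length - 50))
        if occupied[max(0, start0 - 10) : start0 + length + 10].any():
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_orf_seq(rng, n_codons)
        planted = cds if strand == "+" else str(Seq(cds).reverse_complement())
        seq[start0 : start0 + length] = list(planted)
        occupied[start0 : start0 + length] = True
        orfs.append(
            Orf(
                name=f"ORF{len(orfs):02d}",
                start=start0 + 1,
                end=start0 + length,
                strand=strand,
            )
        )
    genome = {"toy": "".join(seq)}
    return genome, orfs


def _orf_containing(orfs: Sequence[Orf], lo: int, hi: int) -> Optional[Orf]:
    """The ORF fully containing the 1-based inclusive span [lo, hi]."""
    for orf in orfs:
        if orf.start <= lo and hi <= orf.end:
            return orf
    return None


def _cds_sequence(orf: Orf, genome) -> str:
    raw = genome["toy"][orf.start - 1 : orf.end]
    return raw if orf.strand == "+" else str(Seq(raw).reverse_complement())


def _cds_position(orf: Orf, pos: int) -> int:
    return pos - orf.start + 1 if orf.strand == "+" else orf.end - pos + 1


def consequence_oracle(v: VariantRecord, orfs: Sequence[Orf], genome) -> str:
    """Label a variant's functional consequence by direct translation.

    Independent of the generator's bookkeeping: rebuilds the coding
    sequence from the genome, applies the edit on the coding strand, and
    compares translations codon by codon. Variants not fully inside an
    ORF are noncoding; a lost stop codon is labelled ``stop_lost`` (the
    generator resamples those).
    """
    if v.ref == "-":  # insertion between pos and pos+1
        lo, hi = v.pos, v.pos + 1
        orf = _orf_containing(orfs, lo, hi)
        if orf is None:
            return "noncoding"
        return "inframe_ins" if len(v.alt) % 3 == 0 else "frameshift_ins"
    lo, hi = v.pos, v.pos + len(v.ref) - 1
    orf = _orf_containing(orfs, lo, hi)
    if orf is None:
        return "noncoding"
    if v.alt == "-":
        return "inframe_del" if len(v.ref) % 3 == 0 else "frameshift_del"
    # substitution on the coding strand
    cds = _cds_sequence(orf, genome)
    cpos = _cds_position(orf, v.pos)  # 1-based within CDS
    ref_c, alt_c = v.ref, v.alt
    if orf.strand == "-":
        ref_c = str(Seq(ref_c).reverse_complement())
        alt_c = str(Seq(alt_c).reverse_complement())
        cpos = cpos - len(v.ref) + 1
    assert cds[cpos - 1 : cpos - 1 + len(ref_c)] == ref_c
    mutated = cds[: cpos - 1] + alt_c + cds[cpos - 1 + len(ref_c):]
    prot_ref = str(Seq(cds).translate())
    prot_alt = str(Seq(mutated).translate())
    if prot_alt == prot_ref:
        return "silent"
    if "*" in prot_alt[:-1] and "*" not in prot_ref[:-1]:
        return "nonsense"
    if prot_ref.endswith("*") and not prot_alt.endswith("*"):
        return "stop_lost"
    return "missense"


def _random_variant(rng, genome, orfs, coding_bias: float) -> VariantRecord:
    n = len(genome["toy"])
    if rng.random() < coding_bias and orfs:
        orf = orfs[rng.integers(0, len(orfs))]
        pos = int(rng.integers(orf.start, orf.end + 1))
    else:
        pos = int(rng.integers(2, n - 4))
    seq = genome["toy"]
    u = rng.random()
    if u < 0.7:  # SBS
        ref = seq[pos - 1]
        alt = _other_base(rng, ref)
    elif u < 0.85:  # deletion of 1-3 bases
        L = int(rng.integers(1, 4))
        ref, alt = seq[pos - 1 : pos - 1 + L], "-"
    else:  # insertion of 1-3 bases
        ref, alt = "-", _random_seq(rng, int(rng.integers(1, 4)))
    orf = _orf_containing(
        orfs, pos, pos + (len(ref) - 1 if ref != "-" else 1)
    )
    gene = orf.name if orf else None
    strand = orf.strand if orf else None
    cds_pos = _cds_position(orf, pos) if orf else None
    return VariantRecord(
        chrom="toy",
        pos=pos,
        ref=ref,
        alt=alt,
        ref_count=50,
        alt_count=25,
        sample_id="toy-sample",
        gene=gene,
        strand=strand,
        cds_pos=cds_pos,
    )


def gen_consequence_task(spec: TaskSpec, per_class: Optional[int] = None):
    """Per-instance consequence task over a toy coding genome.

    Draws variants until every class has roughly ``per_class`` examples
    (default ``n_instances / 8``), labelling each with the translation
    oracle. Returns (records, labels, genome, orfs) with integer labels
    indexing :data:`CONSEQUENCE_CLASSES`.
    """
    genome, orfs = make_toy_genome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    per_class = per_class or max(1, spec.n_instances // len(CONSEQUENCE_CLASSES))
    counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    records, labels = [], []
    max_draws = 400 * per_class * len(CONSEQUENCE_CLASSES)
    draws = 0
    while min(counts.values()) < per_class and draws < max_draws:
        draws += 1
        v = _random_variant(rng, genome, orfs, coding_bias=0.75)
        label = consequence_oracle(v, orfs, genome)
        if label not in counts or counts[label] >= per_class:
            continue
        counts[label] += 1
        records.append(v)
        labels.append(CONSEQUENCE_CLASSES.index(label))
    if min(counts.values()) < per_class:
        logger.warning("consequence task: class counts %s after %d draws", counts, draws)
    return records, np.array(labels, dtype=np.int64), genome, orfs


def singleton_bags(instances: dict[str, np.ndarray], labels: np.ndarray) -> list[Bag]:
    """Wrap a per-instance supervised task as bags of size one."""
    n = len(labels)
    return [
        Bag(
            sample_id=f"inst{i:05d}",
            instances={k: v[i : i + 1] for k, v in instances.items()},
            label=int(labels[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# file emission: exercise the MAF/FASTA path end to end


def write_fasta(genome: dict[str, str], path, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_maf(records: Sequence[VariantRecord], path):
    """Write records in the minimal dialect (columns: chrom, pos, ...)."""
    cols = [
        "chrom", "pos", "ref", "alt", "ref_count", "alt_count",
        "filter", "sample", "gene", "strand", "cds_pos",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        r.ref,
                        r.alt,
                        str(r.ref_count),
                        str(r.alt_count),
                        ",".join(sorted(r.filter_flags)) or "PASS",
                        r.sample_id,
                        r.gene or "",
                        r.strand or "",
                        "" if r.cds_pos is None else str(r.cds_pos),
                    ]
                )
                + "\n"
            )


def _genome_with_runs(rng, length: int) -> str:
    return _random_seq(rng, length)


def write_task_dir(spec: TaskSpec, outdir):
    """Write a self-contained task directory (FASTA + MAF + labels TSV).

    Supported tasks: ``repeat_indel`` (variants placed on a toy contig so
    featurization from the genome reproduces the planted structure) and
    ``consequence``. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    if spec.task == "consequence":
        records, labels, genome, orfs = gen_consequence_task(spec)
        write_fasta(genome, outdir / "genome.fa")
        write_maf(
            [replace(r, sample_id=f"inst{i:05d}") for i, r in enumerate(records)],
            outdir / "variants.maf",
        )
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("sample\tlabel\tclass\n")
            for i, y in enumerate(labels):
                fh.write(f"inst{i:05d}\t{y}\t{CONSEQUENCE_CLASSES[y]}\n")
    elif spec.task == "repeat_indel":
        genome_seq = _genome_with_runs(rng, max(spec.genome_length, 20000))
        genome = {"toy": genome_seq}
        runs = _find_runs(genome_seq, min_len=5)
        if not runs:
            raise RuntimeError("toy genome contains no homopolymer runs")
        sizes = _bag_sizes(spec, rng)
        labels = rng.integers(0, 2, size=spec.n_bags)
        records = []
        with open(outdir / "truth.tsv", "w") as truth:
            truth.write("sample\tpos\tis_key\n")
            for i, (n, y) in enumerate(zip(sizes, labels)):
                sid = f"bag{i:04d}"
                k = max(1, rng.binomial(n, spec.witness_rate)) if y else 0
                for j in range(n):
                    if j < k:
                        run_start, run_len = runs[rng.integers(0, len(runs))]
                        pos = int(run_start + rng.integers(0, run_len))
                        v = VariantRecord(
                            chrom="toy", pos=pos, ref=genome_seq[pos - 1], alt="-",
                            ref_count=50, alt_count=25, sample_id=sid,
                        )
                        truth.write(f"{sid}\t{pos}\t1\n")
                    else:
                        while True:
                            pos = int(rng.integers(spec.W + 1, len(genome_seq) - spec.W))
                            ref = genome_seq[pos - 1]
                            five = genome_seq[max(0, pos - 6) : pos - 1]
                            three = genome_seq[pos : pos + 5]
                            if rng.random() < 0.7:
                                v = VariantRecord(
                                    chrom="toy", pos=pos, ref=ref,
                                    alt=_other_base(rng, ref),
                                    ref_count=50, alt_count=25, sample_id=sid,
                                )
                                break
                            if _spanning_run(five, ref, three) < 5:
                                v = VariantRecord(
                                    chrom="toy", pos=pos, ref=ref, alt="-",
                                    ref_count=50, alt_count=25, sample_id=sid,
                                )
                                break
                        truth.write(f"{sid}\t{pos}\t0\n")
                    records.append(v)
        write_fasta(genome, outdir / "genome.fa")
        write_maf(records, outdir / "variants.maf")
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("sample\tlabel\n")
            for i, y in enumerate(labels):
                fh.write(f"bag{i:04d}\t{int(y)}\n")
    else:
        raise ValueError(
            f"task {spec.task!r} has no file representation; "
            "use the in-memory generator"
        )
    return outdir


def _find_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """(1-based start, length) of homopolymer runs of at least `min_len`."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i + 1, j - i))
        i = j
    return runs
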
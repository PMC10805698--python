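"""Instance featurization: turning a variant call into "genomic concepts".

A genomic concept is a model-ready encoding of one of the properties that
uniquely define a somatic mutation:

* local sequence context — fixed-width padded nucleotide arrays for the
  5' flank, reference allele, alternate allele and 3' flank, produced in
  both the forward and reverse-complement orientations so a downstream
  encoder can symmetrize or learn strand;
* the SBS96 trinucleotide-context category (pyrimidine-centred, with a
  97th outgroup so non-SBS calls are never discarded);
* the genomic position as a fixed-size bin over the concatenated genome;
* gene identity through a deterministic vocabulary with an OTHER bucket;
* reading frame as strand plus coding-sequence position modulo 3 (a zero
  vector for noncoding variants).

Nucleotides are integer-coded A=0, C=1, G=2, T=3 with PAD=4; ambiguous
bases (N) are treated as PAD. One-hot encoding maps PAD to the all-zero
row, so padding contributes nothing to convolutions or logos.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PAD",
    "NUC_ORDER",
    "SequenceConcept",
    "ReadingFrame",
    "extract_sequence_concept",
    "sequence_concept_from_strings",
    "sbs96_index",
    "sbs96_label",
    "SBS96_N_CATEGORIES",
    "SBS96_OUTGROUP",
    "GenomicBins",
    "position_bin",
    "GeneVocabulary",
    "reading_frame",
    "encode_sequence_concepts",
    "encode_sbs96",
    "encode_reading_frames",
    "one_hot_sequences",
    "contig_lengths",
]

NUC_ORDER = "ACGT"
PAD = 4
_NUC2INT = {c: i for i, c in enumerate(NUC_ORDER)}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, PAD fixed
_COMP_STR = str.maketrans("ACGT", "TGCA")

SBS96_N_CATEGORIES = 97
SBS96_OUTGROUP = 96
_SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_SUB_INDEX = {s: i for i, s in enumerate(_SUBSTITUTIONS)}


def _seq_to_ints(seq: str) -> np.ndarray:
    return np.array([_NUC2INT.get(c, PAD) for c in seq.upper()], dtype=np.int8)


def _ints_to_str(arr: np.ndarray) -> str:
    return "".join((NUC_ORDER + "N")[i] for i in arr)


# ---------------------------------------------------------------------------
# genome accessors: plain dict[str, str] or pyfaidx.Fasta both work


def _contig_seq_len(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def contig_lengths(genome) -> dict[str, int]:
    """Contig name -> length, preserving the genome's contig order."""
    return {name: _contig_seq_len(genome, name) for name in genome.keys()}


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) clipped to contig bounds (no padding here)."""
    n = _contig_seq_len(genome, chrom)
    s, e = max(start0, 0), min(end0, n)
    if s >= e:
        return ""
    return str(genome[chrom][s:e])


# ---------------------------------------------------------------------------
# sequence concept


@dataclass(frozen=True)
class SequenceConcept:
    """Fixed-width padded arrays for flanks and alleles, one orientation.

    Flanks are stored in genomic order: the 5' flank's last element and the
    3' flank's first element are adjacent to the variant, so PAD can only
    occur distally. Alleles are proximal-aligned (right-padded).
    """

    five_prime: np.ndarray
    three_prime: np.ndarray
    ref_seq: np.ndarray
    alt_seq: np.ndarray

    @property
    def W(self) -> int:
        return len(self.five_prime)

    def reverse_complement(self) -> "SequenceConcept":
        """The same variant viewed from the opposite strand."""

        def rc_flank(a):
            return _COMPLEMENT[a[::-1]]

        def rc_allele(a):
            core = a[a != PAD]
            out = np.full_like(a, PAD)
            out[: len(core)] = _COMPLEMENT[core[::-1]]
            return out

        return SequenceConcept(
            five_prime=rc_flank(self.three_prime),
            three_prime=rc_flank(self.five_prime),
            ref_seq=rc_allele(self.ref_seq),
            alt_seq=rc_allele(self.alt_seq),
        )

    def stack(self) -> np.ndarray:
        """(8, W) int8: forward 5'/3'/ref/alt then reverse-complement ones."""
        rc = self.reverse_complement()
        return np.stack(
            [
                self.five_prime,
                self.three_prime,
                self.ref_seq,
                self.alt_seq,
                rc.five_prime,
                rc.three_prime,
                rc.ref_seq,
                rc.alt_seq,
            ]
        )


def _pad_left(seq: str, W: int) -> np.ndarray:
    out = np.full(W, PAD, dtype=np.int8)
    ints = _seq_to_ints(seq[-W:]) if seq else np.empty(0, dtype=np.int8)
    out[W - len(ints):] = ints
    return out


def _pad_right(seq: str, W: int) -> np.ndarray:
    out = np.full(W, PAD, dtype=np.int8)
    ints = _seq_to_ints(seq[:W]) if seq else np.empty(0, dtype=np.int8)
    out[: len(ints)] = ints
    return out


def extract_sequence_concept(
    v: VariantRecord, genome, W: int = 6
) -> SequenceConcept:
    """Extract the forward-orientation sequence concept for a variant.

    ``W`` is the flank/allele width (6 for the classification setting, 20
    for the microsatellite setting). Flanks that run off a contig end are
    PAD-filled distally; alleles longer than ``W`` are truncated with a
    warning; a "-" allele (insertion/deletion gap) is all PAD.
    """
    if v.ref == "-":
        five_end = v.pos  # insertion anchored after pos: flank includes pos
    else:
        five_end = v.pos - 1
    three_start = five_end + v.ref_span
    five = _fetch(genome, v.chrom, five_end - W, five_end)
    three = _fetch(genome, v.chrom, three_start, three_start + W)
    if len(five) < W or len(three) < W:
        logger.debug("variant %s:%d within %d bp of contig end", v.chrom, v.pos, W)
    for allele in (v.ref, v.alt):
        if allele != "-" and len(allele) > W:
            logger.warning(
                "allele of length %d truncated to W=%d at %s:%d",
                len(allele), W, v.chrom, v.pos,
            )
    return SequenceConcept(
        five_prime=_pad_left(five, W),
        three_prime=_pad_right(three, W),
        ref_seq=_pad_right("" if v.ref == "-" else v.ref, W),
        alt_seq=_pad_right("" if v.alt == "-" else v.alt, W),
    )


def sequence_concept_from_strings(
    five: str, three: str, ref: str, alt: str, W: int
) -> SequenceConcept:
    """Build a concept directly from flank/allele strings (synthetic data).

    Gap alleles may be given as ``"-"`` or the empty string.
    """
    return SequenceConcept(
        five_prime=_pad_left(five, W),
        three_prime=_pad_right(three, W),
        ref_seq=_pad_right("" if ref == "-" else ref, W),
        alt_seq=_pad_right("" if alt == "-" else alt, W),
    )


# ---------------------------------------------------------------------------
# SBS96


def sbs96_index(v: VariantRecord, genome) -> int:
    """Pyrimidine-centred trinucleotide-context index in [0, 96].

    Ordering follows the conventional mutational-signature layout:
    substitution type major (C>A, C>G, C>T, T>A, T>C, T>G), then the 5'
    then 3' flanking base, each in A,C,G,T order:
    ``index = sub * 16 + five * 4 + three``. Purine-reference SBSs are
    reverse-complemented first, so the index is strand-symmetric. Anything
    that is not an unambiguous SBS in an unambiguous context maps to the
    outgroup index 96.
    """
    if v.variant_class != "SBS":
        return SBS96_OUTGROUP
    ref, alt = v.ref, v.alt
    five = _fetch(genome, v.chrom, v.pos - 2, v.pos - 1)
    three = _fetch(genome, v.chrom, v.pos, v.pos + 1)
    if ref in "AG":  # purine-centred: flip to the pyrimidine strand
        ref, alt = ref.translate(_COMP_STR), alt.translate(_COMP_STR)
        five, three = three.translate(_COMP_STR), five.translate(_COMP_STR)
    sub = _SUB_INDEX.get((ref, alt))
    if sub is None or five not in _NUC2INT or three not in _NUC2INT:
        return SBS96_OUTGROUP
    return sub * 16 + _NUC2INT[five] * 4 + _NUC2INT[three]


def sbs96_label(index: int) -> str:
    """Human-readable label, e.g. ``A[C>T]G``; 96 -> ``outgroup``."""
    if index == SBS96_OUTGROUP:
        return "outgroup"
    sub, rest = divmod(index, 16)
    five, three = divmod(rest, 4)
    ref, alt = _SUBSTITUTIONS[sub]
    return f"{NUC_ORDER[five]}[{ref}>{alt}]{NUC_ORDER[three]}"


# ---------------------------------------------------------------------------
# genomic position bins


class GenomicBins:
    """Fixed-size bins over a genome concatenated in contig order."""

    def __init__(self, lengths: Mapping[str, int], bin_size: int):
        if bin_size < 1:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.offsets: dict[str, int] = {}
        total = 0
        for chrom, n in lengths.items():
            self.offsets[chrom] = total
            total += int(n)
        self.genome_length = total
        self.n_bins = -(-total // self.bin_size)  # ceil

    def index(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise ValueError(f"unknown chromosome {chrom!r} for position binning")
        return (self.offsets[chrom] + pos - 1) // self.bin_size


def position_bin(v: VariantRecord, bins: GenomicBins) -> int:
    return bins.index(v.chrom, v.pos)


# ---------------------------------------------------------------------------
# gene vocabulary


class GeneVocabulary:
    """Deterministic gene -> index map with a trailing OTHER bucket.

    Built from the training folds only; sorted unique names make the
    mapping independent of input order.
    """

    def __init__(self, genes):
        names = sorted({g for g in genes if g is not None})
        self._index = {g: i for i, g in enumerate(names)}
        self.other_index = len(names)
        self.n_genes = len(names) + 1  # including OTHER

    def index(self, gene: Optional[str]) -> int:
        return self._index.get(gene, self.other_index)


# ---------------------------------------------------------------------------
# reading frame


@dataclass(frozen=True)
class ReadingFrame:
    strand: Optional[str]
    frame: Optional[int]
    is_coding: bool

    def vector(self) -> np.ndarray:
        """[strand+, strand-, frame0, frame1, frame2]; zeros if noncoding."""
        out = np.zeros(5)
        if not self.is_coding:
            return out
        out[0 if self.strand == "+" else 1] = 1.0
        out[2 + self.frame] = 1.0
        return out


def reading_frame(v: VariantRecord) -> ReadingFrame:
    """Strand and coding-sequence position modulo 3 (zeros if noncoding)."""
    if v.cds_pos is None or v.strand not in ("+", "-"):
        return ReadingFrame(strand=None, frame=None, is_coding=False)
    return ReadingFrame(strand=v.strand, frame=v.cds_pos % 3, is_coding=True)


# ---------------------------------------------------------------------------
# bulk encoders (array-in, array-out surfaces used by the model and CLI)


def encode_sequence_concepts(
    records: Sequence[VariantRecord], genome, W: int = 6
) -> np.ndarray:
    """(n, 8, W) int8 stack of forward + reverse-complement components."""
    if not records:
        return np.empty((0, 8, W), dtype=np.int8)
    return np.stack([extract_sequence_concept(v, genome, W).stack() for v in records])


def encode_sbs96(records: Sequence[VariantRecord], genome) -> np.ndarray:
    return np.array([sbs96_index(v, genome) for v in records], dtype=np.int64)


def encode_reading_frames(records: Sequence[VariantRecord]) -> np.ndarray:
    if not records:
        return np.empty((0, 5))
    return np.stack([reading_frame(v).vector() for v in records])


def one_hot_sequences(seqs: np.ndarray) -> np.ndarray:
    """Int-coded sequences -> one-hot with PAD as the all-zero row.

    Input (..., W) integer array; output (..., W, 4) float64.
    """
    eye = np.zeros((5, 4))
    eye[:4] = np.eye(4)
    return eye[np.asarray(seqs, dtype=np.int64)]
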
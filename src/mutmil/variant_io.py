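"""Reading, filtering and normalizing somatic variant calls from MAF tables.

MAF (Mutation Annotation Format) is a tab-delimited table of somatic
variant calls with 1-based inclusive coordinates. Column names vary by
producer, so readers take a :class:`MafDialect` mapping logical fields to
header names; defaults cover the TCGA MC3 naming.

The module also implements the preprocessing applied before featurization:

* retention by FILTER flag sets (a call is kept iff its flags are a subset
  of the allowed set, so combinations of allowed flags pass);
* optional multi-caller support thresholding;
* intersection with covered regions given as BED-style 0-based half-open
  intervals (a variant is kept only when its full reference span lies in
  the covered union; insertions are anchored to one base);
* merging of runs of consecutive single-base substitutions into one
  multi-nucleotide variant when their read counts agree, correcting for
  callers that report doublet/longer substitutions base-by-base.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from itertools import groupby
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "MafDialect",
    "MC3_DIALECT",
    "MINIMAL_DIALECT",
    "MafFormatError",
    "MafRowError",
    "PUBLIC_MAF_FILTERS",
    "CONTROLLED_MAF_FILTERS",
    "read_maf",
    "filter_by_flags",
    "filter_by_caller_count",
    "read_bed",
    "intersect_intervals",
    "merge_consecutive_snvs",
]

#: FILTER values retained for public MC3-style MAFs.
PUBLIC_MAF_FILTERS = frozenset({"PASS", "wga", "native_wga_mix"})

#: FILTER values retained for controlled MC3-style MAFs (any combination).
CONTROLLED_MAF_FILTERS = frozenset(
    {"PASS", "NonExonic", "wga", "bitgt", "broad_PoN_v2", "native_wga_mix"}
)

_GAP = "-"


class MafFormatError(ValueError):
    """The file as a whole cannot be interpreted (e.g. a missing column)."""


class MafRowError(ValueError):
    """A single row is malformed; the message carries the 1-based line."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation call.

    Coordinates are MAF-style: ``pos`` is the 1-based first reference base
    of the event. A ``ref`` of ``"-"`` denotes an insertion (no reference
    bases consumed, anchored after ``pos``); an ``alt`` of ``"-"`` denotes
    a deletion.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int = 0
    alt_count: int = 0
    filter_flags: frozenset = frozenset({"PASS"})
    sample_id: str = ""
    gene: Optional[str] = None
    strand: Optional[str] = None
    cds_pos: Optional[int] = None
    n_callers: Optional[int] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref == _GAP and self.alt == _GAP:
            raise ValueError("at most one of ref/alt may be '-'")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def variant_class(self) -> str:
        if self.ref == _GAP:
            return "insertion"
        if self.alt == _GAP:
            return "deletion"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SBS"
        if len(self.ref) == 2 and len(self.alt) == 2:
            return "DBS"
        return "MNV" if len(self.ref) == len(self.alt) else "complex"

    @property
    def vaf(self) -> Optional[float]:
        depth = self.ref_count + self.alt_count
        return self.alt_count / depth if depth > 0 else None

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (0 for insertions)."""
        return 0 if self.ref == _GAP else len(self.ref)


@dataclass(frozen=True)
class MafDialect:
    """Mapping from logical fields to a MAF's header names."""

    chrom: str = "Chromosome"
    pos: str = "Start_Position"
    ref: str = "Reference_Allele"
    alt: str = "Tumor_Seq_Allele2"
    ref_count: str = "t_ref_count"
    alt_count: str = "t_alt_count"
    filter: str = "FILTER"
    sample_id: str = "Tumor_Sample_Barcode"
    gene: Optional[str] = "Hugo_Symbol"
    strand: Optional[str] = "STRAND"
    cds_pos: Optional[str] = "CDS_position"
    n_callers: Optional[str] = None

    @property
    def required(self) -> dict:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "ref_count": self.ref_count,
            "alt_count": self.alt_count,
            "filter": self.filter,
            "sample_id": self.sample_id,
        }


MC3_DIALECT = MafDialect()

MINIMAL_DIALECT = MafDialect(
    chrom="chrom",
    pos="pos",
    ref="ref",
    alt="alt",
    ref_count="ref_count",
    alt_count="alt_count",
    filter="filter",
    sample_id="sample",
    gene="gene",
    strand="strand",
    cds_pos="cds_pos",
)


def _parse_flags(value) -> frozenset:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    return frozenset(f for f in re.split(r"[,;]", str(value).strip()) if f)


def _opt_int(value):
    if value is None or value == "" or value == ".":
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return int(value)


def read_maf(path, dialect: MafDialect = MC3_DIALECT) -> list[VariantRecord]:
    """Read a MAF-style table into a list of :class:`VariantRecord`.

    Raises :class:`MafFormatError` naming the first missing required
    column, and :class:`MafRowError` with a 1-based line number for rows
    whose position or counts fail to parse.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for logical, col in dialect.required.items():
        if col not in df.columns:
            raise MafFormatError(
                f"missing required column {col!r} (field {logical}) in {path}"
            )
    records: list[VariantRecord] = []
    optional = {
        "gene": dialect.gene,
        "strand": dialect.strand,
        "cds_pos": dialect.cds_pos,
        "n_callers": dialect.n_callers,
    }
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rowd = dict(zip(df.columns, row))
        try:
            pos = int(rowd[dialect.pos])
            ref_count = int(float(rowd[dialect.ref_count]))
            alt_count = int(float(rowd[dialect.alt_count]))
        except (TypeError, ValueError) as exc:
            raise MafRowError(f"{path} line {line}: unparseable value ({exc})") from exc
        kwargs = {}
        for fieldname, col in optional.items():
            if col and col in df.columns:
                raw = rowd[col]
                if fieldname in ("cds_pos", "n_callers"):
                    try:
                        kwargs[fieldname] = _opt_int(raw)
                    except ValueError as exc:
                        raise MafRowError(
                            f"{path} line {line}: bad {fieldname} ({raw!r})"
                        ) from exc
                else:
                    kwargs[fieldname] = raw if raw not in ("", ".") else None
        records.append(
            VariantRecord(
                chrom=str(rowd[dialect.chrom]),
                pos=pos,
                ref=str(rowd[dialect.ref]).upper(),
                alt=str(rowd[dialect.alt]).upper(),
                ref_count=ref_count,
                alt_count=alt_count,
                filter_flags=_parse_flags(rowd[dialect.filter]),
                sample_id=str(rowd[dialect.sample_id]),
                **kwargs,
            )
        )
    logger.info("read %d variant records from %s", len(records), path)
    return records


def filter_by_flags(
    records: Sequence[VariantRecord], allowed: Iterable[str]
) -> list[VariantRecord]:
    """Keep records whose FILTER flags are a subset of `allowed`.

    Subset semantics mean any combination of allowed flags passes, while a
    single disallowed flag rejects the call.
    """
    allowed = frozenset(allowed)
    kept = [r for r in records if r.filter_flags <= allowed]
    logger.info("filter_by_flags: kept %d / %d", len(kept), len(records))
    return kept


def filter_by_caller_count(
    records: Sequence[VariantRecord], min_callers: int = 2
) -> list[VariantRecord]:
    """Keep records supported by at least `min_callers` mutation callers.

    Records without caller-count annotation are kept (the column is not
    present in every dialect).
    """
    kept = [r for r in records if r.n_callers is None or r.n_callers >= min_callers]
    logger.info("filter_by_caller_count: kept %d / %d", len(kept), len(records))
    return kept


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file into (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def _merged_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        acc = []
        for s, e in ivals:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = np.array(acc, dtype=np.int64).reshape(-1, 2)
    return merged


def intersect_intervals(
    records: Sequence[VariantRecord],
    intervals: Iterable[tuple[str, int, int]],
) -> list[VariantRecord]:
    """Keep records whose full reference span lies inside the interval union.

    Intervals are BED-style 0-based half-open. A record's span is
    ``[pos-1, pos-1+max(ref_span, 1))``; insertions therefore test their
    single anchor base. Records on chromosomes absent from the intervals
    are dropped with a warning.
    """
    merged = _merged_intervals(intervals)
    kept: list[VariantRecord] = []
    warned: set[str] = set()
    for r in records:
        ivals = merged.get(r.chrom)
        if ivals is None:
            if r.chrom not in warned:
                logger.warning("dropping records on unknown chromosome %r", r.chrom)
                warned.add(r.chrom)
            continue
        start = r.pos - 1
        end = start + max(r.ref_span, 1)
        # rightmost interval starting at or before `start`
        i = int(np.searchsorted(ivals[:, 0], start, side="right")) - 1
        if i >= 0 and end <= ivals[i, 1]:
            kept.append(r)
    logger.info("intersect_intervals: kept %d / %d", len(kept), len(records))
    return kept


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _run_qualifies(
    run: Sequence[VariantRecord],
    count_tol: float,
    pct_tol: float,
    vaf_tol: float,
    pct_mode: str,
    vaf_mode: str,
) -> bool:
    alts = np.array([r.alt_count for r in run], dtype=float)
    refs = np.array([r.ref_count for r in run], dtype=float)
    # criterion 1: every count close to its family mean in absolute reads
    dev = max(np.abs(alts - alts.mean()).max(), np.abs(refs - refs.mean()).max())
    if dev < count_tol:
        return True
    # criterion 2: relative deviation of counts
    if pct_mode == "vs_mean":
        pct = 0.0
        for counts in (alts, refs):
            m = counts.mean()
            if m > 0:
                pct = max(pct, (np.abs(counts - m) / m).max())
            elif np.any(counts > 0):
                pct = np.inf
        if pct < pct_tol:
            return True
    elif pct_mode == "pairwise":
        pct = 0.0
        for counts in (alts, refs):
            hi, lo = counts.max(), counts.min()
            if hi > 0:
                pct = max(pct, (hi - lo) / hi)
        if pct < pct_tol:
            return True
    else:  # pragma: no cover - config validation
        raise ValueError(f"unknown pct_mode {pct_mode!r}")
    # criterion 3: variant allele fraction deviation
    depths = alts + refs
    if np.all(depths > 0):
        vafs = alts / depths
        if vaf_mode == "pairwise":
            dv = vafs.max() - vafs.min()
        elif vaf_mode == "vs_mean":
            dv = np.abs(vafs - vafs.mean()).max()
        else:  # pragma: no cover
            raise ValueError(f"unknown vaf_mode {vaf_mode!r}")
        if dv < vaf_tol:
            return True
    return False


def _merge_run(run: Sequence[VariantRecord]) -> VariantRecord:
    flags = frozenset().union(*(r.filter_flags for r in run))
    return replace(
        run[0],
        ref="".join(r.ref for r in run),
        alt="".join(r.alt for r in run),
        ref_count=_round_half_up(float(np.mean([r.ref_count for r in run]))),
        alt_count=_round_half_up(float(np.mean([r.alt_count for r in run]))),
        filter_flags=flags,
    )


def merge_consecutive_snvs(
    records: Sequence[VariantRecord],
    count_tol: float = 5.0,
    pct_tol: float = 0.05,
    vaf_tol: float = 0.05,
    pct_mode: str = "vs_mean",
    vaf_mode: str = "pairwise",
) -> list[VariantRecord]:
    """Merge runs of consecutive same-sample SBSs into one substitution.

    A maximal run of single-base substitutions at strictly consecutive
    positions (same sample, same chromosome) is merged when ANY of three
    read-count agreement criteria holds over the whole run:

    1. every alt count is within `count_tol` reads of the run's mean alt
       count, and likewise for ref counts;
    2. the relative deviation of each count from its family mean
       (`pct_mode="vs_mean"`, default) or the max pairwise relative range
       (`pct_mode="pairwise"`) is below `pct_tol`;
    3. the spread of variant allele fractions — max pairwise difference by
       default (`vaf_mode="pairwise"`) or deviation from the mean
       (`vaf_mode="vs_mean"`) — is below `vaf_tol`.

    The merged record takes the run's first position, concatenated
    ref/alt alleles, the union of FILTER flags, and mean counts rounded
    half-up (which keeps the merged alt count within the constituent
    range). The operation is idempotent: merged products are no longer
    SBSs and are never re-merged. Output is sorted by
    (sample, chromosome, position).
    """
    keyed = sorted(records, key=lambda r: (r.sample_id, r.chrom, r.pos))
    out: list[VariantRecord] = []
    n_merged_runs = 0
    for _, group in groupby(keyed, key=lambda r: (r.sample_id, r.chrom)):
        group = list(group)
        i = 0
        while i < len(group):
            r = group[i]
            if r.variant_class != "SBS":
                out.append(r)
                i += 1
                continue
            j = i + 1
            while (
                j < len(group)
                and group[j].variant_class == "SBS"
                and group[j].pos == group[j - 1].pos + 1
            ):
                j += 1
            run = group[i:j]
            if len(run) >= 2 and _run_qualifies(
                run, count_tol, pct_tol, vaf_tol, pct_mode, vaf_mode
            ):
                out.append(_merge_run(run))
                n_merged_runs += 1
            else:
                out.extend(run)
            i = j
    if n_merged_runs:
        logger.info(
            "merge_consecutive_snvs: merged %d runs (%d -> %d records)",
            n_merged_runs,
            len(records),
            len(out),
        )
    return out
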
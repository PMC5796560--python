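"""Core domain types, pipeline parameters and genome-mask handling.

Every coordinate in this package is 0-based, half-open (BED convention).
SAM input (1-based) is converted at the reader; BED output needs no
conversion.

The pipeline targets the three human TE subfamilies that account for the
bulk of ongoing retrotransposition: L1HS (LINE1 class) and the AluYa5/8 and
AluYb8/9 groups (Alu class). Each subfamily is described by a
:class:`SubfamilyProfile` carrying the assay's two primers, the subfamily's
diagnostic "TE-like" consensus stretch between the nested primer and the
poly-A tail, and the per-subfamily mismatch cap used to keep a read pair.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InputError(ValueError):
    """Malformed input data (bad interval, bad sequence, unsorted file)."""


class ConfigError(ValueError):
    """Inconsistent or missing configuration."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"{what} is empty")
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise InputError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class SubfamilyProfile:
    """One targeted TE subfamily: primers, TE-like sequence, mismatch cap.

    ``te_like`` is the subfamily consensus immediately 3' of the nested
    primer, up to (excluding) the poly-A tail; ``max_te_like_mismatches``
    is the largest number of substitutions against it for which a read 2
    is still considered TE-derived.
    """

    name: str
    te_class: str  # "LINE1" or "Alu"
    target_primer: str
    nested_primer: str
    te_like: str
    max_te_like_mismatches: int
    index_tag: str = ""

    def __post_init__(self) -> None:
        if self.te_class not in ("LINE1", "Alu"):
            raise ConfigError(f"unknown TE class {self.te_class!r}")
        _check_dna(self.target_primer, f"{self.name} target primer")
        _check_dna(self.nested_primer, f"{self.name} nested primer")
        _check_dna(self.te_like, f"{self.name} TE-like sequence")
        if self.max_te_like_mismatches < 0:
            raise ConfigError("max_te_like_mismatches must be >= 0")


def default_profiles() -> dict[str, SubfamilyProfile]:
    """The three shipped subfamily profiles.

    The sequences below are synthetic stand-ins: they reproduce the assay's
    structural layout (primer lengths typical of the protocol, TE-like
    lengths of 8, 37 and 29 nt for L1HS, AluYa5/8 and AluYb8/9 and mismatch
    caps of 3, 10 and 10) but are not the proprietary genomic primer
    sequences, which users supply via their own profile configuration when
    analysing real libraries.
    """
    return {
        "L1HS": SubfamilyProfile(
            name="L1HS",
            te_class="LINE1",
            target_primer="AGGAGCCAAGATGGCCGAAT",
            nested_primer="CCTAATGCTAGATGACACAG",
            te_like="TGGTGACC",
            max_te_like_mismatches=3,
            index_tag="i7-L1",
        ),
        "AluYa5/8": SubfamilyProfile(
            name="AluYa5/8",
            te_class="Alu",
            target_primer="GAGCGAGACTCCGTCTCAAA",
            nested_primer="CGAGATCGAGACCATCCCGG",
            te_like="CTAAAACGGTGAAACCCCGTCTCTACTGAAAATACAG",
            max_te_like_mismatches=10,
            index_tag="i7-Ya",
        ),
        "AluYb8/9": SubfamilyProfile(
            name="AluYb8/9",
            te_class="Alu",
            target_primer="GGATTACAGGCGTGAGCCAC",
            nested_primer="CGCCTGTAGTCCCAGCTACT",
            te_like="CGGGAGGCTGAGGCAGGAGAATGGCGTGC",
            max_te_like_mismatches=10,
            index_tag="i7-Yb",
        ),
    }


#: Which reference-annotation subfamily names satisfy each targeted library.
DEFAULT_SUBFAMILY_SYNONYMS: dict[str, frozenset[str]] = {
    "L1HS": frozenset({"L1HS", "L1Ta"}),
    "AluYa5/8": frozenset({"AluYa5/8", "AluYa5", "AluYa8"}),
    "AluYb8/9": frozenset({"AluYb8/9", "AluYb8", "AluYb9"}),
}

#: TE class of each shipped library name (used when only class-level
#: annotation is available, as in polymorphic-TE databases).
DEFAULT_SUBFAMILY_CLASS: dict[str, str] = {
    "L1HS": "LINE1",
    "AluYa5/8": "Alu",
    "AluYb8/9": "Alu",
}


@dataclass(frozen=True)
class PipelineParams:
    """All numeric knobs of the calling pipeline, with assay defaults.

    The defaults encode the published operating point of the assay:
    read 2 must start with the full nested primer (a partial match is
    defined as >= 7 of the first 10 primer bases); read pairs with an
    unmapped read 1 or read-1 MAPQ 0 are removed; clusters join read-1
    anchors closer than 200 bp, must span >= 100 bp, and need >= 2 read-1
    members at MAPQ >= 3; annotation matching uses a 600 bp window around
    the TE 3' end; gaps are masked with a 500 bp flank and satellite
    regions (centromeres/sub-telomeres) with a 1 Mb window; chrY is
    excluded; trio comparisons use a 100 bp window.
    """

    primer_partial_min_matches: int = 7
    primer_prefix_len: int = 10
    min_report_mapq: int = 1
    min_cluster_mapq: int = 3
    cluster_gap_bp: int = 200
    min_cluster_span_bp: int = 100
    min_read1_per_cluster: int = 2
    annotation_window_bp: int = 600
    gap_flank_bp: int = 500
    satellite_window_bp: int = 1_000_000
    excluded_chroms: frozenset[str] = frozenset({"chrY"})
    parental_window_bp: int = 100
    primer_scan_max_mismatch: int = 1
    target_pair_max_gap_bp: int = 200
    inverted_max_span_bp: int = 1000
    polya_min_run: int = 8
    polya_max_nonA: int = 1

    def __post_init__(self) -> None:
        for name in (
            "primer_partial_min_matches", "primer_prefix_len",
            "min_report_mapq", "min_cluster_mapq", "cluster_gap_bp",
            "min_cluster_span_bp", "min_read1_per_cluster",
            "annotation_window_bp", "gap_flank_bp", "satellite_window_bp",
            "parental_window_bp", "primer_scan_max_mismatch",
            "target_pair_max_gap_bp", "inverted_max_span_bp",
            "polya_min_run", "polya_max_nonA",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.primer_partial_min_matches > self.primer_prefix_len:
            raise ConfigError(
                "primer_partial_min_matches cannot exceed primer_prefix_len"
            )
        object.__setattr__(self, "excluded_chroms", frozenset(self.excluded_chroms))


Interval = tuple[int, int]


def _expand_and_merge(
    intervals: Iterable[tuple[str, int, int]], flank: int
) -> dict[str, list[Interval]]:
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, start, end in intervals:
        if start > end:
            raise InputError(f"interval start > end: {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((max(0, start - flank), end + flank))
    merged: dict[str, list[Interval]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[Interval] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


@dataclass
class GenomeMask:
    """Excluded genomic territory: flanked gaps, widened satellite regions
    and whole excluded chromosomes.

    Intervals are stored per chromosome, sorted, merged and half-open; a
    query overlaps the mask if it shares >= 1 bp with any stored interval
    or lies on an excluded chromosome.
    """

    gap_intervals: dict[str, list[Interval]] = field(default_factory=dict)
    satellite_intervals: dict[str, list[Interval]] = field(default_factory=dict)
    excluded_chroms: frozenset[str] = frozenset()
    _warned_chroms: set[str] = field(default_factory=set, repr=False)

    def all_intervals(self, chrom: str) -> list[Interval]:
        ivs = self.gap_intervals.get(chrom, []) + self.satellite_intervals.get(chrom, [])
        return sorted(ivs)


def build_mask(
    gap_intervals: Iterable[tuple[str, int, int]],
    satellite_intervals: Iterable[tuple[str, int, int]],
    params: PipelineParams,
) -> GenomeMask:
    """Build a :class:`GenomeMask` from raw gap and satellite intervals.

    Gaps are expanded by ``gap_flank_bp`` on each side, satellite regions
    by ``satellite_window_bp``; intervals are clamped at 0 and merged.
    """
    return GenomeMask(
        gap_intervals=_expand_and_merge(gap_intervals, params.gap_flank_bp),
        satellite_intervals=_expand_and_merge(
            satellite_intervals, params.satellite_window_bp
        ),
        excluded_chroms=frozenset(params.excluded_chroms),
    )


def _overlaps_sorted(ivs: Sequence[Interval], start: int, end: int) -> bool:
    # ivs sorted, non-overlapping; find candidate by start position
    i = bisect_right(ivs, (start, float("inf")))
    if i < len(ivs) and ivs[i][0] < end:
        return True
    if i > 0 and ivs[i - 1][1] > start:
        return True
    return False


def in_mask(mask: GenomeMask, chrom: str, start: int, end: int) -> bool:
    """True iff the half-open query overlaps the mask by >= 1 bp or lies on
    an excluded chromosome. Unknown chromosomes are silently unmasked
    (logged once per chromosome)."""
    if chrom in mask.excluded_chroms:
        return True
    known = chrom in mask.gap_intervals or chrom in mask.satellite_intervals
    if not known:
        if chrom not in mask._warned_chroms:
            mask._warned_chroms.add(chrom)
            logger.debug("chromosome %s not present in mask; treated as unmasked", chrom)
        return False
    for ivs in (mask.gap_intervals.get(chrom, ()), mask.satellite_intervals.get(chrom, ())):
        if ivs and _overlaps_sorted(ivs, start, end):
            return True
    return False


@dataclass(frozen=True)
class Read1:
    """Read-1 alignment state: the unique-flank anchor of a pair."""

    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: str = "+"
    mapq: int = 0
    is_mapped: bool = True

    def __post_init__(self) -> None:
        if self.is_mapped:
            if self.chrom is None or self.start is None or self.end is None:
                raise InputError("mapped read 1 requires chrom/start/end")
            if self.start >= self.end:
                raise InputError("read 1 start must be < end")


@dataclass(frozen=True)
class Read2:
    """Read 2: the TE-derived mate (primer + TE-like + poly-A + flank)."""

    sequence: str
    is_mapped: bool = False
    mapq: int = 0


@dataclass(frozen=True)
class AlignedPair:
    """One read pair from a sample x subfamily targeted library."""

    sample_id: str
    subfamily_name: str
    read1: Read1
    read2: Read2
    is_duplicate: bool = False
    pair_id: str = ""


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN bookkeeping with precision = TP/(TP+FP), recall = TP/(TP+FN).

    A metric whose denominator is zero is undefined and reported as NaN
    with the corresponding ``*_defined`` flag set to False.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise InputError("TP/FP/FN counts must be non-negative")

    @property
    def precision_defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def recall_defined(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.precision_defined else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.recall_defined else float("nan")


__all__ = [
    "AlignedPair",
    "ConfigError",
    "DEFAULT_SUBFAMILY_CLASS",
    "DEFAULT_SUBFAMILY_SYNONYMS",
    "EvalResult",
    "GenomeMask",
    "InputError",
    "PipelineParams",
    "Read1",
    "Read2",
    "SubfamilyProfile",
    "build_mask",
    "default_profiles",
    "in_mask",
    "revcomp",
]
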
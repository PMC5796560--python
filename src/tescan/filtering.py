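"""Per-read-pair filtering: mobilome vs genomic-background discrimination.

Read 2 of an on-target pair starts with the subfamily's nested primer,
continues through the TE-like consensus stretch and the poly-A tail, and
may run into unique flank. Read 1 comes from the unique flank and anchors
the insertion site. Filtering therefore requires, in order: the pair not
be a PCR duplicate; read 2 begin with the full-length nested primer
exactly; the TE-like region carry at most the subfamily's mismatch cap;
read 1 be mapped with MAPQ above 0. Read 2 mapping state is never
required — non-reference insertions routinely leave read 2 unmapped.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import AlignedPair, InputError, PipelineParams, SubfamilyProfile


class PrimerClass(enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


class FilterReason(enum.Enum):
    OK = "OK"
    NO_PRIMER = "NO_PRIMER"
    PARTIAL_PRIMER = "PARTIAL_PRIMER"
    TE_LIKE_EXCEEDED = "TE_LIKE_EXCEEDED"
    TE_LIKE_UNCOVERED = "TE_LIKE_UNCOVERED"  # read ends inside the primer
    READ1_UNMAPPED = "READ1_UNMAPPED"
    MAPQ_ZERO = "MAPQ_ZERO"
    DUPLICATE = "DUPLICATE"


@dataclass(frozen=True)
class FilterResult:
    """Outcome of filtering one read pair.

    ``polya_detected`` is annotation only; it never changes the verdict.
    """

    keep: bool
    reason: FilterReason
    primer_class: PrimerClass
    te_like_mismatches: Optional[int]
    te_like_covered: int
    polya_detected: bool

    @property
    def verdict(self) -> str:
        return "keep" if self.keep else "drop"


def classify_primer_match(
    read2_sequence: str, nested_primer: str, params: PipelineParams
) -> PrimerClass:
    """FULL iff the read begins with the entire primer exactly; else
    PARTIAL iff at least ``primer_partial_min_matches`` of the first
    ``primer_prefix_len`` primer bases match the read position-wise;
    else NONE."""
    if not read2_sequence:
        raise InputError("empty read 2 sequence")
    read = read2_sequence.upper()
    primer = nested_primer.upper()
    if read.startswith(primer):
        return PrimerClass.FULL
    prefix = primer[: params.primer_prefix_len]
    hits = sum(
        1 for i in range(min(len(prefix), len(read))) if read[i] == prefix[i]
    )
    if hits >= params.primer_partial_min_matches:
        return PrimerClass.PARTIAL
    return PrimerClass.NONE


def te_like_mismatches(
    read2_sequence: str, profile: SubfamilyProfile
) -> tuple[Optional[int], int]:
    """Position-wise mismatches of the read bases immediately after the
    primer against the profile's TE-like sequence.

    Returns ``(mismatches, covered)`` where covered = min(remaining read
    length, len(te_like)); mismatches are counted over covered positions
    only, and are None when covered == 0.
    """
    read = read2_sequence.upper()
    region = read[len(profile.nested_primer): len(profile.nested_primer) + len(profile.te_like)]
    covered = len(region)
    if covered == 0:
        return None, 0
    mm = sum(1 for a, b in zip(region, profile.te_like) if a != b)
    return mm, covered


def detect_polya(
    read2_sequence: str, profile: SubfamilyProfile, params: PipelineParams
) -> bool:
    """True iff, 3' of the TE-like region, some window of length
    ``polya_min_run`` contains at most ``polya_max_nonA`` non-A bases."""
    read = read2_sequence.upper()
    tail = read[len(profile.nested_primer) + len(profile.te_like):]
    w = params.polya_min_run
    if w == 0:
        return True
    if len(tail) < w:
        return False
    non_a = sum(1 for c in tail[:w] if c != "A")
    if non_a <= params.polya_max_nonA:
        return True
    for i in range(1, len(tail) - w + 1):
        non_a += (tail[i + w - 1] != "A") - (tail[i - 1] != "A")
        if non_a <= params.polya_max_nonA:
            return True
    return False


def filter_pair(
    pair: AlignedPair, profile: SubfamilyProfile, params: PipelineParams
) -> FilterResult:
    """Apply the full per-pair filter cascade; pure function of its inputs.

    Order: duplicate flag, primer classification, TE-like coverage and
    mismatch cap, read-1 mapped, read-1 MAPQ above the reporting floor.
    """
    if not pair.read2.sequence:
        raise InputError(f"pair {pair.pair_id!r} is missing the read 2 sequence")

    def drop(reason: FilterReason, pc: PrimerClass,
             mm: Optional[int] = None, cov: int = 0, polya: bool = False) -> FilterResult:
        return FilterResult(False, reason, pc, mm, cov, polya)

    if pair.is_duplicate:
        return drop(FilterReason.DUPLICATE, PrimerClass.NONE)
    pc = classify_primer_match(pair.read2.sequence, profile.nested_primer, params)
    if pc is PrimerClass.NONE:
        return drop(FilterReason.NO_PRIMER, pc)
    if pc is PrimerClass.PARTIAL:
        return drop(FilterReason.PARTIAL_PRIMER, pc)
    mm, covered = te_like_mismatches(pair.read2.sequence, profile)
    if covered == 0:
        return drop(FilterReason.TE_LIKE_UNCOVERED, pc, None, 0)
    polya = detect_polya(pair.read2.sequence, profile, params)
    if mm is not None and mm > profile.max_te_like_mismatches:
        return drop(FilterReason.TE_LIKE_EXCEEDED, pc, mm, covered, polya)
    if not pair.read1.is_mapped:
        return drop(FilterReason.READ1_UNMAPPED, pc, mm, covered, polya)
    if pair.read1.mapq < params.min_report_mapq:
        return drop(FilterReason.MAPQ_ZERO, pc, mm, covered, polya)
    return FilterResult(True, FilterReason.OK, pc, mm, covered, polya)


def apply_filters(
    pairs: Iterable[AlignedPair],
    profile: SubfamilyProfile,
    params: PipelineParams,
) -> tuple[list[tuple[AlignedPair, FilterResult]], Counter]:
    """Filter a whole library.

    Returns the kept ``(pair, result)`` list and a Counter of every
    filter reason (including OK), so that kept + dropped-by-reason counts
    always sum to the number of input pairs.
    """
    kept: list[tuple[AlignedPair, FilterResult]] = []
    tally: Counter = Counter()
    for pair in pairs:
        res = filter_pair(pair, profile, params)
        tally[res.reason] += 1
        if res.keep:
            kept.append((pair, res))
    return kept, tally


def filter_summary(tally: Counter) -> dict[str, float]:
    """Per-library summary: counts by reason plus the on-target fractions
    the assay reports (fraction of pairs with a discernible primer match,
    i.e. FULL or PARTIAL, and the strictly-FULL fraction)."""
    total = sum(tally.values())
    out: dict[str, float] = {r.value: tally.get(r, 0) for r in FilterReason}
    out["total"] = total
    no_primer = tally.get(FilterReason.NO_PRIMER, 0)
    dup = tally.get(FilterReason.DUPLICATE, 0)
    denom = total - dup
    if denom > 0:
        out["discernible_primer_fraction"] = (denom - no_primer) / denom
        full = denom - no_primer - tally.get(FilterReason.PARTIAL_PRIMER, 0)
        out["full_primer_fraction"] = full / denom
    return out


__all__ = [
    "FilterReason",
    "FilterResult",
    "PrimerClass",
    "apply_filters",
    "classify_primer_match",
    "detect_polya",
    "filter_pair",
    "filter_summary",
    "te_like_mismatches",
]
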
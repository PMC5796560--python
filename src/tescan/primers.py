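"""Primer-site genomics on a reference sequence.

Mismatch-tolerant primer matching (both strands, exact-3'-end rule),
construction of the targeted-locus set (target + nested primer in proper
order/orientation), detection of head-to-head inverted-repeat primer pairs
(an amplification-artifact class), and derivation of the TE-like sequence
from a subfamily consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import (
    DNA_ALPHABET,
    GenomeMask,
    InputError,
    PipelineParams,
    in_mask,
    revcomp,
)


@dataclass(frozen=True)
class PrimerMatch:
    """A primer hit on the forward-strand coordinate system.

    ``pos`` is the 0-based position of the match's 5'-most reference base
    on the forward strand regardless of strand; ``length`` is the primer
    length, so the occupied window is ``[pos, pos + length)``.
    """

    primer_id: str
    chrom: str
    pos: int
    strand: str  # "+" or "-"
    n_mismatch: int
    length: int

    @property
    def three_prime_pos(self) -> int:
        """Reference position of the base pairing the primer's 3'-ultimate
        base: rightmost window base on "+", leftmost on "-"."""
        return self.pos + self.length - 1 if self.strand == "+" else self.pos


@dataclass(frozen=True)
class TargetLocus:
    """A reference locus carrying both primers in amplifiable layout."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily_name: str
    target_match: PrimerMatch
    nested_match: PrimerMatch


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two opposite-strand primer matches with facing 3' ends."""

    chrom: str
    match_a: PrimerMatch  # "+" strand, upstream
    match_b: PrimerMatch  # "-" strand, downstream
    span_bp: int


def _hamming_window(seq: str, pos: int, pattern: str, cap: int) -> Optional[int]:
    """Mismatches of seq[pos:pos+len(pattern)] vs pattern, or None if > cap
    or the window contains a non-ACGT base."""
    n = 0
    for i, p in enumerate(pattern):
        c = seq[pos + i]
        if c not in "ACGT":
            return None
        if c != p:
            n += 1
            if n > cap:
                return None
    return n


def scan_primer(
    genome_sequence: str,
    primer: str,
    params: PipelineParams,
    chrom: str = "chr1",
    primer_id: str = "primer",
) -> list[PrimerMatch]:
    """All primer matches on either strand of ``genome_sequence``.

    A position matches when the Hamming distance to the primer is at most
    ``primer_scan_max_mismatch`` AND the base pairing the primer's
    3'-ultimate base is an exact match. Windows containing N (or any
    non-ACGT base) never match. Minus-strand hits are reported in
    forward-strand coordinates with strand "-".
    """
    if not primer:
        raise InputError("empty primer")
    primer = primer.upper()
    bad = set(primer) - DNA_ALPHABET
    if bad:
        raise InputError(f"primer contains non-ACGT characters: {sorted(bad)}")
    seq = genome_sequence.upper()
    L, m = len(seq), len(primer)
    cap = params.primer_scan_max_mismatch
    matches: list[PrimerMatch] = []
    if m > L:
        return matches
    rc = revcomp(primer)  # minus-strand binding site on the forward strand
    for pos in range(L - m + 1):
        # forward strand: 3'-ultimate primer base pairs seq[pos + m - 1]
        if seq[pos + m - 1] == primer[-1]:
            n = _hamming_window(seq, pos, primer, cap)
            if n is not None:
                matches.append(PrimerMatch(primer_id, chrom, pos, "+", n, m))
        # minus strand: primer binds revcomp; its 3'-ultimate base pairs
        # the leftmost forward-strand base of the window, which must equal
        # rc[0] (= complement of primer's last base)
        if seq[pos] == rc[0]:
            n = _hamming_window(seq, pos, rc, cap)
            if n is not None:
                matches.append(PrimerMatch(primer_id, chrom, pos, "-", n, m))
    matches.sort(key=lambda mt: (mt.pos, mt.strand))
    return matches


def build_target_set(
    target_matches: Sequence[PrimerMatch],
    nested_matches: Sequence[PrimerMatch],
    mask: Optional[GenomeMask],
    cnv_intervals: Optional[Iterable[tuple[str, int, int]]],
    params: PipelineParams,
    subfamily_name: str = "",
) -> list[TargetLocus]:
    """Pair target- and nested-primer matches into targeted loci.

    A locus requires both matches on the same strand and chromosome, the
    nested match 3' of the target match, and a gap (distance between the
    two match start positions) of at most ``target_pair_max_gap_bp``.
    Loci overlapping the genome mask or any supplied copy-number-variant
    interval are removed.
    """
    cnv_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if cnv_intervals is not None:
        for c, s, e in cnv_intervals:
            cnv_by_chrom.setdefault(c, []).append((s, e))
    loci: list[TargetLocus] = []
    nested_sorted = sorted(nested_matches, key=lambda mt: (mt.chrom, mt.pos))
    for t in target_matches:
        for n in nested_sorted:
            if n.chrom != t.chrom or n.strand != t.strand:
                continue
            if t.strand == "+":
                downstream, gap = n.pos > t.pos, n.pos - t.pos
            else:
                downstream, gap = n.pos < t.pos, t.pos - n.pos
            if not downstream or gap > params.target_pair_max_gap_bp:
                continue
            start = min(t.pos, n.pos)
            end = max(t.pos + t.length, n.pos + n.length)
            if mask is not None and in_mask(mask, t.chrom, start, end):
                continue
            if any(s < end and start < e for s, e in cnv_by_chrom.get(t.chrom, ())):
                continue
            loci.append(
                TargetLocus(t.chrom, start, end, t.strand, subfamily_name, t, n)
            )
    loci.sort(key=lambda lo: (lo.chrom, lo.start, lo.end))
    return loci


def find_inverted_repeats(
    matches_all_primers: Sequence[PrimerMatch],
    params: PipelineParams,
) -> list[InvertedRepeatPair]:
    """Head-to-head pairs: a "+" match upstream of a "-" match with their
    3' ends pointing toward each other, separated by at most
    ``inverted_max_span_bp`` (span measured between the two 3'-end
    positions). Each pair is reported once, sorted by coordinate."""
    plus = sorted(
        (m for m in matches_all_primers if m.strand == "+"),
        key=lambda m: (m.chrom, m.pos),
    )
    minus = sorted(
        (m for m in matches_all_primers if m.strand == "-"),
        key=lambda m: (m.chrom, m.pos),
    )
    pairs: list[InvertedRepeatPair] = []
    for p in plus:
        for q in minus:
            if q.chrom != p.chrom:
                continue
            span = q.three_prime_pos - p.three_prime_pos
            if 0 <= span <= params.inverted_max_span_bp:
                pairs.append(InvertedRepeatPair(p.chrom, p, q, span))
    pairs.sort(key=lambda pr: (pr.chrom, pr.match_a.pos, pr.match_b.pos))
    return pairs


def derive_te_like(consensus_sequence: str, nested_primer: str) -> str:
    """TE-like sequence from a subfamily consensus: the bases after the
    single exact nested-primer match, up to (excluding) the terminal
    poly-A run.

    The terminal poly-A run is the maximal trailing run of A's, which must
    be at least 8 nt (a consensus without a recognizable tail is rejected).
    """
    consensus = consensus_sequence.upper()
    primer = nested_primer.upper()
    if not primer:
        raise InputError("empty nested primer")
    first = consensus.find(primer)
    if first < 0:
        raise InputError("nested primer not found in consensus")
    if consensus.find(primer, first + 1) >= 0:
        raise InputError("nested primer matches consensus more than once")
    after = consensus[first + len(primer):]
    tail = len(after) - len(after.rstrip("A"))
    if tail < 8:
        raise InputError("consensus lacks a terminal poly-A run (>= 8 A's)")
    te_like = after[: len(after) - tail]
    if not te_like:
        raise InputError(
            "nested primer abuts the poly-A tail; TE-like sequence is empty"
        )
    return te_like


__all__ = [
    "InvertedRepeatPair",
    "PrimerMatch",
    "TargetLocus",
    "build_target_set",
    "derive_te_like",
    "find_inverted_repeats",
    "scan_primer",
]
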
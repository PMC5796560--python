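"""Truth-set evaluation: TP/FP/FN bookkeeping, precision/recall, trio
parental truth sets and de novo classification, long-read validation, and
descriptive support summaries.

Truth matching is greedy one-to-one by increasing distance: a truth record
is a true positive when a call of the required annotation level (subfamily
for reference truth, TE class for MEI truth) lies within the annotation
window of its 3' anchor; unmatched truth records are false negatives and
unmatched calls false positives. One-to-one matching prevents a single
cluster from satisfying two truth records (or vice versa).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import TECall, anchor_distance, subfamily_matches
from .clustering import Cluster, apply_cluster_thresholds
from .core import (
    DEFAULT_SUBFAMILY_CLASS,
    DEFAULT_SUBFAMILY_SYNONYMS,
    EvalResult,
    InputError,
    PipelineParams,
    SubfamilyProfile,
    revcomp,
)

REFERENCE_TRUTH = "reference_truth"
MEI_TRUTH = "mei_truth"
PARENTAL_TRUTH = "parental_truth"


@dataclass(frozen=True)
class TruthRecord:
    """One truth insertion, anchored at its 3' terminal position."""

    chrom: str
    anchor_pos: int
    subfamily: Optional[str]
    te_class: Optional[str]
    source: str
    record_id: str = ""


@dataclass
class TrioResult:
    """Proband evaluation against a parental truth set."""

    parental_truth_size: int
    observed_in_proband: int
    proband_novel_inherited: int
    proband_de_novo: int
    per_subfamily: dict[str, EvalResult]


def _level_matches(
    call: TECall,
    truth: TruthRecord,
    match_level: str,
    synonyms: Mapping[str, frozenset[str]],
    class_of: Mapping[str, str],
) -> bool:
    sub = call.cluster.subfamily_name
    if match_level == "subfamily":
        if truth.subfamily is None:
            return False
        return truth.subfamily == sub or subfamily_matches(sub, truth.subfamily, synonyms)
    if match_level == "class":
        return truth.te_class is not None and truth.te_class == class_of.get(sub)
    raise InputError(f"unknown match level {match_level!r}")


def match_calls_to_truth(
    calls: Sequence[TECall],
    truth_records: Sequence[TruthRecord],
    params: PipelineParams,
    match_level: str = "subfamily",
    synonyms: Mapping[str, frozenset[str]] = DEFAULT_SUBFAMILY_SYNONYMS,
    class_of: Mapping[str, str] = DEFAULT_SUBFAMILY_CLASS,
) -> tuple[list[tuple[TruthRecord, TECall]], list[TECall], list[TruthRecord]]:
    """Greedy one-to-one matching of calls to truth anchors.

    Returns ``(tp_pairs, fp_calls, fn_truth)``: matched (truth, call)
    pairs, calls matching no truth record, and unmatched truth records.
    """
    edges: list[tuple[int, int, int]] = []  # (distance, truth_idx, call_idx)
    for ti, t in enumerate(truth_records):
        for ci, c in enumerate(calls):
            if c.cluster.chrom != t.chrom:
                continue
            if not _level_matches(c, t, match_level, synonyms, class_of):
                continue
            d = anchor_distance(c.cluster.start, c.cluster.end, t.anchor_pos)
            if d <= params.annotation_window_bp:
                edges.append((d, ti, ci))
    edges.sort()
    matched_truth: dict[int, int] = {}
    matched_call: set[int] = set()
    for d, ti, ci in edges:
        if ti in matched_truth or ci in matched_call:
            continue
        matched_truth[ti] = ci
        matched_call.add(ci)
    tp = [(truth_records[ti], calls[ci]) for ti, ci in sorted(matched_truth.items())]
    fn = [t for ti, t in enumerate(truth_records) if ti not in matched_truth]
    fp = [c for ci, c in enumerate(calls) if ci not in matched_call]
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int) -> EvalResult:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN); NaN when undefined."""
    return EvalResult(tp=tp, fp=fp, fn=fn)


def evaluate_against_truth(
    calls: Sequence[TECall],
    truth_records: Sequence[TruthRecord],
    params: PipelineParams,
    match_level: str = "subfamily",
    **kwargs,
) -> EvalResult:
    tp, fp, fn = match_calls_to_truth(calls, truth_records, params, match_level, **kwargs)
    return precision_recall(len(tp), len(fp), len(fn))


def _interval_distance(a: Cluster, b: Cluster) -> int:
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end + 1
    return a.start - b.end + 1


def build_parental_truth(
    parent1_clusters: Sequence[Cluster],
    parent2_clusters: Sequence[Cluster],
    params: PipelineParams,
) -> list[TruthRecord]:
    """Insertions detected in both parents: greedy one-to-one pairing of
    same-subfamily clusters within ``parental_window_bp`` (edge distance),
    one record per pair anchored at the midpoint of the combined span."""
    edges: list[tuple[int, int, int]] = []
    for i, a in enumerate(parent1_clusters):
        for j, b in enumerate(parent2_clusters):
            if a.chrom != b.chrom or a.subfamily_name != b.subfamily_name:
                continue
            d = _interval_distance(a, b)
            if d <= params.parental_window_bp:
                edges.append((d, i, j))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    records: list[TruthRecord] = []
    for d, i, j in edges:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = parent1_clusters[i], parent2_clusters[j]
        mid = (min(a.start, b.start) + max(a.end, b.end)) // 2
        records.append(
            TruthRecord(
                chrom=a.chrom,
                anchor_pos=mid,
                subfamily=a.subfamily_name,
                te_class=DEFAULT_SUBFAMILY_CLASS.get(a.subfamily_name),
                source=PARENTAL_TRUTH,
                record_id=f"parental_{a.chrom}_{mid}_{a.subfamily_name.replace('/', '')}",
            )
        )
    records.sort(key=lambda r: (r.chrom, r.anchor_pos))
    return records


def classify_proband_novel(
    proband_novel_calls: Sequence[TECall],
    parent1_raw_clusters: Sequence[Cluster],
    parent2_raw_clusters: Sequence[Cluster],
    params: PipelineParams,
) -> tuple[list[TECall], list[TECall]]:
    """Split a proband's novel calls into inherited vs de novo.

    Parent clusters must be supplied at the relaxed single-read threshold
    (no minimum read count): a novel call is *inherited* when either
    parent shows at least one filtered read-1 within
    ``parental_window_bp``; otherwise it is *de novo* and counts as a
    false positive for precision.
    """
    inherited: list[TECall] = []
    de_novo: list[TECall] = []
    parents = list(parent1_raw_clusters) + list(parent2_raw_clusters)
    for call in proband_novel_calls:
        c = call.cluster
        supported = any(
            p.chrom == c.chrom
            and p.subfamily_name == c.subfamily_name
            and p.read1_total >= 1
            and _interval_distance(c, p) <= params.parental_window_bp
            for p in parents
        )
        (inherited if supported else de_novo).append(call)
    return inherited, de_novo


def evaluate_trio(
    proband_calls: Sequence[TECall],
    parent1_clusters: Sequence[Cluster],
    parent2_clusters: Sequence[Cluster],
    params: PipelineParams,
) -> TrioResult:
    """Full trio evaluation: recall against the parental truth set and
    de novo (false-positive) classification of the proband's novel calls."""
    truth = build_parental_truth(parent1_clusters, parent2_clusters, params)
    tp, unmatched_calls, fn = match_calls_to_truth(
        proband_calls, truth, params, match_level="subfamily"
    )
    novel_unmatched = [c for c in unmatched_calls if c.status == "novel"]
    inherited, de_novo = classify_proband_novel(
        novel_unmatched, parent1_clusters, parent2_clusters, params
    )
    per_subfamily: dict[str, EvalResult] = {}
    for sub in sorted({t.subfamily for t in truth if t.subfamily}):
        s_tp = sum(1 for t, _ in tp if t.subfamily == sub)
        s_fn = sum(1 for t in fn if t.subfamily == sub)
        s_fp = sum(1 for c in de_novo if c.cluster.subfamily_name == sub)
        per_subfamily[sub] = EvalResult(tp=s_tp, fp=s_fp, fn=s_fn)
    return TrioResult(
        parental_truth_size=len(truth),
        observed_in_proband=len(tp),
        proband_novel_inherited=len(inherited),
        proband_de_novo=len(de_novo),
        per_subfamily=per_subfamily,
    )


@dataclass(frozen=True)
class LongRead:
    """A long-read alignment footprint plus its full read sequence."""

    chrom: str
    start: int
    end: int
    sequence: str


def validate_with_long_reads(
    call: TECall,
    long_read_alignments: Iterable[LongRead],
    profile: SubfamilyProfile,
) -> int:
    """Count long reads whose alignment footprint fully spans the call's
    cluster interval and whose sequence contains the profile's TE-like
    string exactly, in either orientation. The call is validated iff the
    count is >= 1."""
    c = call.cluster
    te = profile.te_like.upper()
    te_rc = revcomp(te)
    n = 0
    for read in long_read_alignments:
        if read.chrom != c.chrom or read.start > c.start or read.end < c.end:
            continue
        seq = read.sequence.upper()
        if te in seq or te_rc in seq:
            n += 1
    return n


def summarize_support(calls: Sequence[TECall]) -> pd.DataFrame:
    """Per-subfamily support totals: calls, reads spanning calls, poly-A
    corroborated reads, and the poly-A ratio. Empty input yields an empty
    table with the same columns."""
    cols = ["subfamily", "n_calls", "reads_total", "polya_reads", "polya_ratio"]
    rows = []
    by_sub: dict[str, list[TECall]] = {}
    for call in calls:
        by_sub.setdefault(call.cluster.subfamily_name, []).append(call)
    for sub in sorted(by_sub):
        group = by_sub[sub]
        reads = sum(c.cluster.read1_total for c in group)
        polya = sum(c.cluster.polya_count for c in group)
        rows.append({
            "subfamily": sub,
            "n_calls": len(group),
            "reads_total": reads,
            "polya_reads": polya,
            "polya_ratio": polya / reads if reads else float("nan"),
        })
    return pd.DataFrame(rows, columns=cols)


def mismatch_density(
    read2_sequences: Sequence[str], profile: SubfamilyProfile
) -> np.ndarray:
    """Per-position mismatch density over the TE-like region for a group
    of full-primer read-2 sequences (descriptive profile used to contrast
    reads over true-positive vs false-positive loci)."""
    L = len(profile.te_like)
    mism = np.zeros(L)
    cover = np.zeros(L)
    p0 = len(profile.nested_primer)
    for seq in read2_sequences:
        region = seq.upper()[p0: p0 + L]
        for i, base in enumerate(region):
            cover[i] += 1
            if base != profile.te_like[i]:
                mism[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cover > 0, mism / np.maximum(cover, 1), np.nan)


def read_depth_sweep(
    clusters: Sequence[Cluster],
    truth_records: Sequence[TruthRecord],
    params: PipelineParams,
    thresholds: Iterable[int] = range(1, 11),
    match_level: str = "subfamily",
) -> pd.DataFrame:
    """Precision/recall as a function of the minimum read-1 count per
    cluster, on pre-threshold clusters against a truth set.

    Every retained cluster is treated as a call (status-agnostic), so the
    sweep isolates the read-depth threshold.
    """
    rows = []
    for t in thresholds:
        p = dataclasses.replace(params, min_read1_per_cluster=int(t))
        retained = apply_cluster_thresholds(clusters, p)
        calls = [TECall(c, "novel", None, None) for c in retained]
        tp, fp, fn = match_calls_to_truth(calls, truth_records, p, match_level)
        res = precision_recall(len(tp), len(fp), len(fn))
        rows.append({
            "min_read1_per_cluster": int(t),
            "tp": res.tp, "fp": res.fp, "fn": res.fn,
            "precision": res.precision, "recall": res.recall,
        })
    return pd.DataFrame(rows)


__all__ = [
    "MEI_TRUTH",
    "PARENTAL_TRUTH",
    "REFERENCE_TRUTH",
    "LongRead",
    "TrioResult",
    "TruthRecord",
    "build_parental_truth",
    "classify_proband_novel",
    "evaluate_against_truth",
    "evaluate_trio",
    "match_calls_to_truth",
    "mismatch_density",
    "precision_recall",
    "read_depth_sweep",
    "summarize_support",
    "validate_with_long_reads",
]
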
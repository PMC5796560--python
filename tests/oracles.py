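"""Independent brute-force oracles and tiny record builders shared by the
test suite. Each oracle is written from the operation's definition, not
from the implementation it checks."""

import random

from tescan.annotate import TECall
from tescan.core import AlignedPair, Read1, Read2, revcomp
from tescan.evaluate import TruthRecord
from tescan.filtering import FilterReason, FilterResult, PrimerClass


def brute_force_scan(seq, primer, cap):
    """All-positions Hamming scan on both strands with the
    exact-3'-ultimate-base rule and N exclusion."""
    seq = seq.upper()
    hits = []
    for pattern, strand, ult_idx in (
        (primer, "+", len(primer) - 1),
        (revcomp(primer), "-", 0),
    ):
        for pos in range(len(seq) - len(primer) + 1):
            window = seq[pos: pos + len(primer)]
            if any(c not in "ACGT" for c in window):
                continue
            if window[ult_idx] != pattern[ult_idx]:
                continue
            mm = sum(1 for a, b in zip(window, pattern) if a != b)
            if mm <= cap:
                hits.append((pos, strand, mm))
    return sorted(hits)


def brute_force_clusters(starts, gap):
    """Transitive closure of the pairwise linkage |s_i - s_j| <= gap via
    union-find over all pairs."""
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) <= gap:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(starts[i])
    return sorted(sorted(g) for g in groups.values())


def oracle_match(calls, truths, window):
    """Exhaustive greedy nearest matching: build the full distance matrix
    and repeatedly extract the global minimum."""

    def dist(c, t):
        s, e = c.cluster.start, c.cluster.end
        if s <= t.anchor_pos < e:
            return 0
        return s - t.anchor_pos if t.anchor_pos < s else t.anchor_pos - e + 1

    entries = []
    for ti, t in enumerate(truths):
        for ci, c in enumerate(calls):
            d = dist(c, t)
            if d <= window and t.subfamily == c.cluster.subfamily_name:
                entries.append((d, ti, ci))
    used_t, used_c, n_tp = set(), set(), 0
    while entries:
        entries.sort()
        d, ti, ci = entries.pop(0)
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        n_tp += 1
    return n_tp, len(calls) - n_tp, len(truths) - n_tp


def kept_read(start, mapq=60, chrom="chr1", read_len=151, polya=True,
              read2_mapped=False, pair_id=None):
    """A (pair, FilterResult) tuple as the filter stage would emit it."""
    pair = AlignedPair(
        sample_id="s1",
        subfamily_name="L1HS",
        read1=Read1(chrom, start, start + read_len, "-", mapq, True),
        read2=Read2("A" * read_len, is_mapped=read2_mapped),
        pair_id=pair_id or f"r{chrom}_{start}_{mapq}",
    )
    res = FilterResult(True, FilterReason.OK, PrimerClass.FULL, 0, 8, polya)
    return pair, res


def make_truth(anchor, subfamily="L1HS", chrom="chr1", te_class="LINE1", rid=""):
    return TruthRecord(chrom, anchor, subfamily, te_class, "reference_truth",
                       rid or f"t{anchor}")


def make_call(cluster_factory, start, subfamily="L1HS", status="novel", **kw):
    return TECall(
        cluster_factory(start=start, end=start + 160, subfamily=subfamily, **kw),
        status, None, None,
    )
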
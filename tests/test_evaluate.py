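import math
import random

import pytest

from tescan.annotate import TECall
from tescan.core import PipelineParams, revcomp
from tescan.evaluate import (
    LongRead,
    TruthRecord,
    build_parental_truth,
    classify_proband_novel,
    evaluate_trio,
    match_calls_to_truth,
    mismatch_density,
    precision_recall,
    read_depth_sweep,
    summarize_support,
    validate_with_long_reads,
)


from oracles import make_call as call
from oracles import make_truth as truth
from oracles import oracle_match as _oracle_match


class TestPrecisionRecall:
    def test_reference_precision_fraction(self):
        """589 TP against 9 FP gives the 0.985 precision the L1HS
        reference benchmark reports."""
        r = precision_recall(tp=589, fp=9, fn=0)
        assert round(r.precision, 3) == 0.985

    def test_parental_truth_recall_fraction(self):
        """5384 of 5692 parental-truth loci seen in the proband: 95%."""
        r = precision_recall(tp=5384, fp=0, fn=308)
        assert round(r.recall, 2) == 0.95
        assert r.recall == pytest.approx(5384 / 5692)

    def test_undefined_precision(self):
        r = precision_recall(tp=0, fp=0, fn=5)
        assert math.isnan(r.precision) and not r.precision_defined
        assert r.recall == 0.0


class TestMatching:
    def test_single_match(self, cluster_factory, params):
        tp, fp, fn = match_calls_to_truth(
            [call(cluster_factory, 1000)], [truth(900)], params
        )
        assert (len(tp), len(fp), len(fn)) == (1, 0, 0)

    def test_unmatched_truth_is_fn(self, cluster_factory, params):
        tp, fp, fn = match_calls_to_truth(
            [call(cluster_factory, 10_000)], [truth(900)], params
        )
        assert (len(tp), len(fp), len(fn)) == (0, 1, 1)

    def test_subfamily_level_requires_subfamily(self, cluster_factory, params):
        tp, _, fn = match_calls_to_truth(
            [call(cluster_factory, 1000, subfamily="AluYa5/8")], [truth(900, "L1HS")],
            params, "subfamily",
        )
        assert not tp and len(fn) == 1

    def test_class_level_matching(self, cluster_factory, params):
        t = TruthRecord("chr1", 900, None, "Alu", "mei_truth", "m1")
        tp, _, _ = match_calls_to_truth(
            [call(cluster_factory, 1000, subfamily="AluYb8/9")], [t], params, "class"
        )
        assert len(tp) == 1

    def test_one_to_one_matching(self, cluster_factory, params):
        """A single call cannot satisfy two truth records."""
        tp, fp, fn = match_calls_to_truth(
            [call(cluster_factory, 1000)], [truth(900), truth(1100, rid="t2")], params
        )
        assert (len(tp), len(fn)) == (1, 1)

    def test_conservation(self, cluster_factory, params):
        rnd = random.Random(31)
        truths = [truth(rnd.randrange(0, 200_000), rid=f"t{i}") for i in range(40)]
        calls = [call(cluster_factory, rnd.randrange(0, 200_000)) for _ in range(40)]
        tp, fp, fn = match_calls_to_truth(calls, truths, params)
        assert len(tp) + len(fn) == len(truths)
        assert len(tp) + len(fp) == len(calls)

    def test_matches_exhaustive_oracle(self, cluster_factory, params):
        """Greedy one-to-one matching equals an independently coded
        exhaustive nearest-pair matcher on small random instances."""
        for seed in range(25):
            rnd = random.Random(seed)
            truths = [truth(rnd.randrange(0, 30_000), rid=f"t{i}") for i in range(rnd.randint(0, 40))]
            calls = [call(cluster_factory, rnd.randrange(0, 30_000)) for _ in range(rnd.randint(0, 40))]
            tp, fp, fn = match_calls_to_truth(calls, truths, params)
            o_tp, o_fp, o_fn = _oracle_match(calls, truths, params.annotation_window_bp)
            assert (len(tp), len(fp), len(fn)) == (o_tp, o_fp, o_fn)


class TestParentalTruth:
    def test_shared_cluster_included(self, cluster_factory, params):
        a = [cluster_factory(start=1000, end=1200)]
        b = [cluster_factory(start=1010, end=1210)]
        records = build_parental_truth(a, b, params)
        assert len(records) == 1
        assert records[0].anchor_pos == (1000 + 1210) // 2

    def test_single_parent_cluster_excluded(self, cluster_factory, params):
        assert build_parental_truth([cluster_factory()], [], params) == []

    def test_clusters_150bp_apart_excluded(self, cluster_factory, params):
        a = [cluster_factory(start=1000, end=1200)]
        b = [cluster_factory(start=1350, end=1550)]  # 150 bp edge gap
        assert build_parental_truth(a, b, params) == []

    def test_different_subfamilies_not_paired(self, cluster_factory, params):
        a = [cluster_factory(start=1000, end=1200, subfamily="L1HS")]
        b = [cluster_factory(start=1000, end=1200, subfamily="AluYa5/8")]
        assert build_parental_truth(a, b, params) == []


class TestProbandNovel:
    def test_single_parent_read_means_inherited(self, cluster_factory, params):
        novel = [call(cluster_factory, 1000)]
        father = [cluster_factory(start=1020, end=1171, hq=0, total=1)]
        inherited, de_novo = classify_proband_novel(novel, father, [], params)
        assert len(inherited) == 1 and not de_novo

    def test_no_parent_reads_means_de_novo(self, cluster_factory, params):
        novel = [call(cluster_factory, 1000)]
        inherited, de_novo = classify_proband_novel(novel, [], [], params)
        assert not inherited and len(de_novo) == 1

    def test_distant_parent_cluster_does_not_rescue(self, cluster_factory, params):
        novel = [call(cluster_factory, 1000)]
        father = [cluster_factory(start=5000, end=5151, total=1)]
        _, de_novo = classify_proband_novel(novel, father, [], params)
        assert len(de_novo) == 1


class TestTrio:
    def test_full_inheritance_zero_de_novo(self, cluster_factory, params):
        shared = [cluster_factory(start=s, end=s + 160) for s in (1000, 5000, 9000)]
        proband_calls = [call(cluster_factory, s) for s in (1000, 5000, 9000)]
        res = evaluate_trio(proband_calls, shared, list(shared), params)
        assert res.parental_truth_size == 3
        assert res.observed_in_proband == 3
        assert res.proband_de_novo == 0

    def test_extra_proband_call_is_de_novo(self, cluster_factory, params):
        shared = [cluster_factory(start=s, end=s + 160) for s in (1000, 5000)]
        proband_calls = [call(cluster_factory, s) for s in (1000, 5000, 20_000)]
        res = evaluate_trio(proband_calls, shared, list(shared), params)
        assert res.proband_de_novo == 1
        assert res.per_subfamily["L1HS"].tp == 2


class TestLongReadValidation:
    def test_spanning_read_with_te_like(self, cluster_factory, profiles):
        c = call(cluster_factory, 1000)
        read = LongRead("chr1", 500, 2000, "G" * 100 + profiles["L1HS"].te_like + "G" * 100)
        assert validate_with_long_reads(c, [read], profiles["L1HS"]) == 1

    def test_spanning_read_without_te_like(self, cluster_factory, profiles):
        c = call(cluster_factory, 1000)
        read = LongRead("chr1", 500, 2000, "G" * 300)
        assert validate_with_long_reads(c, [read], profiles["L1HS"]) == 0

    def test_non_spanning_read_ignored(self, cluster_factory, profiles):
        c = call(cluster_factory, 1000)
        read = LongRead("chr1", 1050, 2000, "G" * 50 + profiles["L1HS"].te_like)
        assert validate_with_long_reads(c, [read], profiles["L1HS"]) == 0

    def test_reverse_complement_invariance(self, cluster_factory, profiles):
        c = call(cluster_factory, 1000)
        seq = "G" * 100 + profiles["L1HS"].te_like + "C" * 100
        fwd = LongRead("chr1", 500, 2000, seq)
        rev = LongRead("chr1", 500, 2000, revcomp(seq))
        p = profiles["L1HS"]
        assert validate_with_long_reads(c, [fwd], p) == validate_with_long_reads(c, [rev], p) == 1


class TestSupportSummary:
    def test_polya_ratio(self, cluster_factory):
        calls = [TECall(cluster_factory(total=948_311, polya=943_744), "reference", "r", 0)]
        table = summarize_support(calls)
        assert table.loc[0, "polya_ratio"] == pytest.approx(943_744 / 948_311)
        assert round(table.loc[0, "polya_ratio"], 3) == 0.995

    def test_empty(self):
        table = summarize_support([])
        assert table.empty and list(table.columns) == [
            "subfamily", "n_calls", "reads_total", "polya_reads", "polya_ratio"
        ]

    def test_all_polya(self, cluster_factory):
        calls = [TECall(cluster_factory(total=10, polya=10), "novel", None, None)]
        assert summarize_support(calls).loc[0, "polya_ratio"] == 1.0


class TestMismatchDensity:
    def test_density_profile(self, profiles):
        p = profiles["L1HS"]
        clean = p.nested_primer + p.te_like
        mutated = list(p.te_like)
        mutated[2] = "C" if mutated[2] != "C" else "G"
        reads = [clean, p.nested_primer + "".join(mutated)]
        dens = mismatch_density(reads, p)
        assert dens[2] == 0.5 and dens[0] == 0.0


class TestReadDepthSweep:
    def test_monotone_on_synthetic_clusters(self, cluster_factory, params):
        rnd = random.Random(41)
        truths, clusters = [], []
        for i in range(30):
            pos = 2000 * (i + 1)
            truths.append(truth(pos, rid=f"t{i}"))
            clusters.append(cluster_factory(start=pos + 20, end=pos + 220,
                                            hq=rnd.randint(1, 10), total=10))
        for i in range(10):  # noise clusters far from truth, low depth
            clusters.append(cluster_factory(start=70_000 + 2000 * i, end=70_200 + 2000 * i,
                                            hq=rnd.randint(1, 3), total=3))
        table = read_depth_sweep(clusters, truths, params, range(1, 11))
        rec = table["recall"].tolist()
        assert all(a >= b - 1e-12 for a, b in zip(rec, rec[1:]))
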
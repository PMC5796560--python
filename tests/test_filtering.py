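import dataclasses

import pytest

from tescan.core import AlignedPair, InputError, PipelineParams, Read1, Read2
from tescan.filtering import (
    FilterReason,
    PrimerClass,
    apply_filters,
    classify_primer_match,
    detect_polya,
    filter_pair,
    filter_summary,
    te_like_mismatches,
)


@pytest.fixture()
def l1(profiles):
    return profiles["L1HS"]


@pytest.fixture()
def ya(profiles):
    return profiles["AluYa5/8"]


def make_pair(read2_seq, mapq=20, mapped=True, dup=False, read2_mapped=False,
              subfamily="L1HS"):
    read1 = (
        Read1("chr1", 1000, 1151, "+", mapq, True)
        if mapped
        else Read1(None, None, None, "+", 0, False)
    )
    return AlignedPair(
        sample_id="s1",
        subfamily_name=subfamily,
        read1=read1,
        read2=Read2(read2_seq, is_mapped=read2_mapped),
        is_duplicate=dup,
        pair_id="p1",
    )


def on_target_read2(profile, mismatch_positions=(), tail="A" * 40, read_len=151):
    te = list(profile.te_like)
    for i in mismatch_positions:
        te[i] = "C" if te[i] != "C" else "G"
    seq = profile.nested_primer + "".join(te) + tail
    return (seq + "G" * read_len)[:read_len]


class TestClassifyPrimerMatch:
    def test_full(self, l1, params):
        assert classify_primer_match(l1.nested_primer + "AAAA", l1.nested_primer, params) is PrimerClass.FULL

    def test_partial_seven_of_ten(self, l1, params):
        prefix = list(l1.nested_primer[:10])
        for i in (2, 5, 8):
            prefix[i] = "C" if prefix[i] != "C" else "G"
        read = "".join(prefix) + "T" * 60
        assert classify_primer_match(read, l1.nested_primer, params) is PrimerClass.PARTIAL

    def test_none_five_of_ten(self, l1, params):
        prefix = list(l1.nested_primer[:10])
        for i in (0, 2, 4, 6, 8):
            prefix[i] = "C" if prefix[i] != "C" else "G"
        read = "".join(prefix) + "T" * 60
        assert classify_primer_match(read, l1.nested_primer, params) is PrimerClass.NONE

    def test_read_shorter_than_primer_not_full(self, l1, params):
        assert classify_primer_match(l1.nested_primer[:8], l1.nested_primer, params) is not PrimerClass.FULL

    def test_empty_read_rejected(self, l1, params):
        with pytest.raises(InputError):
            classify_primer_match("", l1.nested_primer, params)

    def test_lowering_partial_threshold_is_monotone(self, l1):
        """Lowering primer_partial_min_matches never decreases the set of
        PARTIAL+FULL classifications."""
        import random

        rnd = random.Random(5)
        reads = ["".join(rnd.choice("ACGT") for _ in range(40)) for _ in range(300)]
        reads += [l1.nested_primer[:10] + "T" * 30, l1.nested_primer + "T" * 20]
        counts = []
        for thr in range(10, -1, -1):
            p = PipelineParams(primer_partial_min_matches=thr)
            n = sum(
                classify_primer_match(r, l1.nested_primer, p) is not PrimerClass.NONE
                for r in reads
            )
            counts.append(n)
        assert counts == sorted(counts)


class TestTeLikeMismatches:
    def test_exact(self, ya):
        mm, cov = te_like_mismatches(on_target_read2(ya), ya)
        assert (mm, cov) == (0, len(ya.te_like))

    def test_one_substitution(self, ya):
        mm, cov = te_like_mismatches(on_target_read2(ya, mismatch_positions=(3,)), ya)
        assert (mm, cov) == (1, len(ya.te_like))

    def test_cap_exceeded_drops_pair(self, ya, params):
        read = on_target_read2(ya, mismatch_positions=tuple(range(11)))
        res = filter_pair(make_pair(read, subfamily="AluYa5/8"), ya, params)
        assert not res.keep and res.reason is FilterReason.TE_LIKE_EXCEEDED
        assert res.te_like_mismatches == 11

    def test_truncated_coverage(self, ya):
        read = ya.nested_primer + ya.te_like[:12]
        mm, cov = te_like_mismatches(read, ya)
        assert (mm, cov) == (0, 12)

    def test_zero_coverage(self, ya):
        mm, cov = te_like_mismatches(ya.nested_primer, ya)
        assert mm is None and cov == 0


class TestDetectPolya:
    def test_pure_run(self, l1, params):
        assert detect_polya(l1.nested_primer + l1.te_like + "A" * 20, l1, params)

    def test_run_below_minimum(self, l1, params):
        assert not detect_polya(l1.nested_primer + l1.te_like + "A" * 7, l1, params)

    def test_read_ending_inside_te_like(self, l1, params):
        assert not detect_polya(l1.nested_primer + l1.te_like[:4], l1, params)

    def test_one_non_a_tolerated(self, l1, params):
        assert detect_polya(l1.nested_primer + l1.te_like + "AAAGAAAA", l1, params)

    def test_two_non_a_in_every_window_rejected(self, l1, params):
        tail = "AAGAAGAAGAAG"  # every 8-mer window holds >= 2 non-A
        assert not detect_polya(l1.nested_primer + l1.te_like + tail, l1, params)


class TestFilterPair:
    def test_clean_pair_kept(self, l1, params):
        res = filter_pair(make_pair(on_target_read2(l1)), l1, params)
        assert res.keep and res.reason is FilterReason.OK
        assert res.primer_class is PrimerClass.FULL and res.polya_detected

    def test_mapq_zero_dropped(self, l1, params):
        res = filter_pair(make_pair(on_target_read2(l1), mapq=0), l1, params)
        assert not res.keep and res.reason is FilterReason.MAPQ_ZERO

    def test_read2_unmapped_is_fine(self, l1, params):
        res = filter_pair(
            make_pair(on_target_read2(l1), mapq=10, read2_mapped=False), l1, params
        )
        assert res.keep

    def test_read1_unmapped_dropped(self, l1, params):
        res = filter_pair(make_pair(on_target_read2(l1), mapped=False), l1, params)
        assert not res.keep and res.reason is FilterReason.READ1_UNMAPPED

    def test_duplicate_takes_precedence(self, l1, params):
        res = filter_pair(make_pair(on_target_read2(l1), dup=True), l1, params)
        assert not res.keep and res.reason is FilterReason.DUPLICATE

    def test_background_read_no_primer(self, l1, params):
        res = filter_pair(make_pair("T" * 151), l1, params)
        assert not res.keep and res.reason is FilterReason.NO_PRIMER

    def test_primer_only_read_uncovered(self, l1, params):
        res = filter_pair(make_pair(l1.nested_primer), l1, params)
        assert not res.keep and res.reason is FilterReason.TE_LIKE_UNCOVERED

    def test_missing_read2_sequence_rejected(self, l1, params):
        pair = make_pair("A")
        pair = dataclasses.replace(pair, read2=Read2("", is_mapped=False))
        with pytest.raises(InputError):
            filter_pair(pair, l1, params)

    def test_pure_function(self, l1, params):
        pair = make_pair(on_target_read2(l1))
        assert filter_pair(pair, l1, params) == filter_pair(pair, l1, params)

    def test_raising_mismatch_cap_is_monotone(self, l1, params):
        """Raising max_te_like_mismatches never shrinks the kept set."""
        reads = [on_target_read2(l1, mismatch_positions=tuple(range(k))) for k in range(9)]
        pairs = [make_pair(r) for r in reads]
        kept_sets = []
        for cap in range(0, 9):
            prof = dataclasses.replace(l1, max_te_like_mismatches=cap)
            kept_sets.append({i for i, p in enumerate(pairs) if filter_pair(p, prof, params).keep})
        for a, b in zip(kept_sets, kept_sets[1:]):
            assert a <= b


class TestLibraryFiltering:
    def test_conservation(self, l1, params):
        pairs = (
            [make_pair(on_target_read2(l1)) for _ in range(5)]
            + [make_pair("T" * 151) for _ in range(3)]
            + [make_pair(on_target_read2(l1), mapq=0)]
            + [make_pair(on_target_read2(l1), dup=True)]
        )
        kept, tally = apply_filters(pairs, l1, params)
        assert sum(tally.values()) == len(pairs)
        assert len(kept) == tally[FilterReason.OK] == 5

    def test_background_fraction_recovered(self, profiles, params, sim_default):
        """With error rate 0 and background fraction b, the NO_PRIMER drop
        fraction converges to b (binomial tolerance)."""
        config, _, _, _, sim_pairs = sim_default
        b = config.background_fraction
        n_no_primer = 0
        n_total = 0
        for sub, profile in profiles.items():
            lib = [sp.pair for sp in sim_pairs if sp.pair.subfamily_name == sub]
            _, tally = apply_filters(lib, profile, params)
            n_no_primer += tally[FilterReason.NO_PRIMER] + tally[FilterReason.PARTIAL_PRIMER]
            n_total += sum(tally.values())
        frac = n_no_primer / n_total
        # 4 sigma binomial band around b
        sigma = (b * (1 - b) / n_total) ** 0.5
        assert abs(frac - b) < 4 * sigma + 0.01

    def test_summary_fractions(self, l1, params):
        pairs = [make_pair(on_target_read2(l1)) for _ in range(8)] + [
            make_pair("T" * 151) for _ in range(2)
        ]
        _, tally = apply_filters(pairs, l1, params)
        summary = filter_summary(tally)
        assert summary["discernible_primer_fraction"] == pytest.approx(0.8)
        assert summary["total"] == 10
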
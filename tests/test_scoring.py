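"""Replicate-group consensus scoring: scales, composition, invariants."""

import numpy as np
import pytest

from cnvconsensus import (
    CallSet,
    CNVCall,
    CNVType,
    Cohort,
    GenomicInterval,
    assign_confidence_gain_loss,
    assign_confidence_loh,
    build_support_matrix,
    caller_cumulative_score,
    convert_cumulative,
    normalize,
    score_cohort,
)
from cnvconsensus.intervals import ExclusionMask
from cnvconsensus.scoring import Confidence, GroupingScheme

from conftest import base_mask


def make_callset(caller, center, replicate, gains=(), cn=3.0):
    calls = [CNVCall(GenomicInterval(c, s, e), cn) for c, s, e in gains]
    return CallSet(caller, center, replicate, "WGS", calls)


class TestGroupingScheme:
    def test_default_layout(self):
        scheme = GroupingScheme.default()
        assert len(scheme.replicates) == 21
        assert scheme.max_cumulative == 15
        assert scheme.divisor_of["G4"] == 3

    def test_frame_round_trip(self):
        scheme = GroupingScheme.default()
        back = GroupingScheme.from_frame(scheme.to_frame())
        assert back.group_of == scheme.group_of
        assert back.divisor_of == scheme.divisor_of

    def test_divisor_below_one_rejected(self):
        with pytest.raises(ValueError):
            GroupingScheme({("a", "1"): "g"}, {"g": 0.5})


class TestCumulativeScore:
    def test_two_of_three_in_center_group(self):
        scheme = GroupingScheme.default()
        support = {rep: False for rep in scheme.replicates}
        support[("FD", "1")] = support[("FD", "2")] = True
        assert caller_cumulative_score(support, scheme) == 2

    def test_full_support_is_fifteen(self):
        scheme = GroupingScheme.default()
        support = {rep: True for rep in scheme.replicates}
        # 3 + 3 + 3 + 9/3 + 3
        assert caller_cumulative_score(support, scheme) == 15

    def test_nine_replicate_group_normalized(self):
        scheme = GroupingScheme.default()
        support = {rep: rep[0] == "NS" for rep in scheme.replicates}
        assert caller_cumulative_score(support, scheme) == 3

    def test_no_support_zero(self):
        scheme = GroupingScheme.default()
        assert caller_cumulative_score({r: False for r in scheme.replicates}, scheme) == 0

    def test_unknown_replicate_named(self):
        with pytest.raises(ValueError, match="ZZ"):
            caller_cumulative_score({("ZZ", "9"): True}, GroupingScheme.default())


class TestConversionScales:
    @pytest.mark.parametrize(
        "cumulative,expected",
        [(0, 0), (1, 0), (3, 0), (4, 1), (6, 1), (7, 2), (9, 2), (10, 3), (12, 3), (15, 3)],
    )
    def test_convert_cumulative_table(self, cumulative, expected):
        assert convert_cumulative(cumulative) == expected

    @pytest.mark.parametrize(
        "cumulative,expected",
        [(3 + 1 / 3, 1), (6 + 1 / 3, 2), (9 + 1 / 3, 3), (2 + 2 / 3, 0)],
    )
    def test_convert_fractional_scores(self, cumulative, expected):
        assert convert_cumulative(cumulative) == expected

    def test_convert_out_of_range(self):
        with pytest.raises(ValueError):
            convert_cumulative(16)
        with pytest.raises(ValueError):
            convert_cumulative(-1)

    @pytest.mark.parametrize(
        "total,expected",
        [
            (0, Confidence.NONE), (1, Confidence.NEUTRAL), (3, Confidence.NEUTRAL),
            (4, Confidence.WEAK), (7, Confidence.WEAK), (8, Confidence.MEDIUM),
            (10, Confidence.MEDIUM), (11, Confidence.STRONG), (18, Confidence.STRONG),
        ],
    )
    def test_gain_loss_scale(self, total, expected):
        assert assign_confidence_gain_loss(total) == expected

    @pytest.mark.parametrize(
        "total,expected",
        [
            (0, Confidence.NONE), (1, Confidence.NEUTRAL), (3, Confidence.NEUTRAL),
            (4, Confidence.WEAK), (5, Confidence.WEAK), (6, Confidence.MEDIUM),
            (7, Confidence.MEDIUM), (8, Confidence.MEDIUM), (9, Confidence.STRONG),
            (15, Confidence.STRONG),
        ],
    )
    def test_loh_scale(self, total, expected):
        assert assign_confidence_loh(total) == expected

    def test_scale_range_errors(self):
        with pytest.raises(ValueError):
            assign_confidence_gain_loss(19)
        with pytest.raises(ValueError):
            assign_confidence_loh(16)

    def test_monotone_in_total(self):
        gl = [assign_confidence_gain_loss(t).rank for t in range(19)]
        loh = [assign_confidence_loh(t).rank for t in range(16)]
        assert gl == sorted(gl) and loh == sorted(loh)


def small_scheme():
    """2 centers x 2 replicates, divisors 1."""
    group_of = {(c, str(r)): c for c in ("A", "B") for r in (1, 2)}
    return GroupingScheme(group_of, {"A": 1.0, "B": 1.0})


class TestBuildSupportMatrix:
    def test_identical_segments(self):
        scheme = GroupingScheme.default()
        cohort = Cohort(
            [
                make_callset("x", "FD", "1", [("chr1", 0, 100)]),
                make_callset("y", "FD", "1", [("chr1", 0, 100)]),
            ],
            grouping=scheme,
        )
        keys, matrix = build_support_matrix(cohort, CNVType.GAIN)
        assert matrix == [(GenomicInterval("chr1", 0, 100), (True, True))]

    def test_half_overlap_three_pieces(self):
        cohort = Cohort(
            [
                make_callset("x", "FD", "1", [("chr1", 0, 100)]),
                make_callset("y", "FD", "1", [("chr1", 50, 150)]),
            ],
            grouping=GroupingScheme.default(),
        )
        _, matrix = build_support_matrix(cohort, CNVType.GAIN)
        assert [(m.start, m.end) for m, _ in matrix] == [(0, 50), (50, 100), (100, 150)]

    def test_absent_type_empty(self):
        cohort = Cohort(
            [make_callset("x", "FD", "1", [("chr1", 0, 100)])],
            grouping=GroupingScheme.default(),
        )
        _, matrix = build_support_matrix(cohort, CNVType.LOSS)
        assert matrix == []


def full_agreement_cohort(n_callers=6, segment=("chr1", 0, 1_000_000), cn=3.0):
    scheme = GroupingScheme.default()
    callsets = [
        make_callset(f"c{i}", center, rep, [segment], cn)
        for i in range(n_callers)
        for center, rep in scheme.replicates
    ]
    return Cohort(callsets, grouping=scheme)


class TestScoreCohort:
    def test_unanimous_gain_is_strong_18(self):
        scored = score_cohort(full_agreement_cohort(), CNVType.GAIN)
        assert len(scored) == 1
        s = scored[0]
        assert s.total_score == 18
        assert all(v == 15 for v in s.per_caller_cumulative.values())
        assert s.confidence == Confidence.STRONG

    def test_single_replicate_single_caller_is_none(self):
        scheme = GroupingScheme.default()
        cohort = Cohort(
            [make_callset("x", "FD", "1", [("chr1", 0, 100)])], grouping=scheme
        )
        scored = score_cohort(cohort, CNVType.GAIN)
        assert scored[0].per_caller_cumulative == {"x": 1}
        assert scored[0].total_score == 0
        assert scored[0].confidence == Confidence.NONE

    def test_empty_type_empty_output(self):
        assert score_cohort(full_agreement_cohort(), CNVType.LOSS) == []

    def test_loh_drops_non_reporting_caller(self, caplog):
        scheme = GroupingScheme.default()
        callsets = []
        for center, rep in scheme.replicates:
            callsets.append(
                CallSet("loh_caller", center, rep, "WGS",
                        [CNVCall(GenomicInterval("chr1", 0, 1000), 2, minor_cn=0.0)])
            )
            callsets.append(make_callset("gain_only", center, rep, [("chr1", 0, 1000)]))
        cohort = Cohort(callsets, grouping=scheme)
        scored = score_cohort(cohort, CNVType.LOH)
        assert len(scored) == 1
        assert set(scored[0].per_caller_converted) == {"loh_caller"}
        # five-caller-style LOH scale: a single unanimous caller scores 3
        assert scored[0].total_score == 3
        assert scored[0].confidence == Confidence.NEUTRAL

    def test_mask_applied_before_partitioning(self):
        mask = ExclusionMask(normalize([GenomicInterval("chr1", 0, 500_000)]))
        scored = score_cohort(full_agreement_cohort(), CNVType.GAIN, mask)
        assert len(scored) == 1
        assert scored[0].interval == GenomicInterval("chr1", 500_000, 1_000_000)

    def test_permutation_invariance(self):
        cohort = full_agreement_cohort(3)
        rng = np.random.default_rng(0)
        shuffled = list(cohort.callsets)
        rng.shuffle(shuffled)
        a = score_cohort(cohort, CNVType.GAIN)
        b = score_cohort(Cohort(shuffled, grouping=cohort.grouping), CNVType.GAIN)
        assert [(s.interval, s.total_score, s.confidence) for s in a] == [
            (s.interval, s.total_score, s.confidence) for s in b
        ]

    def test_adding_supporting_replicate_is_monotone(self):
        scheme = GroupingScheme.default()
        reps = scheme.replicates
        rng = np.random.default_rng(3)
        for _ in range(20):
            support = {r: bool(rng.random() < 0.4) for r in reps}
            off = [r for r in reps if not support[r]]
            if not off:
                continue
            more = dict(support)
            more[off[int(rng.integers(len(off)))]] = True
            c0 = caller_cumulative_score(support, scheme)
            c1 = caller_cumulative_score(more, scheme)
            assert c1 >= c0
            assert convert_cumulative(c1) >= convert_cumulative(c0)
            assert (
                assign_confidence_gain_loss(6 * convert_cumulative(c1)).rank
                >= assign_confidence_gain_loss(6 * convert_cumulative(c0)).rank
            )

    def test_conservation_of_masked_input_union(self):
        scheme = GroupingScheme.default()
        rng = np.random.default_rng(5)
        callsets = []
        for i, (center, rep) in enumerate(scheme.replicates):
            gains = [
                ("chr1", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 9000, 3), rng.integers(100, 900, 3)
                )
            ]
            callsets.append(make_callset("x", center, rep, gains))
        mask = ExclusionMask(normalize([GenomicInterval("chr1", 2000, 2500)]))
        cohort = Cohort(callsets, grouping=scheme)
        scored = score_cohort(cohort, CNVType.GAIN, mask)
        union_in = normalize([])
        for cs in callsets:
            union_in = union_in.union(cs.typed_regions(CNVType.GAIN))
        union_in = union_in.subtract(mask.regions)
        assert normalize(s.interval for s in scored) == union_in

    def test_matches_per_base_oracle(self):
        """Total scores agree with a brute-force per-base recomputation."""
        scheme = GroupingScheme.default()
        rng = np.random.default_rng(42)
        callers = ["a", "b", "c"]
        cohort_sets = []
        for caller in callers:
            for center, rep in scheme.replicates:
                n = int(rng.integers(0, 4))
                gains = []
                for _ in range(n):
                    s = int(rng.integers(0, 9500))
                    gains.append(("chr1", s, s + int(rng.integers(50, 500))))
                cohort_sets.append(make_callset(caller, center, rep, gains))
        cohort = Cohort(cohort_sets, grouping=scheme)
        scored = score_cohort(cohort, CNVType.GAIN)

        # oracle: per-base coverage flags per call set
        masks = {
            cs.key: base_mask(cs.typed_regions(CNVType.GAIN)) for cs in cohort_sets
        }
        for s in scored:
            for base in range(s.interval.start, s.interval.end, 37):
                total = 0
                for caller in callers:
                    support = {
                        (cs.center, cs.replicate): bool(
                            masks[cs.key]["chr1"][base]
                        )
                        for cs in cohort_sets
                        if cs.caller == caller
                    }
                    total += convert_cumulative(
                        caller_cumulative_score(support, scheme)
                    )
                assert total == s.total_score
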
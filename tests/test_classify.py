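import pytest
from hypothesis import given
from hypothesis import strategies as st

from cushionbench import (
    BModel,
    IntervalEstimate,
    MagnitudeClass,
    OverallLevel,
    RedistributionClass,
    ThresholdConfig,
    assign_level,
    classify_magnitude,
    classify_redistribution,
    flag_borderline,
    suggest_retests,
)
from cushionbench.classify import CushionReport, ModelResult
from cushionbench.stats import RatioEstimate

E, T = BModel.ELLIPTICAL, BModel.TRIGONOMETRIC


def interval(mean, lower, upper):
    return IntervalEstimate(mean=mean, sd=0.0, n=12, lower=lower, upper=upper)


def ratio(mean, lower, upper, unbounded=False):
    return RatioEstimate(ratio=mean, lower=lower, upper=upper,
                         method="fieller", n_test=12, n_ref=12,
                         unbounded=unbounded)


class TestClassifyRedistribution:
    @pytest.mark.parametrize(
        "model, mean, lower, upper, expected",
        [
            (E, 0.46, 0.45, 0.47, RedistributionClass.HIGH),
            (E, 0.50, 0.49, 0.50, RedistributionClass.MODERATE),
            (T, 0.69, 0.68, 0.71, RedistributionClass.LOW),
            # a bound exactly on the criterion is Moderate (strict < and >)
            (E, 0.495, 0.49, 0.50, RedistributionClass.MODERATE),
            (T, 0.555, 0.55, 0.56, RedistributionClass.MODERATE),
        ],
    )
    def test_examples(self, config, model, mean, lower, upper, expected):
        assert classify_redistribution(interval(mean, lower, upper), model, config) == expected


class TestClassifyMagnitude:
    @pytest.mark.parametrize(
        "mean, lower, upper, expected",
        [
            (0.70, 0.66, 0.75, MagnitudeClass.SUPERIOR),
            (0.84, 0.78, 0.91, MagnitudeClass.COMPARABLE),
            (1.20, 1.11, 1.29, MagnitudeClass.INFERIOR),
            # non-strict limits: touching the LEL/UEL still counts
            (0.85, 0.80, 0.90, MagnitudeClass.SUPERIOR),
            (1.15, 1.10, 1.20, MagnitudeClass.INFERIOR),
            (1.0, 0.95, 1.05, MagnitudeClass.COMPARABLE),
        ],
    )
    def test_examples(self, config, mean, lower, upper, expected):
        assert classify_magnitude(ratio(mean, lower, upper), config) == expected

    def test_unbounded_interval_is_comparable_with_warning(self, config):
        warnings = []
        cls = classify_magnitude(
            ratio(0.8, float("-inf"), float("inf"), unbounded=True), config, warnings
        )
        assert cls == MagnitudeClass.COMPARABLE
        assert warnings


interval_strategy = st.tuples(
    st.floats(min_value=0.0, max_value=1.5),
    st.floats(min_value=0.0, max_value=1.5),
).map(lambda ab: interval((ab[0] + ab[1]) / 2, min(ab), max(ab)))


class TestTrichotomyProperties:
    @given(iv=interval_strategy, model=st.sampled_from([E, T]))
    def test_redistribution_exhaustive_and_exclusive(self, iv, model):
        config = ThresholdConfig()
        cls = classify_redistribution(iv, model, config)
        tau = config.redistribution_threshold[model]
        matches = [
            cls == RedistributionClass.HIGH and iv.upper < tau,
            cls == RedistributionClass.LOW and iv.lower > tau,
            cls == RedistributionClass.MODERATE
            and iv.lower <= tau <= iv.upper,
        ]
        assert sum(matches) == 1

    @given(iv=interval_strategy)
    def test_magnitude_exhaustive_and_exclusive(self, iv):
        config = ThresholdConfig()
        r = ratio(iv.mean, iv.lower, iv.upper)
        cls = classify_magnitude(r, config)
        matches = [
            cls == MagnitudeClass.SUPERIOR and r.upper <= config.lel,
            cls == MagnitudeClass.INFERIOR and r.lower >= config.uel,
            cls == MagnitudeClass.COMPARABLE
            and r.upper > config.lel and r.lower < config.uel,
        ]
        assert sum(matches) == 1

    @given(iv=interval_strategy, shift=st.floats(min_value=0.0, max_value=0.5),
           model=st.sampled_from([E, T]))
    def test_upward_translation_never_raises_class(self, iv, shift, model):
        config = ThresholdConfig()
        rank = {RedistributionClass.HIGH: 2, RedistributionClass.MODERATE: 1,
                RedistributionClass.LOW: 0}
        before = classify_redistribution(iv, model, config)
        moved = interval(iv.mean + shift, iv.lower + shift, iv.upper + shift)
        after = classify_redistribution(moved, model, config)
        assert rank[after] <= rank[before]

    @given(iv=interval_strategy, shrink=st.floats(min_value=0.0, max_value=1.0))
    def test_shrinking_cannot_jump_across_comparable(self, iv, shrink):
        config = ThresholdConfig()
        before = classify_magnitude(ratio(iv.mean, iv.lower, iv.upper), config)
        lo = iv.mean + (iv.lower - iv.mean) * (1 - shrink)
        hi = iv.mean + (iv.upper - iv.mean) * (1 - shrink)
        after = classify_magnitude(ratio(iv.mean, lo, hi), config)
        forbidden = {
            (MagnitudeClass.SUPERIOR, MagnitudeClass.INFERIOR),
            (MagnitudeClass.INFERIOR, MagnitudeClass.SUPERIOR),
        }
        assert (before, after) not in forbidden


H, M, L = RedistributionClass.HIGH, RedistributionClass.MODERATE, RedistributionClass.LOW
S, C, I = MagnitudeClass.SUPERIOR, MagnitudeClass.COMPARABLE, MagnitudeClass.INFERIOR


class TestAssignLevel:
    def test_top_level_profile(self):
        # High/High redistribution with Superior/Superior magnitude vs 3"
        level = assign_level({E: H, T: H}, {E: S, T: S})
        assert level == OverallLevel.LEVEL1

    def test_single_model_moderate_reaches_level3(self):
        # Moderate ellip + Low trig fails the both-model tier but passes the
        # elliptical-only tier even with Superior magnitude on both
        level = assign_level({E: M, T: L}, {E: S, T: S})
        assert level == OverallLevel.LEVEL3

    def test_inferior_vs_2in_is_below_minimum(self):
        level = assign_level({E: M, T: L}, None, {E: I, T: I})
        assert level == OverallLevel.BELOW_MINIMUM

    def test_comparable_vs_2in_is_general_use(self):
        level = assign_level({E: L, T: L}, None, {E: C})
        assert level == OverallLevel.GENERAL_USE

    def test_no_inputs_is_indeterminate(self):
        assert assign_level({}, None, None) == OverallLevel.INDETERMINATE

    def test_missing_3in_data_caps_at_general_use(self):
        level = assign_level({E: H, T: H}, None, {E: S, T: S})
        assert level == OverallLevel.GENERAL_USE

    @given(
        re=st.sampled_from([H, M, L]), rt=st.sampled_from([H, M, L]),
        me=st.sampled_from([S, C, I]), mt=st.sampled_from([S, C, I]),
    )
    def test_matrix_nesting(self, re, rt, me, mt):
        """Any profile awarded Level1 also satisfies the Level2 and Level3
        conditions; Level2 implies Level3."""
        level = assign_level({E: re, T: rt}, {E: me, T: mt})
        redis_rank = {L: 0, M: 1, H: 2}
        mag_rank = {I: 0, C: 1, S: 2}
        l2_holds = (redis_rank[re] >= 1 and redis_rank[rt] >= 1
                    and mag_rank[me] >= 1 and mag_rank[mt] >= 1)
        l3_holds = redis_rank[re] >= 1 and mag_rank[me] >= 1
        if level == OverallLevel.LEVEL1:
            assert l2_holds and l3_holds
        if level == OverallLevel.LEVEL2:
            assert l3_holds


class TestFlagBorderline:
    def test_minimally_crossed_lel_flagged(self, config):
        flags = flag_borderline(ratio(0.84, 0.78, 0.91), [config.lel, config.uel],
                                config, parameter="magnitude")
        assert len(flags) == 1
        assert flags[0].threshold == 0.9
        assert flags[0].distance == pytest.approx(0.01)

    def test_far_zero_width_interval_not_flagged(self, config):
        assert flag_borderline(interval(0.7, 0.7, 0.7), [0.5], config) == []

    def test_boundary_touch_flagged_at_zero_distance(self, config):
        flags = flag_borderline(interval(0.495, 0.49, 0.50), [0.50], config)
        assert len(flags) == 1
        assert flags[0].distance == pytest.approx(0.0)

    def test_unbounded_interval_not_flagged(self, config):
        r = ratio(0.9, float("-inf"), float("inf"), unbounded=True)
        assert flag_borderline(r, [config.lel], config) == []


class TestSuggestRetests:
    def _report(self, **kwargs):
        report = CushionReport(cushion_id="x")
        for key, value in kwargs.items():
            setattr(report, key, value)
        return report

    def test_superior_vs_2in_without_3in_triggers_comparison(self):
        res = ModelResult(magnitude_2in=ratio(0.74, 0.70, 0.78),
                          magnitude_2in_class=S)
        report = self._report(per_model={T: res})
        assert suggest_retests(report) == ["compare_vs_3in"]

    def test_borderline_triggers_add_trials(self, config):
        res = ModelResult()
        report = self._report(per_model={E: res})
        report.borderline_flags = flag_borderline(
            ratio(0.84, 0.78, 0.91), [config.lel], config, parameter="magnitude"
        )
        assert suggest_retests(report) == ["add_trials"]

    def test_clean_full_report_suggests_nothing(self):
        res = ModelResult(magnitude_3in=ratio(0.8, 0.75, 0.85),
                          magnitude_3in_class=S)
        report = self._report(per_model={E: res})
        assert suggest_retests(report) == []
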
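import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cushionbench import (
    BModel,
    LiteratureIPMRecord,
    ThresholdConfig,
    bony_fraction,
    coefficient_of_variation,
    derive_equivalence_limit,
    pooled_interval,
    ratio_interval,
    sum_internal,
)
from cushionbench.stats import Parameter, ParameterSamples, collect_parameters

from conftest import build_trial


class TestBonyFraction:
    def test_uniform_surface_gives_half(self):
        assert bony_fraction(build_trial(surface_value=10)) == pytest.approx(0.5)

    def test_hand_summed_example(self, layout):
        overrides = {c: 10 for c in layout.bony_ids}
        overrides.update({c: 5 for c in layout.nonbony_ids})
        trial = build_trial(surface_overrides=overrides)
        assert bony_fraction(trial) == pytest.approx(60 / 90)

    def test_all_load_on_bony_gives_one(self, layout):
        overrides = {c: 0 for c in layout.nonbony_ids}
        trial = build_trial(surface_overrides=overrides)
        assert bony_fraction(trial) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroDivisionError):
            bony_fraction(build_trial(surface_value=0))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 100.0, size=12)
        base = build_trial(surface_overrides={c: values[c - 1] for c in range(1, 13)})
        scaled = build_trial(
            surface_overrides={c: values[c - 1] * scale for c in range(1, 13)}
        )
        assert bony_fraction(scaled) == pytest.approx(bony_fraction(base), rel=1e-9)


class TestSumInternal:
    def test_plain_sum(self):
        trial = build_trial()
        trial.internal = {"I1": 100.0, "I2": 80.0, "I3": 20.0}
        assert sum_internal(trial) == 200.0

    def test_zero(self):
        trial = build_trial(internal_value=0)
        assert sum_internal(trial) == 0.0

    def test_missing_channel_rejected(self):
        trial = build_trial()
        del trial.internal["I2"]
        with pytest.raises(KeyError):
            sum_internal(trial)


class TestPooledInterval:
    def test_zero_variance(self, config):
        iv = pooled_interval([0.5] * 12, config)
        assert (iv.mean, iv.lower, iv.upper) == (0.5, 0.5, 0.5)
        assert iv.n == 12

    def test_two_load_pooling_hand_computation(self, config):
        # 6 values at 0.4 and 6 at 0.6: mean 0.5, sd = sqrt(12*0.01/11)
        values = [0.4] * 6 + [0.6] * 6
        iv = pooled_interval(values, config)
        assert iv.mean == pytest.approx(0.5)
        assert iv.sd == pytest.approx(0.104447, abs=1e-6)
        assert iv.half_width == pytest.approx(0.030151, abs=1e-6)

    def test_pooled_width_exceeds_per_load_width(self, config):
        pooled = pooled_interval([0.4] * 6 + [0.6] * 6, config)
        per_load = pooled_interval([0.4] * 6, config)
        assert per_load.half_width == 0.0
        assert pooled.half_width > 0.0

    def test_symmetry_about_mean(self, config):
        rng = np.random.default_rng(3)
        iv = pooled_interval(rng.uniform(0.3, 0.7, 12), config)
        assert iv.upper - iv.mean == pytest.approx(iv.mean - iv.lower)

    @given(n=st.integers(min_value=2, max_value=200))
    def test_width_nonincreasing_in_n(self, n):
        # fixed mean/sd: the half-width sigma/sqrt(n) shrinks with n
        config = ThresholdConfig()
        small = pooled_interval([0.4, 0.6] * n, config)
        big = pooled_interval([0.4, 0.6] * (n + 1), config)
        assert big.half_width <= small.half_width + 1e-12

    def test_ci_multiplier_scales_width(self):
        values = [0.4] * 6 + [0.6] * 6
        z1 = pooled_interval(values, ThresholdConfig(ci_multiplier=1.0))
        z196 = pooled_interval(values, ThresholdConfig(ci_multiplier=1.96))
        assert z196.half_width == pytest.approx(1.96 * z1.half_width)

    def test_single_value_rejected(self, config):
        with pytest.raises(ValueError):
            pooled_interval([0.5], config)


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([5.0] * 6) == 0.0

    def test_two_point_hand_value(self):
        assert coefficient_of_variation([90.0, 110.0]) == pytest.approx(0.141421, abs=1e-6)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            coefficient_of_variation([-1.0, 1.0])


class TestRatioInterval:
    @pytest.mark.parametrize("method", ["fieller", "delta", "bootstrap"])
    def test_identical_samples_contain_unity(self, config, method):
        values = [100.0, 102.0, 98.0, 101.0, 99.0, 100.0] * 2
        est = ratio_interval(values, values, method, config, seed=1)
        assert est.ratio == pytest.approx(1.0)
        assert est.lower <= 1.0 <= est.upper

    @pytest.mark.parametrize("method", ["fieller", "delta", "bootstrap"])
    def test_constant_samples_zero_width(self, config, method):
        est = ratio_interval([80.0] * 12, [100.0] * 12, method, config, seed=1)
        assert est.ratio == pytest.approx(0.8)
        assert est.lower == pytest.approx(0.8)
        assert est.upper == pytest.approx(0.8)

    def test_fieller_unbounded_when_reference_not_significant(self):
        config = ThresholdConfig(ci_multiplier=1.96)
        # reference mean 1.0 with huge spread: z*SEM exceeds the mean (g >= 1)
        ref = [0.05, 1.95]
        est = ratio_interval([5.0, 5.0], ref, "fieller", config)
        assert est.unbounded
        assert est.lower == -math.inf and est.upper == math.inf

    def test_methods_agree_on_simulated_samples(self, config):
        """Fieller, delta and bootstrap half-widths within 10% of consensus."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            test = rng.normal(160.0, 160.0 * 0.04, 12)
            ref = rng.normal(200.0, 200.0 * 0.04, 12)
            widths = []
            for method in ("fieller", "delta", "bootstrap"):
                est = ratio_interval(test, ref, method, config, seed=7)
                widths.append((est.upper - est.lower) / 2)
            consensus = float(np.mean(widths))
            for w in widths:
                assert abs(w - consensus) / consensus <= 0.10

    def test_bootstrap_requires_seed(self, config):
        with pytest.raises(ValueError, match="seed"):
            ratio_interval([1.0] * 12, [1.0] * 12, "bootstrap", config)

    def test_designed_ratio_recovered_across_seeds(self, config):
        """Samples built at a 0.75 design ratio with 2% CV estimate the ratio
        within [0.70, 0.80] in at least 95% of 200 seeds."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            test = rng.normal(150.0, 150.0 * 0.02, 12)
            ref = rng.normal(200.0, 200.0 * 0.02, 12)
            est = ratio_interval(test, ref, "fieller", config)
            hits += 0.70 <= est.ratio <= 0.80
        assert hits >= 190


class TestCollectParameters:
    def test_excluded_trials_dropped(self, layout):
        trials = [build_trial(trial_index=i + 1) for i in range(6)]
        trials[0].excluded = True
        params = collect_parameters(trials, layout)
        samples = params[(BModel.ELLIPTICAL, Parameter.BONY_FRACTION)]
        assert samples.n == 5
        assert all(idx != 1 for _, idx, _ in samples.values)


class TestEquivalenceLimitDerivation:
    def test_zero_sd_gives_zero(self):
        rec = LiteratureIPMRecord("a", mean=100.0, sd=0.0, n=10)
        assert derive_equivalence_limit([rec]) == 0.0

    def test_single_record_hand_value(self):
        rec = LiteratureIPMRecord("a", mean=100.0, sd=10.0, n=16)
        assert derive_equivalence_limit([rec]) == pytest.approx(0.049)

    def test_bundled_synthetic_table_averages_to_published_value(self):
        from importlib import resources

        from cushionbench.io import read_ipm_table

        source = resources.files("cushionbench.data").joinpath(
            "ipm_literature_synthetic.csv"
        )
        with resources.as_file(source) as path:
            records = read_ipm_table(path)
        assert len(records) == 9
        assert sum(r.n for r in records) == 62
        assert derive_equivalence_limit(records) == pytest.approx(0.153, abs=5e-4)

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            LiteratureIPMRecord("bad", mean=-1.0, sd=1.0, n=5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            derive_equivalence_limit([])
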
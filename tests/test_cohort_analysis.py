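"""Response metrics, exact rank-sum comparison, Gaussianity check."""

import math

import numpy as np
import pandas as pd
import pytest

import levotap as lt
from levotap.cohort_analysis import (
    PARAMETER_NAMES,
    UndefinedDurationError,
    response_metrics,
)
from levotap.errors import InputError


def _series(times, values):
    return lt.SampledSeries(np.asarray(times, float),
                            np.asarray(values, float))


class TestLatency:
    def test_first_time_at_or_above_threshold(self):
        s = _series([0, 15, 30, 45], [100, 110, 115, 130])
        assert lt.latency_to_onset(s, baseline=100.0) == 30.0

    def test_boundary_value_qualifies(self):
        # exactly 15% above baseline counts (inclusive threshold)
        s = _series([0, 20], [100, 115.0])
        assert lt.latency_to_onset(s, 100.0) == 20.0

    def test_never_reached_is_absent(self):
        s = _series([0, 60, 120], [100, 114.9, 110])
        assert lt.latency_to_onset(s, 100.0) is None

    def test_positive_baseline_required(self):
        s = _series([0, 10], [0, 10])
        with pytest.raises(InputError):
            lt.latency_to_onset(s, 0.0)


class TestDuration:
    def test_onset_to_return_difference(self):
        s = _series([0, 30, 90, 180, 240], [100, 120, 140, 110, 105])
        # onset at 30, first post-onset sample below 115 at 180
        assert lt.effect_duration(s, 100.0) == 150.0

    def test_censored_when_no_return(self):
        s = _series([0, 30, 240], [100, 130, 140])
        assert lt.effect_duration(s, 100.0) is None

    def test_error_without_onset(self):
        s = _series([0, 240], [100, 105])
        with pytest.raises(UndefinedDurationError):
            lt.effect_duration(s, 100.0)


class TestClassification:
    def test_return_within_window_is_fluctuating(self):
        s = _series([0, 30, 120, 210, 240], [100, 140, 150, 108, 100])
        assert lt.classify_response(s, 100.0) == "fluctuating"

    def test_sustained_response_is_stable(self):
        s = _series([0, 30, 120, 240], [100, 140, 150, 135])
        assert lt.classify_response(s, 100.0) == "stable"

    def test_flat_series_stable_with_flag(self):
        s = _series([0, 120, 240], [100, 102, 99])
        m = response_metrics(s, 100.0)
        assert m.classification == "stable"
        assert m.no_onset
        assert m.latency_min is None

    def test_metrics_invariant_to_grid_refinement(self):
        # piecewise-linear curve sampled coarsely vs finely: latency and
        # duration move by less than one coarse sampling interval
        t_c = np.array([0.0, 30, 60, 120, 180, 240])
        v_c = np.array([100.0, 130, 160, 140, 110, 100])
        coarse = _series(t_c, v_c)
        t_f = np.arange(0.0, 241.0, 5.0)
        fine = _series(t_f, np.interp(t_f, t_c, v_c))
        lat_c = lt.latency_to_onset(coarse, 100.0)
        lat_f = lt.latency_to_onset(fine, 100.0)
        assert abs(lat_c - lat_f) <= 30.0
        dur_c = lt.effect_duration(coarse, 100.0)
        dur_f = lt.effect_duration(fine, 100.0)
        assert abs(dur_c - dur_f) <= 60.0


class TestCompareGroups:
    @staticmethod
    def _table(rng, shift=0.0, n=13):
        return pd.DataFrame({
            name: rng.lognormal(mean=shift if name in ("ke3", "ND") else 0.0,
                                sigma=0.3, size=n)
            for name in PARAMETER_NAMES
        })

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        g = self._table(rng)
        out = lt.compare_groups(g, g.copy())
        assert np.all(out["p_raw"] == 1.0)
        assert np.all(out["p_bonferroni"] == 1.0)

    def test_fully_separated_groups_exact_p(self):
        # all of group 2 above all of group 1: p = 2 * 13! 13! / 26!
        g1 = pd.DataFrame({n: np.arange(1.0, 14.0) for n in PARAMETER_NAMES})
        g2 = pd.DataFrame({n: np.arange(100.0, 113.0)
                           for n in PARAMETER_NAMES})
        out = lt.compare_groups(g1, g2)
        expected = 2.0 * (math.factorial(13) ** 2) / math.factorial(26)
        np.testing.assert_allclose(out["p_raw"], expected, rtol=1e-10)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(3)
        out = lt.compare_groups(self._table(rng), self._table(rng))
        assert np.all(out["p_bonferroni"] <= 1.0)
        big = out[out["p_raw"] >= 0.2]
        assert np.all(big["p_bonferroni"] == 1.0)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(5)
        g1, g2 = self._table(rng), self._table(rng, shift=1.0)
        a = lt.compare_groups(g1, g2)
        b = lt.compare_groups(g2, g1)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], rtol=1e-12)

    def test_small_groups_rejected(self):
        g = pd.DataFrame({n: [1.0, 2.0] for n in PARAMETER_NAMES})
        with pytest.raises(InputError):
            lt.compare_groups(g, g)


class TestGaussianity:
    def test_normal_sample_usually_passes(self):
        passed = 0
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(10_000)
            _, p = lt.gaussianity_check(x)
            passed += p > 0.05
        assert passed >= 45

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(1).exponential(size=10_000)
        _, p = lt.gaussianity_check(x)
        assert p < 1e-3

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            lt.gaussianity_check(np.arange(5.0))
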
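import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from sentinelgaze.circstats import (
    _kappa_from_R,
    build_bias_table,
    classify_bias,
    exact_binomial_ci,
    fit_vonmises_weighted,
    summarize_orientation,
    vonmises_bootstrap_ci,
    weighted_mean_angle,
    wrap_degrees,
)
from sentinelgaze.eventio import LookRecord, ObservationMeta

QUAD_ANGLES = [0.0, 90.0, 180.0, 270.0]


class TestWeightedMeanAngle:
    def test_single_look(self):
        th, R = weighted_mean_angle([90.0], [1.3])
        assert th == pytest.approx(90.0)
        assert R == pytest.approx(1.0)

    def test_two_point_example(self):
        th, R = weighted_mean_angle([0.0, 90.0], [2.0, 1.0])
        assert th == pytest.approx(math.degrees(math.atan2(1, 2)), abs=1e-9)
        assert R == pytest.approx(math.sqrt(5) / 3.0, abs=1e-9)

    def test_antipodal_balance_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            weighted_mean_angle([0.0, 180.0], [1.0, 1.0])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_angle([0.0, 90.0], [1.0, 0.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        idx=st.lists(st.integers(0, 3), min_size=2, max_size=30),
        w=st.lists(st.floats(0.05, 10.0), min_size=30, max_size=30),
        delta=st.floats(-720.0, 720.0),
        scale=st.floats(0.01, 100.0),
    )
    def test_rotation_equivariance_and_weight_scaling(self, idx, w, delta, scale):
        angles = [QUAD_ANGLES[i] for i in idx]
        weights = w[: len(angles)]
        # brute-force resultant-vector oracle
        rad = np.deg2rad(angles)
        C = np.sum(np.array(weights) * np.cos(rad))
        S = np.sum(np.array(weights) * np.sin(rad))
        if math.hypot(C, S) / sum(weights) <= 1e-6:
            return  # numerically balanced: mean undefined
        th, R = weighted_mean_angle(angles, weights)
        assert th == pytest.approx(
            wrap_degrees(math.degrees(math.atan2(S, C))), abs=1e-9
        )
        th_rot, R_rot = weighted_mean_angle([a + delta for a in angles], weights)
        assert wrap_degrees(th_rot - th - delta) == pytest.approx(0.0, abs=1e-6)
        assert R_rot == pytest.approx(R, abs=1e-9)
        th_sc, R_sc = weighted_mean_angle(angles, [scale * x for x in weights])
        assert th_sc == pytest.approx(th, abs=1e-9)
        assert R_sc == pytest.approx(R, abs=1e-9)


class TestVonMises:
    def test_kappa_inversion_roundtrip(self):
        for kappa in (0.1, 0.5, 1.0, 5.0, 50.0):
            R = special.i1e(kappa) / special.i0e(kappa)
            assert _kappa_from_R(R) == pytest.approx(kappa, rel=1e-6)

    def test_weighted_fit_recovers_generating_parameters(self):
        rng = np.random.default_rng(0)
        ang = np.degrees(rng.vonmises(np.radians(30.0), 5.0, size=4000))
        mu, kappa = fit_vonmises_weighted(ang, np.ones(ang.size))
        assert mu == pytest.approx(30.0, abs=2.0)
        assert kappa == pytest.approx(5.0, rel=0.1)

    def test_concentrated_sample_narrow_ci_contains_zero(self):
        rng = np.random.default_rng(1)
        ang = np.degrees(rng.vonmises(0.0, 50.0, size=200))
        w = rng.uniform(0.5, 2.0, size=200)
        lo, hi = vonmises_bootstrap_ci(ang, w, B=2000, seed=2)
        assert -10.0 < lo < hi < 10.0
        assert classify_bias(lo, hi, weighted_mean_angle(ang, w)[0]) == "none"

    def test_offset_sample_excludes_zero_right_bias(self):
        rng = np.random.default_rng(3)
        ang = np.degrees(rng.vonmises(np.radians(30.0), 20.0, size=200))
        w = rng.uniform(0.5, 2.0, size=200)
        lo, hi = vonmises_bootstrap_ci(ang, w, B=2000, seed=4)
        assert lo > 0.0
        assert classify_bias(lo, hi, weighted_mean_angle(ang, w)[0]) == "right"

    def test_degenerate_single_replicate_warns(self):
        rng = np.random.default_rng(5)
        ang = np.degrees(rng.vonmises(0.0, 10.0, size=50))
        with pytest.warns(UserWarning, match="too small"):
            lo, hi = vonmises_bootstrap_ci(ang, np.ones(50), B=1, seed=6)
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_near_uniform_spans_circle(self):
        # balanced up to a sliver of weight: resultant ~1e-6, kappa ~2e-6
        angles = [0.0, 90.0, 180.0, 270.0] * 10
        weights = np.ones(40)
        weights[0] += 4e-5
        with pytest.warns(UserWarning, match="near-uniform"):
            lo, hi = vonmises_bootstrap_ci(angles, weights, B=200, seed=7)
        assert (lo, hi) == (-180.0, 180.0)

    def test_coverage_at_nominal_level(self):
        # von Mises data, kappa = 5, n = 75: the bootstrap CI should contain
        # the true direction at close to the nominal 95% rate
        rng = np.random.default_rng(8)
        mu_true = 20.0
        hits = 0
        reps = 300
        for _ in range(reps):
            ang = np.degrees(rng.vonmises(np.radians(mu_true), 5.0, size=75))
            lo, hi = vonmises_bootstrap_ci(ang, np.ones(75), B=400, seed=rng)
            hits += lo <= mu_true <= hi if lo <= hi else (mu_true >= lo or mu_true <= hi)
        assert 0.92 <= hits / reps <= 0.98


class TestClassifyBias:
    @pytest.mark.parametrize(
        "ci,expected",
        [((-15.0, 20.0), "none"), ((5.0, 40.0), "right"), ((-40.0, -5.0), "left")],
    )
    def test_simple_intervals(self, ci, expected):
        assert classify_bias(*ci) == expected

    def test_wrapping_interval_containing_180(self):
        # CI from 170 to -170 crosses the rear axis, not 0
        assert classify_bias(170.0, -170.0, mean_angle=180.0) in ("left", "right")
        assert classify_bias(-10.0, 10.0) == "none"

    def test_full_circle_is_none(self):
        assert classify_bias(-180.0, 180.0) == "none"


class TestExactBinomial:
    def test_printed_juvenile_proportion(self):
        p, lo, hi = exact_binomial_ci(5, 9)
        assert round(p, 2) == 0.56
        assert (round(lo, 2), round(hi, 2)) == (0.21, 0.86)

    def test_boundary_zero_successes(self):
        p, lo, hi = exact_binomial_ci(0, 10)
        assert (p, lo) == (0.0, 0.0)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 1, 10))

    def test_against_direct_beta_quantiles(self):
        p, lo, hi = exact_binomial_ci(9, 17)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 9, 9), abs=1e-12)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 10, 8), abs=1e-12)
        assert (round(lo, 2), round(hi, 2)) == (0.28, 0.77)

    def test_monotone_in_successes(self):
        previous = (-1.0, -1.0)
        for k in range(18):
            _, lo, hi = exact_binomial_ci(k, 17)
            assert lo >= previous[0] and hi >= previous[1]
            previous = (lo, hi)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 3)


def _summary(obs_id, bias):
    from sentinelgaze.circstats import OrientationSummary

    return OrientationSummary(
        obs_id=obs_id, mean_angle=0.0, resultant_length=0.5, kappa=1.0,
        ci_low=-10.0, ci_high=10.0, bias=bias, n_looks=50,
    )


def _meta(obs_id, status):
    return ObservationMeta(obs_id, "G1", f"{obs_id}-i", status, 4, 60.0)


class TestBiasTable:
    def test_field_season_counts(self):
        # bias labels with the structure of a full season: 19 + 24 + 17 = 60
        labels = (
            [("adult_female", b) for b in ["left"] * 6 + ["none"] * 7 + ["right"] * 6]
            + [("adult_male", b) for b in ["left"] * 8 + ["none"] * 7 + ["right"] * 9]
            + [("juvenile", b) for b in ["left"] * 4 + ["none"] * 8 + ["right"] * 5]
        )
        summaries = [_summary(f"o{i}", b) for i, (_, b) in enumerate(labels)]
        meta = [_meta(f"o{i}", s) for i, (s, _) in enumerate(labels)]
        table = build_bias_table(summaries, meta).set_index("status")
        assert table["n"].sum() == 60
        assert table.loc["adult_female", "n"] == 19
        assert table.loc["adult_male", "n"] == 24
        assert table.loc["juveniles" if False else "juvenile", "n"] == 17
        juv = table.loc["juvenile"]
        assert (juv.bias_left, juv.no_bias, juv.bias_right) == (4, 8, 5)
        assert round(juv.prop_right, 2) == 0.56
        assert (round(juv.ci_low, 2), round(juv.ci_high, 2)) == (0.21, 0.86)

    def test_one_of_each(self):
        summaries = [_summary("a", "left"), _summary("b", "right"), _summary("c", "none")]
        meta = [_meta(x, "juvenile") for x in "abc"]
        row = build_bias_table(summaries, meta).set_index("status").loc["juvenile"]
        assert (row.bias_left, row.no_bias, row.bias_right) == (1, 1, 1)
        assert row.prop_right == pytest.approx(0.5)

    def test_all_none_is_undefined(self):
        summaries = [_summary("a", "none")]
        meta = [_meta("a", "adult_male")]
        table = build_bias_table(summaries, meta).set_index("status")
        assert bool(table.loc["adult_male", "undefined"])
        assert math.isnan(table.loc["adult_male", "prop_right"])

    def test_unknown_observation_errors(self):
        with pytest.raises(KeyError):
            build_bias_table([_summary("zz", "left")], [_meta("a", "juvenile")])


class TestSummarizeOrientation:
    def test_consistent_with_component_operations(self):
        rng = np.random.default_rng(9)
        looks = [
            LookRecord("o", i, float(i), float(rng.uniform(0.2, 2.0)),
                       q, QUAD_ANGLES[q - 1], 0.1)
            for i, q in enumerate(rng.choice([1, 1, 1, 2, 4], size=80))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_orientation(looks, B=500, seed=10)
        th, R = weighted_mean_angle([lk.angle for lk in looks],
                                    [lk.duration for lk in looks])
        assert s.mean_angle == pytest.approx(th, abs=1e-12)
        assert s.resultant_length == pytest.approx(R, abs=1e-12)
        assert s.bias == classify_bias(s.ci_low, s.ci_high, s.mean_angle)
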
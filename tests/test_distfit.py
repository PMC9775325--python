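import math
import warnings

import numpy as np
import pytest

from sentinelgaze.distfit import (
    FamilySpec,
    PosteriorFit,
    Priors,
    SamplerConfig,
    compare_elpd,
    family_cdf,
    family_loglik,
    fit_family_mle,
    fit_hier_model,
    predict_status_means,
)
from sentinelgaze.eventio import LookRecord, ObservationMeta, derive_looks
from sentinelgaze.synthgen import SimConfig, simulate_population


class TestFamilySpec:
    def test_exactly_four_families(self):
        assert FamilySpec("normal").link == "identity"
        assert FamilySpec("weibull").aux_name == "k"
        assert FamilySpec("exponential").aux_name is None
        with pytest.raises(ValueError):
            FamilySpec("gamma")


class TestFamilyMLE:
    def test_exponential_closed_form(self):
        params, _ = fit_family_mle([1.0, 1.0, 1.0, 1.0], "exponential")
        assert params["rate"] == pytest.approx(1.0)

    def test_lognormal_log_moments(self):
        data = [math.e ** 0, math.e ** 1, math.e ** 2]
        params, _ = fit_family_mle(data, "lognormal")
        assert params["mu"] == pytest.approx(1.0)
        assert params["sigma"] ** 2 == pytest.approx(2.0 / 3.0)

    def test_weibull_shape_on_exponential_draws(self):
        rng = np.random.default_rng(0)
        data = rng.exponential(1.0, size=10_000)
        params, _ = fit_family_mle(data, "weibull")
        assert params["shape"] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_and_domain_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_family_mle([2.0, 2.0, 2.0], "lognormal")
        with pytest.raises(ValueError, match="positive"):
            fit_family_mle([1.0, -1.0, 2.0], "weibull")
        with pytest.raises(ValueError, match="n >="):
            fit_family_mle([1.0], "normal")

    def test_mle_beats_nearby_parameters(self):
        rng = np.random.default_rng(1)
        data = rng.lognormal(0.2, 0.7, size=300)
        for fam in ("normal", "lognormal", "exponential", "weibull"):
            params, ll = fit_family_mle(data, fam)
            cdf = family_cdf(fam, params)
            assert np.all(np.diff(cdf(np.linspace(0.01, 20, 50))) >= -1e-12)
            assert np.isfinite(ll)


class TestFamilyLoglik:
    def test_weibull_k1_equals_exponential(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(1.3, size=500)
        eta = np.full(d.size, 0.4)
        ll_w = family_loglik("weibull", d, eta, 1.0)
        ll_e = family_loglik("exponential", d, eta, None)
        assert np.allclose(ll_w, ll_e, atol=1e-9)

    def test_lognormal_matches_scipy(self):
        from scipy import stats

        d = np.array([0.3, 1.0, 2.7])
        ours = family_loglik("lognormal", d, 0.5, 0.8)
        scipys = stats.lognorm.logpdf(d, 0.8, scale=np.exp(0.5))
        assert np.allclose(ours, scipys, atol=1e-12)


def _small_study(seed=17, n_obs=10, **kw):
    cfg = SimConfig(n_observations=n_obs, n_groups=6, seed=seed, **kw)
    events, meta, truth = simulate_population(cfg)
    looks = [lk for m in meta for lk in derive_looks(events[m.obs_id])]
    return looks, meta, truth


QUICK = SamplerConfig(chains=2, iterations=500, burnin=250, seed=101)


class TestHierModel:
    def test_default_schedule_retains_4000_draws(self, family_fits):
        for fit in family_fits.values():
            assert fit.n_draws == 4000
            assert fit.draws["beta"].shape[:2] == (4, 1000)

    def test_pointwise_loglik_finite_at_every_draw(self, family_fits):
        for fit in family_fits.values():
            assert np.all(np.isfinite(fit.log_likelihood))
            assert fit.log_likelihood.shape == (4000, fit.n_looks)

    def test_rhat_reported_for_every_block(self, family_fits):
        for fam, fit in family_fits.items():
            expected = {"beta", "sigma_group", "sigma_individual", "u", "v"}
            if fam != "exponential":
                expected.add("aux")
            assert expected <= set(fit.rhat)

    def test_posterior_matches_ols_without_random_effects(self):
        looks, meta, _ = _small_study(
            seed=5, n_obs=40, sigma_group=0.0, sigma_individual=0.0
        )
        fit = fit_hier_model(looks, meta, "lognormal", SamplerConfig(seed=77))
        beta = fit.flat("beta")
        meta_by = {m.obs_id: m for m in meta}
        y = np.log([lk.duration for lk in looks])
        X = np.array(
            [
                [1.0, meta_by[lk.obs_id].group_size,
                 meta_by[lk.obs_id].status == "adult_male",
                 meta_by[lk.obs_id].status == "adult_female"]
                for lk in looks
            ],
            dtype=float,
        )
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        for j in (0, 1):  # intercept and group-size slope
            assert abs(beta[:, j].mean() - ols[j]) < 2 * beta[:, j].std()

    def test_single_group_drops_group_effect(self):
        looks, meta, _ = _small_study(seed=7, n_obs=6)
        one_group = [
            ObservationMeta(m.obs_id, "G001", m.individual_id, m.status,
                            m.group_size, m.duration)
            for m in meta
        ]
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_hier_model(looks, one_group, "lognormal", QUICK)
        assert fit.rhat["sigma_group"] == 1.0
        assert np.all(fit.draws["u"] == 0.0)

    def test_too_few_looks_rejected(self):
        looks = [LookRecord("o", i, float(i), 1.0, 1, 0.0, 0.1) for i in range(5)]
        meta = [ObservationMeta("o", "G1", "i1", "juvenile", 3, 10.0)]
        with pytest.raises(ValueError):
            fit_hier_model(looks, meta, "lognormal", QUICK)

    def test_positive_family_rejects_nonpositive_durations(self):
        looks, meta, _ = _small_study(seed=8, n_obs=4)
        looks = looks + [LookRecord(looks[0].obs_id, 999, 0.0, -0.5, 1, 0.0, 0.1)]
        with pytest.raises(ValueError):
            fit_hier_model(looks, meta, "lognormal", QUICK)


def _fake_lognormal_fit(beta_draws, sigma_draws, loglik=None, digest="x"):
    n_draws = beta_draws.shape[0]
    ll = loglik if loglik is not None else np.zeros((n_draws, 8))
    return PosteriorFit(
        family=FamilySpec("lognormal"),
        draws={
            "beta": beta_draws.reshape(1, n_draws, 4),
            "aux": sigma_draws.reshape(1, n_draws),
        },
        rhat={"beta": 1.0},
        log_likelihood=ll,
        group_labels=["G1"],
        individual_labels=["i1"],
        status_levels=("juvenile", "adult_male", "adult_female"),
        data_digest=digest,
        sampler=SamplerConfig(chains=1, iterations=n_draws + 1, burnin=1, seed=0),
        priors=Priors(),
    )


class TestPredictStatusMeans:
    def test_all_zero_coefficients_predict_one_second(self):
        fit = _fake_lognormal_fit(np.zeros((100, 4)), np.zeros(100))
        out = predict_status_means(fit).set_index("status")
        assert np.allclose(out["mean"], 1.0)

    def test_log_link_group_size_arithmetic(self):
        beta = np.zeros((100, 4))
        beta[:, 1] = 0.05
        fit = _fake_lognormal_fit(beta, np.zeros(100))
        at4 = predict_status_means(fit, at_group_size=4)["mean"].to_numpy()
        at5 = predict_status_means(fit, at_group_size=5)["mean"].to_numpy()
        assert np.allclose(at5 / at4, math.exp(0.05))

    def test_requires_lognormal(self, family_fits):
        with pytest.raises(ValueError, match="lognormal"):
            predict_status_means(family_fits["normal"])


class TestCompareElpd:
    def test_single_fit_difference_zero_and_similar(self, family_fits):
        cmp = compare_elpd([family_fits["lognormal"]])
        assert cmp.table.loc[0, "elpd_diff"] == 0.0
        assert bool(cmp.table.loc[0, "similar"])

    def test_similarity_threshold_at_four(self):
        # hand-built pointwise log-likelihood matrices with exactly known
        # ELPD gaps: a constant per-look offset delta/n yields an ELPD
        # difference of exactly delta
        rng = np.random.default_rng(3)
        n = 40
        base = rng.normal(-1.0, 0.01, size=(200, n))
        fits = {}
        for name, delta in [("lognormal", 0.0), ("weibull", 3.9), ("normal", 4.1)]:
            f = _fake_lognormal_fit(
                np.zeros((200, 4)), np.zeros(200), loglik=base - delta / n
            )
            f.family = FamilySpec(name)
            fits[name] = f
        table = compare_elpd(fits).table.set_index("family")
        assert table.loc["weibull", "elpd_diff"] == pytest.approx(3.9, abs=1e-6)
        assert bool(table.loc["weibull", "similar"])
        assert table.loc["normal", "elpd_diff"] == pytest.approx(4.1, abs=1e-6)
        assert not bool(table.loc["normal", "similar"])

    def test_order_invariance(self, family_fits):
        a = compare_elpd(dict(family_fits)).table
        b = compare_elpd(dict(reversed(list(family_fits.items())))).table
        assert a.equals(b)

    def test_mismatched_look_sets_rejected(self):
        f1 = _fake_lognormal_fit(np.zeros((50, 4)), np.zeros(50), digest="a")
        f2 = _fake_lognormal_fit(np.zeros((50, 4)), np.zeros(50), digest="b")
        f2.family = FamilySpec("normal")
        with pytest.raises(ValueError, match="identical look set"):
            compare_elpd([f1, f2])

    def test_duplicate_family_rejected(self):
        f1 = _fake_lognormal_fit(np.zeros((50, 4)), np.zeros(50))
        f2 = _fake_lognormal_fit(np.zeros((50, 4)), np.zeros(50))
        with pytest.raises(ValueError, match="duplicate"):
            compare_elpd([f1, f2])

    def test_matches_arviz_loo_cross_check(self, family_fits):
        import arviz as az

        fit = family_fits["lognormal"]
        ll = fit.log_likelihood.reshape(4, 1000, -1)
        idata = az.from_dict(log_likelihood={"obs": ll})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.loo(idata, pointwise=False, reff=1.0)
        ours = compare_elpd([fit]).table.loc[0]
        assert ours["elpd"] == pytest.approx(float(ref.elpd_loo), rel=1e-6)
        assert ours["se"] == pytest.approx(float(ref.se), rel=0.02)
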
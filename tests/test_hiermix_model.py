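"""Model mean structure, mixtures, observation model, likelihood and MCMC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from anthrotrend.data_model import CountryMeta, DataSource, YEARS
from anthrotrend.growth_reference import SummaryStatistic
from anthrotrend.hiermix_model import (
    MCMCSettings, ModelSpec, ModelState, combined_stratum_mixture, fit,
    log_likelihood, mean_z, observation_variance, population_mixture,
    prepare_sources, prevalence_obs_variance,
)


def _flat_meta(country="AAA", region="south_asia", urban_fraction=0.3):
    series = pd.DataFrame({
        "pop_under5": 1e6, "urban_fraction": urban_fraction, "educ_years": 0.0,
        "log_gdp": 0.0, "urban_prop": 0.0, "health_access": 0.0,
    }, index=list(YEARS))
    return CountryMeta(country=country, region=region, series=series)


def _zero_state(**kw):
    base = dict(
        countries=("AAA",), regions=("south_asia",), region_of=(0,),
        center_year=1998, covariate_names=("educ_years", "log_gdp", "urban_prop",
                                           "health_access"),
        cov_center=np.zeros(4), cov_scale=np.ones(4),
        beta0=0.0, beta1=0.0,
        b0r=np.zeros(1), b1r=np.zeros(1), b0c=np.zeros(1), b1c=np.zeros(1),
        d0=0.0, d1=0.0, d0r=np.zeros(1), d1r=np.zeros(1),
        d0c=np.zeros(1), d1c=np.zeros(1),
        gamma=np.zeros(4), u=np.zeros((1, 27)),
        sigmas={}, lam_rural=0.5, lam_urban=0.5, s0_rural=1.0, s0_urban=1.0,
    )
    base.update(kw)
    return ModelState(**base)


class TestMeanStructure:
    def test_all_effects_zero_gives_zero(self):
        state = _zero_state()
        meta = _flat_meta()
        for stratum in ("rural", "urban", "combined"):
            assert mean_z("AAA", stratum, 2005, state, meta) == 0.0

    def test_global_slope_only(self):
        state = _zero_state(beta1=0.01)
        assert mean_z("AAA", "rural", 2008, state, _flat_meta()) == pytest.approx(0.1)

    def test_urban_minus_rural_equals_offset(self):
        state = _zero_state(beta0=-1.2, d0=0.4, d1=0.01, b0c=np.array([0.2]))
        meta = _flat_meta()
        for year in (1985, 1998, 2011):
            gap = mean_z("AAA", "urban", year, state, meta) \
                - mean_z("AAA", "rural", year, state, meta)
            assert gap == pytest.approx(0.4 + 0.01 * (year - 1998))

    def test_combined_interpolates_with_urban_fraction(self):
        state = _zero_state(d0=0.5)
        meta = _flat_meta(urban_fraction=0.25)
        assert mean_z("AAA", "combined", 2000, state, meta) == pytest.approx(0.125)

    def test_unknown_country_raises(self):
        with pytest.raises(KeyError):
            mean_z("ZZZ", "rural", 2000, _zero_state(), _flat_meta())


class TestMixtures:
    def test_single_component_is_a_normal(self):
        spec = ModelSpec(K=1, weights=(1.0,), offset_pattern=(0.0,), sd_ratios=(1.0,))
        mix = population_mixture(-1.3, spec, (0.7, 1.2))
        assert mix.mean() == pytest.approx(-1.3)
        assert len(mix.weights) == 1
        assert mix.sds[0] == pytest.approx(1.2)

    @pytest.mark.parametrize("mu", [-2.5, -1.0, 0.0, 0.7])
    def test_anchoring_to_the_mean(self, mu):
        spec = ModelSpec()
        for lam, s0 in [(0.0, 1.0), (0.5, 1.1), (1.7, 0.6)]:
            mix = population_mixture(mu, spec, (lam, s0))
            assert mix.mean() == pytest.approx(mu, abs=1e-12)

    def test_default_shape_skewness_matches_sampling_oracle(self):
        spec = ModelSpec()
        mix = population_mixture(-1.5, spec, (0.5, 1.1))
        rng = np.random.default_rng(99)
        n = 10 ** 6
        comp = rng.choice(spec.K, size=n, p=mix.weights)
        draws = rng.normal(mix.means[comp], mix.sds[comp])
        centred = draws - draws.mean()
        mc_skew = np.mean(centred ** 3) / np.mean(centred ** 2) ** 1.5
        assert mix.skewness() == pytest.approx(mc_skew, abs=0.01)
        assert mix.skewness() < 0  # mild left skew by design

    def test_combined_degenerate_cases(self):
        spec = ModelSpec()
        r = population_mixture(-1.0, spec, (0.5, 1.0))
        u = population_mixture(-0.5, spec, (0.5, 1.0))
        np.testing.assert_allclose(
            combined_stratum_mixture(r, u, 0.0).weights[:spec.K], r.weights)
        assert combined_stratum_mixture(r, u, 0.0).mean() == pytest.approx(-1.0)
        assert combined_stratum_mixture(r, u, 1.0).mean() == pytest.approx(-0.5)
        assert combined_stratum_mixture(r, u, 0.4).mean() == pytest.approx(-0.8)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(K=2, weights=(0.6, 0.6), offset_pattern=(0.0, 0.0),
                      sd_ratios=(1.0, 1.0))


class TestObservationModel:
    def _source(self, **kw):
        base = dict(country="AAA", year=2000, stratum="rural", coverage="national",
                    age_coverage="full", metric="haz",
                    summary=SummaryStatistic(-1.2, 1.1, None, "WHO2006"),
                    n=1600, se_mean=0.03)
        base.update(kw)
        return DataSource(**base)

    def test_national_full_who_is_sampling_variance_only(self):
        spec = ModelSpec(tau_national=0.0, tau_subnational_extra=0.0,
                         tau_partial_age_extra=0.0)
        assert observation_variance(self._source(), spec) == pytest.approx(0.03 ** 2)

    def test_flags_add_their_tau_terms(self):
        spec = ModelSpec()
        base = observation_variance(self._source(), spec)
        sub = observation_variance(self._source(coverage="subnational"), spec)
        part = observation_variance(self._source(age_coverage="partial"), spec)
        assert sub - base == pytest.approx(spec.tau_subnational_extra ** 2)
        assert part - base == pytest.approx(spec.tau_partial_age_extra ** 2)
        assert sub >= base  # subnational never less uncertain than national

    def test_conversion_variance_added(self):
        spec = ModelSpec()
        base = observation_variance(self._source(), spec)
        assert observation_variance(self._source(), spec, 0.004) \
            == pytest.approx(base + 0.004)


class TestLogLikelihood:
    def test_zero_sources_is_zero(self):
        assert log_likelihood(_zero_state(), [], {}, ModelSpec()) == 0.0

    def test_single_source_at_model_mean(self):
        state = _zero_state(beta0=-1.2)
        meta = {"AAA": _flat_meta()}
        spec = ModelSpec()
        src = DataSource(country="AAA", year=2000, stratum="rural", coverage="national",
                         age_coverage="full", metric="haz",
                         summary=SummaryStatistic(-1.2, 1.1, None, "WHO2006"),
                         n=1600, se_mean=0.03)
        v = observation_variance(src, spec)
        want = norm.logpdf(0.0, scale=np.sqrt(v))
        assert log_likelihood(state, [src], meta, spec) == pytest.approx(want, abs=1e-12)

    def test_additive_over_sources(self, tiny_sim):
        cfg, truth, sources = tiny_sim
        spec = cfg.model_spec()
        conv, cvs = prepare_sources(sources)
        state = _tiny_state(truth)
        full = log_likelihood(state, conv, truth.meta, spec, cvs)
        drop = log_likelihood(state, conv[1:], truth.meta, spec, cvs[1:])
        single = log_likelihood(state, conv[:1], truth.meta, spec, cvs[:1])
        assert full == pytest.approx(drop + single, abs=1e-9)

    def test_matches_brute_force_recomputation(self, tiny_sim, tiny_fit):
        """Independent per-source density evaluation reproduces the total."""
        cfg, truth, sources = tiny_sim
        spec = cfg.model_spec()
        conv, cvs = prepare_sources(sources)
        state = tiny_fit.state(0, 5)
        got = log_likelihood(state, conv, truth.meta, spec, cvs)
        want = _brute_force_loglik(state, conv, truth.meta, spec, cvs)
        assert got == pytest.approx(want, abs=1e-10)


def _tiny_state(truth):
    C = len(truth.countries)
    R = len(truth.regions)
    return ModelState(
        countries=truth.countries, regions=truth.regions, region_of=truth.region_of,
        center_year=1998, covariate_names=("educ_years", "log_gdp", "urban_prop",
                                           "health_access"),
        cov_center=np.zeros(4), cov_scale=np.ones(4),
        beta0=-1.4, beta1=0.02,
        b0r=np.linspace(-0.2, 0.2, R), b1r=np.zeros(R),
        b0c=np.linspace(-0.1, 0.1, C), b1c=np.zeros(C),
        d0=0.45, d1=0.0, d0r=np.zeros(R), d1r=np.zeros(R),
        d0c=np.zeros(C), d1c=np.zeros(C),
        gamma=np.array([0.1, 0.05, 0.0, 0.02]), u=np.zeros((C, 27)),
        sigmas={}, lam_rural=0.5, lam_urban=0.45, s0_rural=1.1, s0_urban=1.1,
    )


def _brute_force_loglik(state, sources, meta, spec, cvs):
    """Direct re-computation with scipy densities and explicit formulas."""
    w = np.asarray(spec.weights)
    pat = np.asarray(spec.offset_pattern)
    rat = np.asarray(spec.sd_ratios)
    total = 0.0
    for s, cv in zip(sources, cvs):
        m = meta[s.country]
        c = state.countries.index(s.country)
        r = state.region_of[c]
        t = s.year - 1998
        x = (m.series.loc[s.year, list(state.covariate_names)].to_numpy(dtype=float)
             - state.cov_center) / state.cov_scale
        mu_r = (state.beta0 + state.b0r[r] + state.b0c[c]
                + (state.beta1 + state.b1r[r] + state.b1c[c]) * t
                + state.u[c, s.year - 1985] + x @ state.gamma)
        off = (state.d0 + state.d0r[r] + state.d0c[c]
               + (state.d1 + state.d1r[r] + state.d1c[c]) * t)
        p_urb = m.urban_fraction(s.year)
        mu = {"rural": mu_r, "urban": mu_r + off,
              "combined": mu_r + p_urb * off}[s.stratum]
        v = s.se_mean ** 2 + spec.tau_national ** 2 + cv
        if s.coverage == "subnational":
            v += spec.tau_subnational_extra ** 2
        if s.age_coverage == "partial":
            v += spec.tau_partial_age_extra ** 2
        total += norm.logpdf(s.summary.mean_z, loc=mu, scale=np.sqrt(v))
        if s.summary.prev_below is not None:
            def tail(mu_s, lam, s0):
                return float(w @ norm.cdf((-2.0 - mu_s - lam * pat) / (s0 * rat)))
            if s.stratum == "combined":
                pm = ((1 - p_urb) * tail(mu_r, state.lam_rural, state.s0_rural)
                      + p_urb * tail(mu_r + off, state.lam_urban, state.s0_urban))
            elif s.stratum == "rural":
                pm = tail(mu_r, state.lam_rural, state.s0_rural)
            else:
                pm = tail(mu_r + off, state.lam_urban, state.s0_urban)
            pm = min(max(pm, 1e-6), 1 - 1e-6)
            ph = min(max(s.summary.prev_below, 1e-6), 1 - 1e-6)
            wv = ph * (1 - ph) / s.n / norm.pdf(norm.ppf(ph)) ** 2 \
                + spec.tau_national ** 2 + cv
            if s.coverage == "subnational":
                wv += spec.tau_subnational_extra ** 2
            if s.age_coverage == "partial":
                wv += spec.tau_partial_age_extra ** 2
            wv = max(wv, 1e-8)
            total += norm.logpdf(norm.ppf(ph), loc=norm.ppf(pm), scale=np.sqrt(wv))
    return float(total)


class TestFit:
    def test_draw_count_and_determinism(self, tiny_sim):
        cfg, truth, sources = tiny_sim
        settings = MCMCSettings(chains=2, iterations=200, burnin=60, thin=2, seed=5)
        r1 = fit(sources, truth.meta, cfg.model_spec(), settings)
        r2 = fit(sources, truth.meta, cfg.model_spec(), settings)
        assert r1.n_draws == settings.total_draws
        np.testing.assert_array_equal(r1.theta, r2.theta)
        np.testing.assert_array_equal(r1.rural_mean, r2.rural_mean)

    def test_default_settings_yield_2500_draws(self):
        assert MCMCSettings().total_draws == 2500

    def test_fit_requires_sources(self, tiny_sim):
        cfg, truth, _ = tiny_sim
        with pytest.raises(ValueError):
            fit([], truth.meta, cfg.model_spec(), MCMCSettings())

    def test_diagnostics_present(self, tiny_fit):
        assert "ess" in tiny_fit.diagnostics
        assert "rhat" in tiny_fit.diagnostics
        assert isinstance(tiny_fit.diagnostics["warnings"], list)

    def test_posterior_tracks_strong_signal(self, tiny_sim, tiny_fit):
        # posterior means correlate strongly with the simulated truth
        cfg, truth, _ = tiny_sim
        est, tru = [], []
        for c, country in enumerate(truth.countries):
            est.append(tiny_fit.mean_draws(country, "rural").mean(axis=0))
            tru.append(truth.rural_mean[c])
        r = np.corrcoef(np.concatenate(est), np.concatenate(tru))[0, 1]
        assert r > 0.9

    def test_anchoring_holds_in_every_draw(self, tiny_fit):
        # mixture mean equals the mean-Z parameter by construction in draws
        spec = tiny_fit.spec
        mu = tiny_fit.mean_draws(tiny_fit.countries[0], "rural")[:50, 0]
        lam = tiny_fit.hyper_draws("lam_rural")[:50]
        means = mu[:, None] + lam[:, None] * np.asarray(spec.offset_pattern)
        np.testing.assert_allclose(means @ np.asarray(spec.weights), mu, atol=1e-12)

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        path = tmp_path / "fit.npz"
        tiny_fit.save(path)
        from anthrotrend.hiermix_model import FitResult
        back = FitResult.load(path)
        np.testing.assert_array_equal(back.theta, tiny_fit.theta)
        assert back.countries == tiny_fit.countries
        assert back.spec.K == tiny_fit.spec.K
        np.testing.assert_allclose(
            back.mean_draws(back.countries[0], "urban"),
            tiny_fit.mean_draws(tiny_fit.countries[0], "urban"))
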
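"""The hierarchical probit model: link primitives, dataset construction,
the log-density oracle, recovery, pooling and prior behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inactivity import hier_model as hm
from inactivity.splines import natural_cubic_basis
from inactivity.survey_processing import PrevalenceObservation, ValidationError
from inactivity.synthetic_world import band_midpoint


def make_obs(country="A", year=2010, sex="male", band=(40, 49), p=0.3, n=1000.0,
             instrument="GPAQ", national=True):
    return PrevalenceObservation(
        country=country, year=year, sex=sex, age_lo=band[0], age_hi=band[1],
        p_obs=p, n_effective=n, instrument=instrument, national=national,
    )


def covframe(countries, years):
    return pd.DataFrame(
        [{"country": c, "year": y, "covariate": 0.0} for c in countries for y in years]
    )


# reduced-MCMC settings for test fixtures; the ESS floor scales with the
# much smaller retained-draw count
FAST = dict(n_draws=400, chains=2, warmup=100, min_ess=50.0)


class TestLinkPrimitives:
    def test_probit_symmetry_and_quantile(self):
        assert hm.probit(0.5) == 0.0
        assert hm.inv_probit(0.0) == 0.5
        assert hm.probit(0.975) == pytest.approx(1.959964, abs=1e-6)

    def test_round_trip(self):
        p = np.arange(0.01, 1.0, 0.01)
        np.testing.assert_allclose(hm.inv_probit(hm.probit(p)), p, atol=1e-12)

    def test_probit_domain(self):
        with pytest.raises(ValidationError):
            hm.probit(0.0)

    def test_delta_variance_closed_form(self):
        # p = 0.5: 0.25 / (n * phi(0)^2) = pi / (2n)
        assert hm.delta_variance(0.5, 100) == pytest.approx(math.pi / 200.0, abs=1e-12)

    def test_delta_variance_scaling_and_symmetry(self):
        assert hm.delta_variance(0.3, 200) == pytest.approx(hm.delta_variance(0.3, 100) / 2)
        assert hm.delta_variance(0.3, 100) == pytest.approx(hm.delta_variance(0.7, 100))

    @pytest.mark.parametrize(
        "p,n,expected", [(0.0, 100, 0.005), (1.0, 200, 0.9975), (0.3, 50, 0.3)]
    )
    def test_continuity_correction(self, p, n, expected):
        assert hm.continuity_correct(p, n) == pytest.approx(expected, abs=1e-15)


class TestBuildDataset:
    def test_age_band_midpoints(self):
        cfg = hm.ModelConfig(**FAST)
        obs = [make_obs(band=(18, 29)), make_obs(band=(80, math.inf))]
        ds = hm.build_dataset(obs, covframe(["A"], [2010]), {"A": "R1"}, cfg)
        np.testing.assert_allclose(ds.X[0, ds.columns["spline"]], cfg.spline_basis(23.5))
        np.testing.assert_allclose(ds.X[1, ds.columns["spline"]], cfg.spline_basis(88.5))

    def test_reference_instrument_coded_zero(self):
        cfg = hm.ModelConfig(**FAST)
        obs = [make_obs(instrument="GPAQ"), make_obs(instrument="IPAQ_short")]
        ds = hm.build_dataset(obs, covframe(["A"], [2010]), {"A": "R1"}, cfg)
        assert np.all(ds.X[0, ds.columns["instrument"]] == 0.0)
        assert ds.X[1, ds.columns["instrument"]].sum() == 1.0

    def test_response_is_probit_with_delta_variance(self):
        ds = hm.build_dataset(
            [make_obs(p=0.3, n=500)], covframe(["A"], [2010]), {"A": "R1"}, hm.ModelConfig(**FAST)
        )
        assert ds.y[0] == pytest.approx(hm.probit(0.3))
        assert ds.v_sampling[0] == pytest.approx(hm.delta_variance(0.3, 500))

    def test_missing_covariate_names_country_year(self):
        with pytest.raises(ValidationError, match=r"\('A', 2010\)"):
            hm.build_dataset(
                [make_obs()], covframe(["A"], [2011]), {"A": "R1"}, hm.ModelConfig(**FAST)
            )

    def test_missing_region_errors(self):
        with pytest.raises(ValidationError, match="region"):
            hm.build_dataset(
                [make_obs()], covframe(["A"], [2010]), {"B": "R1"}, hm.ModelConfig(**FAST)
            )

    def test_mixed_sexes_rejected(self):
        with pytest.raises(ValidationError):
            hm.build_dataset(
                [make_obs(sex="male"), make_obs(sex="female")],
                covframe(["A"], [2010]), {"A": "R1"}, hm.ModelConfig(**FAST),
            )


def test_log_density_matches_hand_coded_sum(world, observations):
    """The model's log joint equals an independently assembled sum of
    normal log-densities plus priors, to 1e-8."""
    cfg = hm.ModelConfig(**FAST)
    obs = [o for o in observations if o.sex == "male"][:40]
    ds = hm.build_dataset(obs, world.covariate_frame(), world.region_of_country, cfg)

    rng = np.random.default_rng(0)
    params = {
        "intercept": rng.normal(size=1),
        "region_intercept": rng.normal(size=len(ds.regions)),
        "country_intercept": rng.normal(size=len(ds.countries)),
        "slope": rng.normal(size=1) * 0.01,
        "region_slope": rng.normal(size=len(ds.regions)) * 0.01,
        "country_slope": rng.normal(size=len(ds.countries)) * 0.01,
        "spline": rng.normal(size=3),
        "spline_region": rng.normal(size=3 * len(ds.regions)),
        "instrument": rng.normal(size=3),
        "covariate": rng.normal(size=1),
    }
    scales = {name: abs(rng.normal(0.3)) + 0.05 for name in hm.SCALE_NAMES}

    got = hm.log_density(ds, params, scales)

    # --- independent hand computation ---------------------------------
    cov = {(r.country, r.year): r.covariate for r in world.covariate_frame().itertuples()}
    non_ref = [i for i in ("GPAQ", "IPAQ_short", "EB", "other") if i != "GPAQ"]
    expected = 0.0
    for o in obs:
        c = ds.countries.index(o.country)
        r = ds.regions.index(world.region_of_country[o.country])
        B = natural_cubic_basis(band_midpoint(o.age_lo, o.age_hi))
        mu = (
            params["intercept"][0]
            + params["region_intercept"][r]
            + params["country_intercept"][c]
            + (params["slope"][0] + params["region_slope"][r] + params["country_slope"][c])
            * (o.year - cfg.reference_year)
            + B @ (params["spline"] + params["spline_region"][3 * r : 3 * r + 3])
            + (0.0 if o.instrument == "GPAQ" else params["instrument"][non_ref.index(o.instrument)])
            + params["covariate"][0] * (cov[(o.country, o.year)] - ds.covariate_center)
        )
        y = stats.norm.ppf(o.p_obs)
        v = o.p_obs * (1 - o.p_obs) / (o.n_effective * stats.norm.pdf(y) ** 2)
        tau = scales["tau_national"] if o.national else scales["tau_subnational"]
        expected += stats.norm.logpdf(y, mu, math.sqrt(v + tau**2))
    prior_sds = np.concatenate(
        [
            [1.0],
            np.full(len(ds.regions), scales["sd_region_intercept"]),
            np.full(len(ds.countries), scales["sd_country_intercept"]),
            [1.0],
            np.full(len(ds.regions), scales["sd_region_slope"]),
            np.full(len(ds.countries), scales["sd_country_slope"]),
            [1.0] * 3,
            np.full(3 * len(ds.regions), scales["sd_region_spline"]),
            [1.0] * 3,
            [1.0],
        ]
    )
    beta = np.concatenate(
        [
            params["intercept"], params["region_intercept"], params["country_intercept"],
            params["slope"], params["region_slope"], params["country_slope"],
            params["spline"], params["spline_region"], params["instrument"], params["covariate"],
        ]
    )
    expected += stats.norm.logpdf(beta, 0.0, prior_sds).sum()
    for name in hm.SCALE_NAMES:
        expected += stats.halfnorm.logpdf(scales[name], scale=0.5)

    assert got == pytest.approx(expected, abs=1e-8)


def line_dataset(slope=0.02, duplicate=1):
    """One country observed on an exact probit line with tiny noise."""
    obs = []
    for year in range(2000, 2023):
        z = -0.5 + slope * (year - 2011)
        for _ in range(duplicate):
            obs.append(make_obs(country="A", year=year, p=float(stats.norm.cdf(z)), n=10**6))
    return hm.build_dataset(
        obs, covframe(["A"], range(2000, 2023)), {"A": "R1"},
        hm.ModelConfig(n_draws=800, chains=2, warmup=200, min_ess=50.0, seed=3),
    )


class TestFit:
    def test_recovers_known_line(self):
        ds = line_dataset()
        draws = hm.fit(ds)
        total = draws.total_country_slope()[:, 0]
        assert abs(total.mean() - 0.02) < 2 * total.std()

    def test_duplicated_data_shrinks_posterior(self):
        """Doubling every row can only add information: posterior spread of
        the identified quantities (unit-level prevalence, total slope)
        shrinks."""
        surfs = []
        slopes = []
        for duplicate in (1, 2):
            draws = hm.fit(line_dataset(duplicate=duplicate))
            slopes.append(draws.total_country_slope()[:, 0].std())
            surf = hm.predict_surface(draws, ["A"], [2005], [(40, 49)], covframe(["A"], [2005]))
            surfs.append(surf.values.ravel().std())
        assert slopes[1] < slopes[0]
        assert surfs[1] < surfs[0]

    def test_unidentified_instrument_offsets_revert_to_prior(self):
        """With only reference-instrument data the non-reference offsets are
        unidentified and the posterior matches the N(0,1) prior (KS test)."""
        ds = line_dataset()
        draws = hm.fit(ds)
        ks = stats.kstest(draws.instrument_offsets["EB"], "norm")
        assert ks.pvalue > 0.01

    def test_convergence_gate_enforced(self):
        ds = line_dataset()
        with pytest.raises(hm.ConvergenceError) as err:
            hm.fit(ds, hm.ModelConfig(**FAST, seed=3, rhat_max=0.5))
        assert "max_rhat" in err.value.diagnostics

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValidationError):
            hm.build_dataset([], covframe(["A"], [2010]), {"A": "R1"})

    def test_wider_tau_prior_never_narrows_intervals(self):
        """Widening the extra-variance prior cannot make the posterior
        surface intervals narrower (information can only decrease)."""
        obs = [
            make_obs(country="A", year=y, p=p, n=400)
            for y, p in [(2004, 0.25), (2008, 0.4), (2012, 0.22), (2016, 0.38), (2020, 0.27)]
        ]
        widths = []
        for tau_scale in (0.02, 1.0):
            cfg = hm.ModelConfig(
                **FAST, seed=5,
                prior_sd_scale_overrides={"tau_national": tau_scale, "tau_subnational": tau_scale},
            )
            ds = hm.build_dataset(obs, covframe(["A"], range(2000, 2023)), {"A": "R1"}, cfg)
            draws = hm.fit(ds, cfg)
            surf = hm.predict_surface(
                draws, ["A"], [2010], [(40, 49)], covframe(["A"], [2010])
            )
            lo, hi = np.percentile(surf.values.ravel(), [2.5, 97.5])
            widths.append(hi - lo)
        assert widths[1] >= widths[0] * 0.99  # small Monte-Carlo slack


class TestPredictSurface:
    def test_all_zero_parameters_give_half(self, male_dataset):
        draws = hm.fit(male_dataset)
        zero = hm.PosteriorDraws(
            sex="male", countries=draws.countries, regions=draws.regions,
            region_idx=draws.region_idx, reference_year=2011,
            instrument_names=draws.instrument_names,
            intercept=np.zeros(10), region_intercept=np.zeros((10, len(draws.regions))),
            country_intercept=np.zeros((10, len(draws.countries))), slope=np.zeros(10),
            region_slope=np.zeros((10, len(draws.regions))),
            country_slope=np.zeros((10, len(draws.countries))),
            spline=np.zeros((10, 3)),
            spline_region=np.zeros((10, len(draws.regions), 3)),
            instrument_offsets={"GPAQ": np.zeros(10)},
            covariate_coef=np.zeros(10),
            scales={n: np.ones(10) for n in hm.SCALE_NAMES},
            covariate_center=0.0, config=draws.config,
        )
        surf = hm.predict_surface(
            zero, draws.countries[:2], [2010], [(18, 29)],
            covframe(draws.countries[:2], [2010]),
        )
        np.testing.assert_array_equal(surf.values, 0.5)

    def test_year_outside_range_requires_projection_flag(self, male_draws, world):
        with pytest.raises(ValidationError, match="projection"):
            hm.predict_surface(
                male_draws, male_draws.countries[:1], [2030], [(18, 29)],
                world.covariate_frame(),
            )

    def test_data_free_country_gets_wider_shrinkage_draws(self):
        """A country with no data in a 2-country region receives the region
        mean plus a fresh country deviation; its spread across draws is at
        least the data-rich country's."""
        obs = [
            make_obs(country="A", year=y, band=b, p=0.3, n=2000)
            for y in (2005, 2015) for b in [(18, 29), (40, 49), (60, 69)]
        ]
        cfg = hm.ModelConfig(**FAST, seed=9)
        ds = hm.build_dataset(obs, covframe(["A"], range(2000, 2023)), {"A": "R1"}, cfg)
        draws = hm.fit(ds, cfg)
        surf = hm.predict_surface(
            draws, ["A", "B"], [2010], [(40, 49)],
            covframe(["A", "B"], [2010]),
            region_of_country={"A": "R1", "B": "R1"}, augment_seed=1,
        )
        sd_a = surf.sel("A", 2010, (40, 49)).std()
        sd_b = surf.sel("B", 2010, (40, 49)).std()
        assert sd_b >= sd_a

    def test_partial_pooling_pulls_single_observation_toward_region(self):
        """A one-observation country's posterior-mean prediction lies
        between its own data value and the region's level on the probit
        scale."""
        obs = [make_obs(country="C", year=2010, p=0.2, n=5000) for _ in range(20)]
        obs += [make_obs(country="A", year=2010, p=0.4, n=5000)]
        cfg = hm.ModelConfig(**FAST, seed=13)
        ds = hm.build_dataset(
            obs, covframe(["A", "C"], [2010]), {"A": "R1", "C": "R1"}, cfg
        )
        draws = hm.fit(ds, cfg)
        surf = hm.predict_surface(draws, ["A"], [2010], [(40, 49)], covframe(["A"], [2010]))
        z = stats.norm.ppf(surf.sel("A", 2010, (40, 49))).mean()
        assert stats.norm.ppf(0.2) < z < stats.norm.ppf(0.4)


def test_ipaq_offset_sign_recovered_across_seeds(world):
    """The simulated +0.15 probit IPAQ offset is recovered with the correct
    sign in >= 95% of repeated reduced-draw fits (10 seeds)."""
    from inactivity.synthetic_world import default_survey_plan, simulate_survey_observations

    correct = 0
    for seed in range(10):
        obs = [
            o
            for s in default_survey_plan(world, surveys_per_country=2, sample_size_per_stratum=2000)
            for o in simulate_survey_observations(
                world, s, rng=np.random.default_rng([seed, world.countries.index(s.country), s.midyear])
            )
            if o.sex == "male"
        ]
        cfg = hm.ModelConfig(n_draws=300, chains=2, warmup=80, seed=seed, min_ess=30.0)
        ds = hm.build_dataset(obs, world.covariate_frame(), world.region_of_country, cfg)
        draws = hm.fit(ds, cfg)
        correct += draws.instrument_offsets["IPAQ_short"].mean() > 0
    assert correct >= 9.5  # 95% of 10
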
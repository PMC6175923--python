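"""Price, discount-rate, storm and covariance machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deadwoodnet import presets, synth, uncertainty
from deadwoodnet.uncertainty import (
    DiscountRateSpec,
    GBMSpec,
    StormModel,
    annual_occurrence_probability,
    estimate_covariance,
    estimate_volatility,
    fit_gumbel,
    nearest_positive_definite,
    sample_discount_rates,
    simulate_price_paths,
    storm_damage_fraction,
)


def _history(prices_by_assortment):
    rows = []
    for a, prices in prices_by_assortment.items():
        for y, p in enumerate(prices):
            rows.append({"species": "beech", "assortment_class": a, "year": 2000 + y, "price": p})
    return pd.DataFrame(rows)


class TestVolatility:
    def test_constant_growth_has_zero_sigma(self):
        h = _history({"pulp": [100, 110, 121], "sawlog_small": [50, 55, 60.5]})
        v = estimate_volatility(h, assortment_order=("pulp", "sawlog_small"))
        assert (v["sigma"].abs() < 1e-12).all()

    def test_flat_prices_zero_sigma_not_error(self):
        h = _history({"pulp": [100] * 10, "sawlog_small": [60] * 10})
        v = estimate_volatility(h, assortment_order=("pulp", "sawlog_small"))
        assert (v["sigma"] == 0).all()

    def test_neighbour_substitution_above_cap(self, rng):
        wild = 100 * np.exp(np.cumsum(rng.normal(0, 0.8, 16)))
        calm = 60 * np.exp(np.cumsum(rng.normal(0, 0.05, 16)))
        h = _history({"pulp": wild, "sawlog_small": calm})
        v = estimate_volatility(h, cap=0.2, assortment_order=("pulp", "sawlog_small"))
        pulp = v[v["assortment_class"] == "pulp"].iloc[0]
        saw = v[v["assortment_class"] == "sawlog_small"].iloc[0]
        assert pulp["substituted"]
        assert pulp["sigma"] == pytest.approx(saw["sigma"])

    def test_recovers_generator_volatility(self):
        hist = synth.generate_price_history(seed=5, n_years=400)
        v = estimate_volatility(hist, cap=1.0)
        large = v[v["assortment_class"] == "sawlog_large"]
        assert large["sigma"].mean() == pytest.approx(0.08, abs=0.02)


class TestGBM:
    def test_zero_sigma_constant_paths(self):
        paths = simulate_price_paths(GBMSpec(initial_price=80.0, sigma=0.0, n_paths=5), seed=1)
        assert paths.shape == (5, 51)
        assert np.allclose(paths, 80.0)

    def test_paths_positive_and_deterministic(self):
        spec = GBMSpec(initial_price=60.0, sigma=0.3, n_paths=50)
        a = simulate_price_paths(spec, seed=3)
        b = simulate_price_paths(spec, seed=3)
        np.testing.assert_array_equal(a, b)
        assert (a > 0).all()

    def test_volatility_and_zero_drift_recovery(self):
        """10^4 paths: 1-year log-return SD near sigma, 50-year mean near 0."""
        spec = GBMSpec(initial_price=100.0, sigma=0.1, horizon_years=50, n_paths=10_000)
        paths = simulate_price_paths(spec, seed=7)
        lr1 = np.log(paths[:, 1] / paths[:, 0])
        se_sd = 0.1 / np.sqrt(2 * (spec.n_paths - 1))
        assert abs(lr1.std(ddof=1) - 0.1) < 3 * se_sd
        lr50 = np.log(paths[:, -1] / paths[:, 0])
        assert abs(lr50.mean()) < 3 * lr50.std(ddof=1) / np.sqrt(spec.n_paths)

    def test_log_increments_normal(self):
        spec = GBMSpec(initial_price=100.0, sigma=0.2, horizon_years=2, n_paths=10_000)
        paths = simulate_price_paths(spec, seed=11)
        incr = np.log(paths[:, 1] / paths[:, 0])
        assert stats.kstest(incr, "norm", args=(0.0, 0.2)).pvalue > 0.01

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            GBMSpec(initial_price=10.0, sigma=-0.1)


class TestDiscountRates:
    def test_bounds_and_endpoints(self):
        spec = DiscountRateSpec()
        r = sample_discount_rates(spec, 10_000, seed=2)
        assert r.min() >= 0.0067
        assert r.max() <= 0.03
        # zero deviate maps to the risk-free end, truncation point to the top
        q = -np.log(1 - spec.truncation_quantile) / spec.exp_rate
        assert spec.risk_free + (0.0 / q) * (spec.upper_rate - spec.risk_free) == 0.0067
        assert spec.risk_free + (q / q) * (spec.upper_rate - spec.risk_free) == pytest.approx(0.03)

    def test_density_decreasing_in_rate(self):
        r = sample_discount_rates(DiscountRateSpec(), 10_000, seed=3)
        hist, _ = np.histogram(r, bins=8, range=(0.0067, 0.03))
        assert (np.diff(hist) <= 0).all()

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            DiscountRateSpec(risk_free=0.05, upper_rate=0.03)


class TestGumbel:
    def test_aop_at_location_parameter(self):
        assert annual_occurrence_probability(28.0, 28.0, 4.0) == pytest.approx(
            1 - np.exp(-1), abs=1e-9
        )

    def test_aop_decreasing_in_speed(self):
        xs = np.linspace(20, 60, 40)  # below ~mu-3s the probability saturates at 1
        aops = [annual_occurrence_probability(x, 28.0, 4.0) for x in xs]
        assert all(a > b for a, b in zip(aops, aops[1:]))

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fit_gumbel(np.full(48, 25.0))

    def test_fit_matches_closed_form_oracle(self):
        w = synth.generate_wind_series(seed=21, mu=30.0, s=5.0, n_years=2000)
        mu, s = fit_gumbel(w)
        assert mu == pytest.approx(30.0, abs=0.5)
        assert s == pytest.approx(5.0, abs=0.4)


class TestStormDamage:
    def _model(self, **kw):
        return StormModel(gumbel_mu=28.0, gumbel_s=4.0, **kw)

    def test_zero_predictor_gives_half(self):
        m = self._model(
            damage_coeffs={"beech": (0.0, 0.0, 0.0)}, topex_betas=(0.0, 0.0, 0.0, 0.0)
        )
        assert storm_damage_fraction(40.0, 30.0, 1, "beech", m) == pytest.approx(0.5)

    def test_large_negative_intercept_vanishes(self):
        m = self._model(
            damage_coeffs={"beech": (-50.0, 0.0, 0.0)}, topex_betas=(0.0, 0.0, 0.0, 0.0)
        )
        assert storm_damage_fraction(40.0, 30.0, 1, "beech", m) < 1e-12

    def test_probability_is_damaged_share(self):
        # logit^-1(g)=0.3 -> 30% of the stand damaged, used directly
        g = np.log(0.3 / 0.7)
        m = self._model(
            damage_coeffs={"beech": (g, 0.0, 0.0)}, topex_betas=(0.0, 0.0, 0.0, 0.0)
        )
        assert storm_damage_fraction(40.0, 30.0, 1, "beech", m) == pytest.approx(0.3)

    def test_smoothing_decays_with_distance(self):
        m = self._model(storm_center=(0.0, 0.0))
        near = storm_damage_fraction(40.0, 30.0, 2, "beech", m, location=(0.0, 0.0))
        far = storm_damage_fraction(40.0, 30.0, 2, "beech", m, location=(50_000.0, 0.0))
        assert near > far


@pytest.fixture(scope="module")
def small():
    return presets.small_instance(seed=1)


class TestScenarios:
    def _scen(self, inst, aop, seed=5, n=20, sigma=None):
        storm = presets.default_storm_model(inst.landscape)
        storm = uncertainty.StormModel(
            gumbel_mu=storm.gumbel_mu, gumbel_s=storm.gumbel_s, aop_override=aop
        )
        sig = sigma if sigma is not None else presets.default_sigma_by_species()
        return uncertainty.simulate_scenarios(
            inst.landscape,
            inst.outcomes,
            sig,
            DiscountRateSpec(),
            storm,
            n_per_trajectory=n,
            seed=seed,
        )

    def test_no_storm_no_price_noise_matches_economics(self, small):
        """AOP=0 and zero volatility: scenario NPVs equal storm-free NPVs."""
        from deadwoodnet import economics

        scen = self._scen(small, aop=0.0, sigma={sp: 0.0 for sp in synth.SPECIES})
        n_periods = synth.n_periods_of(small.outcomes)
        s_idx = scen.stand_index()
        r_idx = scen.regime_index()
        labels = scen.labels
        sub = small.outcomes[small.outcomes["trajectory"] == "RCP4.5"]
        for _, row in sub.head(8).iterrows():
            prof = economics.profile_from_outcome(row, n_periods)
            for k in np.where(labels["trajectory"] == "RCP4.5")[0][:4]:
                expect = economics.compute_npv(prof, float(labels.iloc[k]["rate"]))
                got = scen.npv[s_idx[int(row["stand_id"])], r_idx[int(row["regime_id"])], k]
                assert got == pytest.approx(expect, rel=1e-9)

    def test_certain_total_loss_kills_all_harvest_cash(self, small):
        """AOP=1 with damage ~1 from period 1: only the initial stock remains."""
        storm = uncertainty.StormModel(
            gumbel_mu=28.0,
            gumbel_s=4.0,
            aop_override=1.0,
            damage_coeffs={sp: (50.0, 0.0, 0.0) for sp in synth.SPECIES},
            topex_betas=(0.0, 0.0, 0.0, 0.0),
            smoothing_amplitude=0.0,
        )
        scen = uncertainty.simulate_scenarios(
            small.landscape,
            small.outcomes,
            {sp: 0.0 for sp in synth.SPECIES},
            DiscountRateSpec(),
            storm,
            n_per_trajectory=3,
            seed=9,
        )
        sub = small.outcomes[small.outcomes["trajectory"] == "RCP4.5"]
        s_idx = scen.stand_index()
        r_idx = scen.regime_index()
        for _, row in sub.head(6).iterrows():
            got = scen.npv[s_idx[int(row["stand_id"])], r_idx[int(row["regime_id"])], :]
            assert np.allclose(got, -row["ini_stock_value"], rtol=1e-6)

    def test_storm_period_price_shock(self, small):
        """A storm multiplies that period's effective price by 0.75."""
        inst = small
        storm_on = uncertainty.StormModel(
            gumbel_mu=28.0,
            gumbel_s=4.0,
            aop_override=1.0,
            damage_coeffs={sp: (-50.0, 0.0, 0.0) for sp in synth.SPECIES},  # no damage
            topex_betas=(0.0, 0.0, 0.0, 0.0),
            smoothing_amplitude=0.0,
        )
        scen = uncertainty.simulate_scenarios(
            inst.landscape,
            inst.outcomes,
            {sp: 0.0 for sp in synth.SPECIES},
            DiscountRateSpec(),
            storm_on,
            n_per_trajectory=2,
            seed=13,
        )
        from deadwoodnet import economics

        n_periods = synth.n_periods_of(inst.outcomes)
        sub = inst.outcomes[inst.outcomes["trajectory"] == "RCP4.5"]
        row = sub.iloc[1]
        prof = economics.profile_from_outcome(row, n_periods)
        k = int(np.where(scen.labels["trajectory"] == "RCP4.5")[0][0])
        r = float(scen.labels.iloc[k]["rate"])
        shocked = economics.CashflowProfile(
            ini_stock=prof.ini_stock,
            yearly_thin_net=prof.yearly_thin_net * 0.75,  # storms certain every year
            fin_stock=prof.fin_stock,
        )
        expect = economics.compute_npv(shocked, r)
        got = scen.npv[
            scen.stand_index()[int(row["stand_id"])],
            scen.regime_index()[int(row["regime_id"])],
            k,
        ]
        assert got == pytest.approx(expect, rel=1e-9)

    def test_deterministic_per_seed(self, small):
        a = self._scen(small, aop=0.0, seed=3, n=4)
        b = self._scen(small, aop=0.0, seed=3, n=4)
        np.testing.assert_array_equal(a.npv, b.npv)


class TestCovariance:
    def test_diagonal_cholesky(self):
        c = np.diag([4.0, 9.0])
        rep = nearest_positive_definite(c)
        L = np.linalg.cholesky(rep)
        assert np.allclose(np.diag(L), [2.0, 3.0])

    def test_tiny_negative_eigenvalue_repaired(self):
        v = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))[0]
        c = (v * np.array([2.0, 1.0, -1e-10])) @ v.T
        rep = nearest_positive_definite(c)
        w = np.linalg.eigvalsh(rep)
        assert (w > 0).all()
        assert np.linalg.norm(rep - c) <= 1e-9

    def test_cholesky_reproduction_accuracy(self, small_instance):
        scen = presets.default_scenarios(small_instance, n_per_trajectory=10, seed=3)
        cov = estimate_covariance(scen)
        for j in range(cov.chol.shape[0]):
            L = cov.chol[j]
            rel = np.linalg.norm(L @ L.T - cov.repaired[j]) / np.linalg.norm(cov.repaired[j])
            assert rel <= 1e-8

    def test_independent_stands_have_vanishing_covariance(self):
        """Sample covariance off-diagonals shrink as scenarios grow."""
        rng = np.random.default_rng(4)
        n = 10_000
        npv = rng.normal(0, 1.0, size=(3, 1, n))
        scen = uncertainty.ScenarioSet(
            stand_ids=[0, 1, 2],
            regime_ids=[1],
            npv=npv,
            labels=pd.DataFrame({"trajectory": ["x"] * n}),
            seed=0,
        )
        cov = estimate_covariance(scen)
        off = cov.raw[0][~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 3.0 / np.sqrt(n)

    def test_too_few_scenarios_rejected(self):
        scen = uncertainty.ScenarioSet(
            stand_ids=[0],
            regime_ids=[1],
            npv=np.zeros((1, 1, 1)),
            labels=pd.DataFrame({"trajectory": ["x"]}),
            seed=0,
        )
        with pytest.raises(ValueError):
            estimate_covariance(scen)
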
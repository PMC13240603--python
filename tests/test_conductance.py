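"""Penman-Monteith inversion, validity filtering and Medlyn fitting."""

import numpy as np
import pandas as pd
import pytest

from ozflux import meteo
from ozflux.conductance import (REASON_RAIN, REASON_RH, REASON_SZA,
                                canopy_vpd, fit_medlyn, fit_medlyn_windows,
                                h2o_to_o3_conductance, medlyn_model,
                                medlyn_predict, pm_inversion,
                                stomatal_validity_mask, surface_temperature)
from ozflux.meteo import saturation_vapor_pressure


class TestSaturationVaporPressure:
    def test_magnus_at_zero(self):
        assert saturation_vapor_pressure(0.0) == pytest.approx(0.6108)

    def test_at_25C(self):
        assert saturation_vapor_pressure(25.0) == pytest.approx(3.167, abs=2e-3)

    def test_strictly_increasing(self):
        t = np.linspace(-20, 45, 200)
        assert np.all(np.diff(saturation_vapor_pressure(t)) > 0)


class TestSurfaceTemperature:
    def test_no_heat_flux(self):
        assert surface_temperature(20.0, 0.0, 1.2, 1004.0, 50.0, 10.0) == 20.0

    def test_warming_arithmetic(self):
        ts = surface_temperature(20.0, 200.0, 1.2, 1004.0, 50.0, 10.0)
        assert ts - 20.0 == pytest.approx(9.96, abs=0.01)

    def test_negative_heat_flux_cools(self):
        assert surface_temperature(20.0, -50.0, 1.2, 1004.0, 50.0, 10.0) < 20.0


class TestCanopyVpd:
    def test_saturated_air_is_zero(self):
        es = saturation_vapor_pressure(22.0)
        assert canopy_vpd(22.0, es) == pytest.approx(0.0, abs=1e-12)

    def test_magnus_evaluation(self):
        expected = saturation_vapor_pressure(30.0) - 2.0
        assert canopy_vpd(30.0, 2.0) == pytest.approx(expected)
        assert canopy_vpd(30.0, 2.0) == pytest.approx(2.246, abs=5e-3)

    def test_dewlike_negative_possible(self):
        assert canopy_vpd(10.0, 3.0) < 0


class TestPmInversion:
    def test_forward_inverse_round_trip(self):
        rho, cp, gamma, ra, rb = 1.2, 1004.0, 0.066, 20.0, 10.0
        rc_true = 100.0
        vpd_can = 1.5
        lam_e = rho * cp * vpd_can / (gamma * (ra + rb + rc_true))
        g, valid = pm_inversion(lam_e, vpd_can, gamma, rho, cp, ra, rb)
        assert valid
        assert 1.0 / g == pytest.approx(rc_true, rel=1e-12)

    def test_printed_arithmetic(self):
        g, valid = pm_inversion(210.6, 1.5, 0.066, 1.2, 1004.0, 15.0, 15.0)
        assert valid
        assert 1.0 / g == pytest.approx(100.0, abs=0.1)

    def test_huge_lambda_e_flagged(self):
        g, valid = pm_inversion(1e9, 1.5, 0.066, 1.2, 1004.0, 15.0, 15.0)
        assert not valid and np.isnan(g)

    def test_nonpositive_inputs_excluded(self):
        for lam_e, vpd_can in ((-10.0, 1.0), (100.0, -0.5), (0.0, 1.0)):
            g, valid = pm_inversion(lam_e, vpd_can, 0.066, 1.2, 1004.0, 15.0, 15.0)
            assert not valid and np.isnan(g)


def _mask_df(times, precip=0.0, rh=50.0):
    n = len(times)
    return pd.DataFrame({
        "TIMESTAMP": times,
        "P": np.full(n, precip) if np.isscalar(precip) else precip,
        "RH": np.full(n, rh) if np.isscalar(rh) else rh,
    })


class TestValidityMask:
    SITE = dict(lat=40.0062, lon=-88.2904, utc_offset=-6.0)

    def test_rain_window_36h(self):
        times = pd.date_range("2023-07-01 00:30", periods=3 * 48, freq="30min")
        precip = np.zeros(len(times))
        precip[times.get_loc(pd.Timestamp("2023-07-01 12:00"))] = 4.0
        mask, reasons = stomatal_validity_mask(_mask_df(times, precip), **self.SITE)
        # 13:00 next day is within the 36 h window; 12:00 day 3 just outside
        i_in = times.get_loc(pd.Timestamp("2023-07-02 13:00"))
        i_out = times.get_loc(pd.Timestamp("2023-07-03 12:00"))
        assert reasons[REASON_RAIN].iloc[i_in]
        assert not reasons[REASON_RAIN].iloc[i_out]

    def test_rh_boundary_is_exclusive(self):
        times = pd.date_range("2023-07-01 12:00", periods=2, freq="30min")
        mask, reasons = stomatal_validity_mask(
            _mask_df(times, rh=np.array([80.0, 79.9])), **self.SITE)
        assert reasons[REASON_RH].tolist() == [True, False]

    def test_night_excluded_by_sza(self):
        times = pd.DatetimeIndex([pd.Timestamp("2023-07-01 00:30"),
                                  pd.Timestamp("2023-07-01 12:30")])
        mask, reasons = stomatal_validity_mask(_mask_df(times), **self.SITE)
        assert reasons[REASON_SZA].tolist() == [True, False]

    def test_clear_dry_noon_retained(self):
        times = pd.DatetimeIndex([pd.Timestamp("2023-07-01 12:30")])
        mask, _ = stomatal_validity_mask(_mask_df(times), **self.SITE)
        assert mask.all()


class TestMedlynModel:
    def test_printed_value(self):
        g = medlyn_model(30.0, 1.0, 0.01, 3.0, ca_umol=420.0)
        assert g == pytest.approx(0.4671, abs=1e-4)

    def test_zero_gpp_gives_g0(self):
        assert medlyn_model(0.0, 1.0, 0.013, 3.0) == pytest.approx(0.013)

    def test_mol_to_ms_conversion(self):
        g_ms = meteo.conductance_mol_to_ms(0.4671, 25.0, 101.325)
        assert g_ms == pytest.approx(0.01143, abs=2e-5)


class TestMedlynFit:
    def _window_df(self, g0, g1, n=100, noise=0.0, seed=0, days=10):
        rng = np.random.default_rng(seed)
        gpp = rng.uniform(5, 40, n)
        vpd = rng.uniform(0.3, 3.0, n)
        gs = medlyn_model(gpp, vpd, g0, g1)
        gs = gs * (1.0 + noise * rng.standard_normal(n))
        times = pd.date_range("2023-07-01", periods=n,
                              freq=pd.Timedelta(days=days) / n)
        return pd.DataFrame({"TIMESTAMP": times, "GS_H2O_PM_MOL": gs,
                             "GPP": gpp, "VPD_CAN": vpd})

    def test_noiseless_exact_recovery(self):
        df = self._window_df(0.02, 2.5)
        fits = fit_medlyn_windows(df)
        assert len(fits) == 1
        assert fits[0].g0 == pytest.approx(0.02, rel=1e-6, abs=1e-8)
        assert fits[0].g1 == pytest.approx(2.5, rel=1e-6)

    def test_recovery_under_noise(self):
        errs = []
        for seed in range(10):
            df = self._window_df(0.02, 3.0, n=100, noise=0.05, seed=seed)
            fits = fit_medlyn_windows(df)
            errs.append(abs(fits[0].g1 - 3.0) / 3.0)
        assert np.median(errs) < 0.10

    def test_window_below_20_obs_emits_no_fit(self):
        df = self._window_df(0.02, 2.5, n=19)
        assert fit_medlyn_windows(df) == []

    def test_predict_matches_model_in_window(self):
        df = self._window_df(0.02, 2.5)
        fits = fit_medlyn_windows(df)
        pred = medlyn_predict(fits, pd.DatetimeIndex(df["TIMESTAMP"]),
                              df["GPP"], df["VPD_CAN"])
        assert np.allclose(pred, df["GS_H2O_PM_MOL"], rtol=1e-5)


class TestO3Scaling:
    def test_stated_ratio(self):
        assert h2o_to_o3_conductance(1.0) == pytest.approx(0.61)

    def test_zero(self):
        assert h2o_to_o3_conductance(0.0) == 0.0

    def test_linearity(self):
        assert h2o_to_o3_conductance(3.0) == pytest.approx(3 * h2o_to_o3_conductance(1.0))


class TestOnSyntheticSeason:
    def test_pm_medlyn_agreement(self, noisy_analysis):
        """PM and Medlyn conductances correlate strongly when the world is
        itself Medlyn-driven."""
        df = noisy_analysis["table"]
        m = (df["VALID_PM"] & df["VALID_MED"]).to_numpy()
        a = df.loc[m, "GS_H2O_PM"].to_numpy()
        b = df.loc[m, "GS_H2O_MED"].to_numpy()
        assert m.sum() > 100
        assert np.corrcoef(a, b)[0, 1] > 0.9

    def test_retained_ratios_within_unit_interval(self, noisy_analysis):
        df = noisy_analysis["table"]
        for which in ("PM", "MED"):
            r = df.loc[df[f"VALID_{which}"], f"RATIO_{which}"]
            assert ((r >= 0) & (r <= 1)).all()

    def test_parameter_recovery_across_seasons(self, site):
        """Median Medlyn-parameter error across seeded 5%-noise seasons."""
        from ozflux.io import RunConfig
        from ozflux.pipeline import analyze
        from ozflux.synthetic import (TruthParams, gen_halfhourly_truth,
                                      gen_meteorology)
        g0_errs, g1_errs = [], []
        for seed in range(20):
            params = TruthParams(seed=100 + seed)
            met = gen_meteorology(30, params, site)
            obs, _ = gen_halfhourly_truth(met, params, site)
            res = analyze(obs, site, RunConfig(site=site))
            g1 = np.median([f.g1 for f in res["fits"]])
            g0 = np.median([f.g0 for f in res["fits"]])
            g1_errs.append(abs(g1 - params.G1_true) / params.G1_true)
            g0_errs.append(abs(g0 - params.G0_true))
        assert np.median(g1_errs) <= 0.10
        assert np.median(g0_errs) <= 0.01
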
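"""Eddy-covariance block processing: despiking, rotation, fluxes, QC."""

import numpy as np
import pytest

from ozflux import ecflux
from ozflux.ecflux import (FluxRecord, HighFrequencyBlock, block_fluxes,
                           despike, double_rotation, itc_class, qc_screen,
                           ssitc_flags, steady_state_class)
from ozflux.synthetic import gen_highfreq_block


def brute_force_mad_mask(x, k):
    """Independent global median/MAD filter for a window-sized toy list."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return np.abs(x - med) > k * mad


class TestDespike:
    def test_constant_series_removes_nothing(self):
        out, n = despike(np.full(100, 3.0))
        assert n == 0
        assert np.all(out == 3.0)

    def test_single_constructed_outlier_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 600)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        x[300] = med + 10 * mad
        out, n = despike(x, k_mad=6.0, window=600)
        assert n == 1
        assert np.isnan(out[300])

    def test_matches_brute_force_on_toy_list(self):
        x = np.array([1.0, 1.1, 0.9, 1.0, 1.2, 0.8, 1.0, 9.0, 1.1, 0.95,
                      1.05, 1.0, 0.9, 1.1, -6.0, 1.0, 1.02, 0.98, 1.0, 1.1])
        out, n = despike(x, k_mad=6.0, window=len(x))
        expected = brute_force_mad_mask(x, 6.0)
        assert np.array_equal(np.isnan(out), expected)
        assert n == expected.sum()

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            despike(np.full(10, np.nan))


class TestDoubleRotation:
    def test_aligned_flow_is_identity(self):
        u = np.array([2.0, 2.1, 1.9, 2.0])
        v = np.array([0.1, -0.1, 0.05, -0.05])
        w = np.array([0.02, -0.02, 0.01, -0.01])
        u2, v2, w2, yaw, pitch = double_rotation(u, v, w)
        assert yaw == pytest.approx(0.0, abs=1e-12)
        assert pitch == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(u2, u)

    def test_recovers_constructed_pitch(self):
        # pure 10 degree pitch tilt of a mean-wind flow
        th = np.deg2rad(10.0)
        u0 = np.array([2.0, 2.5, 1.5, 2.0, 2.2])
        u = u0 * np.cos(th)
        w = u0 * np.sin(th)
        v = np.zeros_like(u0)
        _, _, w2, yaw, pitch = double_rotation(u, v, w)
        assert np.rad2deg(pitch) == pytest.approx(10.0, abs=1e-10)
        assert abs(np.mean(w2)) < 1e-12

    def test_mean_v_and_w_are_zero_and_norm_preserved(self):
        rng = np.random.default_rng(1)
        u = 2.0 + rng.normal(0, 0.5, 1000)
        v = 0.5 + rng.normal(0, 0.4, 1000)
        w = 0.1 + rng.normal(0, 0.3, 1000)
        u2, v2, w2, _, _ = double_rotation(u, v, w)
        scale = np.mean(np.hypot(u, v))
        assert abs(np.mean(v2)) < 1e-12 * scale
        assert abs(np.mean(w2)) < 1e-12 * scale
        assert np.allclose(u2**2 + v2**2 + w2**2, u**2 + v**2 + w**2)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        u = 2.0 + rng.normal(0, 0.5, 500)
        v = 1.0 + rng.normal(0, 0.4, 500)
        w = 0.2 + rng.normal(0, 0.3, 500)
        u1, v1, w1, _, _ = double_rotation(u, v, w)
        u2, v2, w2, yaw2, pitch2 = double_rotation(u1, v1, w1)
        assert yaw2 == pytest.approx(0.0, abs=1e-12)
        assert pitch2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(u2, u1)

    def test_degenerate_zero_wind_raises(self):
        z = np.zeros(10)
        with pytest.raises(ValueError):
            double_rotation(z, z, z)


class TestBlockFluxes:
    def test_hand_covariance(self):
        blk = HighFrequencyBlock(t=np.arange(4.0),
                                 u=np.zeros(4), v=np.zeros(4),
                                 w=np.array([1.0, -1.0, 1.0, -1.0]),
                                 Ts=np.zeros(4),
                                 c_o3=np.array([2.0, 0.0, 2.0, 0.0]))
        rec = block_fluxes(blk, rho=1.2, cp=1004.0)
        assert rec.flux_o3 == pytest.approx(1.0)

    def test_ustar_from_covariances(self):
        # cov(u,w) = -0.04, cov(v,w) = 0.03 -> u* = 0.0025**0.25
        w = np.array([1.0, -1.0, 1.0, -1.0])
        u = -0.04 * w
        v = 0.03 * w
        blk = HighFrequencyBlock(t=np.arange(4.0), u=u, v=v, w=w,
                                 Ts=np.zeros(4))
        rec = block_fluxes(blk, rho=1.2, cp=1004.0)
        assert rec.ustar == pytest.approx(0.0025**0.25, rel=1e-12)
        assert rec.ustar == pytest.approx(0.2236, abs=5e-5)

    def test_ustar_invariant_under_yaw(self):
        rng = np.random.default_rng(3)
        u = rng.normal(0, 0.5, 2000)
        v = rng.normal(0, 0.4, 2000)
        w = 0.3 * u + rng.normal(0, 0.2, 2000)
        def ustar(u, v, w):
            blk = HighFrequencyBlock(t=np.arange(len(u), dtype=float),
                                     u=u, v=v, w=w, Ts=np.zeros(len(u)))
            return block_fluxes(blk, 1.2, 1004.0).ustar
        th = 0.8
        ur = u * np.cos(th) + v * np.sin(th)
        vr = -u * np.sin(th) + v * np.cos(th)
        assert ustar(ur, vr, w) == pytest.approx(ustar(u, v, w), rel=1e-10)

    def test_covariance_estimate_within_3se(self):
        blk = gen_highfreq_block(cov_ws=0.5, seed=4)
        rec = block_fluxes(blk, 1.2, 1004.0)
        n = len(blk.w)
        # SE of a sample covariance of bivariate normal
        se = np.sqrt((0.4**2 * 2.0**2 + 0.5**2) / n)
        assert abs(rec.flux_o3 - 0.5) < 3 * se

    def test_estimator_unbiased_over_seeded_blocks(self):
        ests = []
        for seed in range(200):
            blk = gen_highfreq_block(cov_ws=0.5, seed=seed, n=2000)
            ests.append(block_fluxes(blk, 1.2, 1004.0).flux_o3)
        se_mean = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 2 * se_mean


class TestSSITC:
    def test_stationary_block_class0(self):
        blk = gen_highfreq_block(cov_ws=0.5, seed=5)
        ss, _ = ssitc_flags(blk, scalar="c_o3")
        assert ss == 0

    def test_midblock_jump_class2(self):
        # coordinated opposite-sign jump at mid-block: the 30-min covariance
        # departs from the sub-block mean by far more than 100%
        rng = np.random.default_rng(6)
        n = 6000
        w = rng.normal(0, 0.4, n)
        s = 0.5 * w + rng.normal(0, 1.0, n)
        w[n // 2:] += 1.0
        s[n // 2:] -= 1.0
        assert steady_state_class(w, s) == 2

    def test_itc_at_model_value_class0(self):
        rng = np.random.default_rng(7)
        w = rng.normal(0, 1.0, 10000)
        sigw = np.std(w)
        assert itc_class(w, ustar=sigw / 1.3) == 0


class TestQcScreen:
    def _rec(self, missing=0.0, ss=0, itc=0):
        return FluxRecord(timestamp=None, flux_o3=1.0, flux_co2=1.0,
                          flux_h2o=1.0, H=1.0, lamE=1.0, ustar=0.3,
                          missing_frac=missing, ss_class=ss, itc_class=itc)

    def test_over_10pct_missing_removed_boundary_kept(self):
        kept, book = qc_screen([self._rec(0.11), self._rec(0.10)])
        assert len(kept) == 1
        assert kept[0].missing_frac == 0.10
        assert book["removed_missing"] == 1

    def test_ssitc_class2_removed(self):
        kept, book = qc_screen([self._rec(ss=2), self._rec(itc=2),
                                self._rec(ss=1, itc=1)])
        assert len(kept) == 1
        assert book["removed_ssitc"] == 2

    def test_clean_input_identity_and_accounting(self):
        recs = [self._rec() for _ in range(5)]
        kept, book = qc_screen(recs)
        assert kept == recs
        assert book["records_in"] == book["records_out"] + \
            book["removed_missing"] + book["removed_ssitc"]


class TestHighFreqGenerator:
    def test_missing_fraction_rejects_downstream(self):
        blk = gen_highfreq_block(cov_ws=0.5, missing_frac=0.2, seed=8)
        rec = block_fluxes(blk, 1.2, 1004.0)
        kept, _ = qc_screen([rec])
        assert kept == []

    def test_tilt_removed_by_double_rotation(self):
        blk = gen_highfreq_block(cov_ws=0.5, tilt_deg=10.0, seed=9)
        _, _, w2, _, pitch = double_rotation(blk.u, blk.v, blk.w)
        assert abs(np.mean(w2)) < 1e-12
        assert np.rad2deg(pitch) == pytest.approx(10.0, abs=1.0)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gen_highfreq_block(cov_ws=0.5, missing_frac=0.6)
        with pytest.raises(ValueError):
            gen_highfreq_block(cov_ws=0.5, tilt_deg=45.0)
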
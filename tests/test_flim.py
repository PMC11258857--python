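"""Decay model, 3x3 binning, pixel/cube fitting, aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import redoxscreen as rs
from redoxscreen.errors import InterfaceError
from redoxscreen.flim import FitBounds, FlimFitParams, estimate_irf_shift


def delta_irf(peak: int = 10, n_bins: int = 256) -> rs.IRF:
    counts = np.zeros(n_bins)
    counts[peak] = 1.0
    return rs.IRF(counts)


def brute_force_model(params: FlimFitParams, irf: rs.IRF, n_bins: int) -> np.ndarray:
    """Independent double-loop convolution oracle."""
    irf_c = irf.counts / irf.counts.sum()
    bw = irf.bin_width
    out = np.zeros(n_bins)
    for k in range(n_bins):
        acc = 0.0
        for j in range(k + 1):
            t = (k - j) * bw
            acc += irf_c[j] * (params.a1 * np.exp(-t / params.tau1)
                               + (1 - params.a1) * np.exp(-t / params.tau2))
        out[k] = params.amplitude * acc + params.offset
    return out


class TestModelDecay:
    def test_delta_irf_is_pure_exponential(self):
        irf = delta_irf(peak=10)
        p = FlimFitParams(tau1=800.0, tau2=3000.0, a1=1.0, amplitude=50.0)
        model = rs.model_decay(p, irf, 256)
        t = np.arange(246) * irf.bin_width
        assert np.allclose(model[10:], 50.0 * np.exp(-t / 800.0), rtol=1e-12)
        assert np.allclose(model[:10], 0.0)

    def test_zero_amplitude_is_constant_offset(self, irf):
        p = FlimFitParams(tau1=500.0, tau2=2500.0, a1=0.5,
                          amplitude=0.0, offset=5.0)
        assert np.allclose(rs.model_decay(p, irf, 256), 5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fft_matches_brute_force(self, irf, seed):
        rng = np.random.default_rng(seed)
        p = FlimFitParams(tau1=rng.uniform(100, 1200),
                          tau2=rng.uniform(1500, 6000),
                          a1=rng.uniform(0, 1),
                          amplitude=rng.uniform(1, 1e4),
                          offset=rng.uniform(0, 10))
        fft = rs.model_decay(p, irf, 256, method="fft")
        direct = rs.model_decay(p, irf, 256, method="direct")
        oracle = brute_force_model(p, irf, 256)
        scale = np.abs(oracle).max()
        assert np.abs(fft - oracle).max() / scale < 1e-9
        assert np.abs(direct - oracle).max() / scale < 1e-9

    def test_bin_mismatch_raises(self, irf):
        p = FlimFitParams(500.0, 2500.0, 0.5)
        with pytest.raises(InterfaceError):
            rs.model_decay(p, irf, 128)


class TestBin3x3:
    def test_uniform_cube_counting(self):
        cube = rs.DecayCube(np.full((6, 6, 8), 2, dtype=np.int64))
        binned = rs.bin_3x3(cube)
        assert binned.counts.shape == cube.counts.shape
        assert np.all(binned.counts[2, 2] == 18)  # interior: 9 pixels x 2
        assert np.all(binned.counts[0, 0] == 8)   # corner: 4 pixels x 2

    def test_single_pixel_spreads_to_neighborhood(self):
        counts = np.zeros((7, 7, 4), dtype=np.int64)
        counts[3, 3, :] = 5
        binned = rs.bin_3x3(rs.DecayCube(counts))
        support = binned.counts.sum(axis=2) > 0
        expect = np.zeros((7, 7), dtype=bool)
        expect[2:5, 2:5] = True
        assert np.array_equal(support, expect)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_neighborhood_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(9, 7, 5))
        binned = rs.bin_3x3(rs.DecayCube(counts))
        for r in range(9):
            for c in range(7):
                r0, r1 = max(r - 1, 0), min(r + 2, 9)
                c0, c1 = max(c - 1, 0), min(c + 2, 7)
                oracle = counts[r0:r1, c0:c1].sum(axis=(0, 1))
                assert np.array_equal(binned.counts[r, c], oracle)


class TestFitPixel:
    def test_noiseless_self_consistency(self, irf):
        true = FlimFitParams(tau1=420.0, tau2=2600.0, a1=0.65,
                             amplitude=5000.0, offset=2.0)
        data = rs.model_decay(true, irf, 256)
        init = FlimFitParams(tau1=420.0 * 1.2, tau2=2600.0 * 0.8,
                             a1=0.65 * 0.8, amplitude=5000.0 * 1.2,
                             offset=2.0)
        fit = rs.fit_pixel(data, irf, init=init)
        assert fit.valid
        assert fit.tau1 == pytest.approx(420.0, rel=1e-3)
        assert fit.tau2 == pytest.approx(2600.0, rel=1e-3)
        assert fit.a1 == pytest.approx(0.65, rel=1e-3)

    def test_pure_background_flagged(self, irf):
        fit = rs.fit_pixel(np.zeros(256), irf)
        assert not fit.valid and fit.photons == 0
        # constant nonzero background: amplitude collapses toward zero
        fit2 = rs.fit_pixel(np.full(256, 5.0), irf)
        assert fit2.amplitude < 0.05 * 5.0 * 256

    def test_monte_carlo_recovery(self, irf):
        # >=5000 photons, well-separated lifetimes: median recovery over
        # repeated noise draws lands within 10 % of the truth
        truth = rs.DecayGroundTruth(400.0, 2500.0, 0.7, photons_target=5000.0)
        cube = rs.simulate_decay_cube(truth, irf, (10, 10), seed=21)
        fits = [rs.fit_pixel(cube.counts[r, c], irf)
                for r in range(10) for c in range(10)]
        assert all(f.valid for f in fits)
        med = lambda key: float(np.median([getattr(f, key) for f in fits]))
        assert med("tau1") == pytest.approx(400.0, rel=0.10)
        assert med("tau2") == pytest.approx(2500.0, rel=0.10)
        assert med("a1") == pytest.approx(0.7, rel=0.10)

    def test_components_ordered_and_normalized(self, irf):
        fit = rs.fit_pixel(rs.model_decay(
            FlimFitParams(500.0, 2500.0, 0.6, amplitude=3000.0), irf, 256), irf)
        assert fit.tau1 <= fit.tau2
        assert fit.a1 + fit.a2 == pytest.approx(1.0, abs=1e-12)


class TestFitCube:
    def test_all_zero_cube_no_valid_pixels(self, irf):
        cube = rs.DecayCube(np.zeros((8, 8, 256), dtype=np.int64))
        res = rs.fit_cube(cube, irf)
        assert res.n_valid == 0
        assert np.isnan(res.tau_m).all()

    def test_infinite_threshold_no_valid_pixels(self, small_cube, irf):
        res = rs.fit_cube(small_cube, irf, photon_threshold=10 ** 12)
        assert res.n_valid == 0

    def test_empty_mask_warns(self, small_cube, irf):
        with pytest.warns(UserWarning, match="empty mask"):
            res = rs.fit_cube(small_cube, irf,
                              mask=np.zeros((8, 8), dtype=bool))
        assert res.status == "empty mask"

    def test_homogeneous_recovery_and_identities(self, irf):
        truth = rs.DecayGroundTruth(400.0, 2500.0, 0.7, photons_target=1500.0)
        cube = rs.simulate_decay_cube(truth, irf, (12, 12), seed=8)
        res = rs.fit_cube(cube, irf, photon_threshold=1000)
        assert res.n_valid >= 0.95 * 144
        assert np.nanmean(res.tau_m) == pytest.approx(truth.tau_m, rel=0.05)
        v = res.valid
        # tau_m identity and fraction normalization to machine precision
        assert np.allclose(res.tau_m[v],
                           res.a1[v] * res.tau1[v] + res.a2[v] * res.tau2[v],
                           rtol=0, atol=1e-9)
        assert np.allclose(res.a1[v] + res.a2[v], 1.0, atol=1e-12)
        # invalid pixels carry NaN, never zeros
        assert np.isnan(res.tau_m[~v]).all()

    def test_monoexponential_limit(self, irf):
        # a1 = 1 data: fitted tau_m approaches tau1 regardless of tau2
        truth = rs.DecayGroundTruth(700.0, 3000.0, 1.0, photons_target=3000.0)
        cube = rs.simulate_decay_cube(truth, irf, (8, 8), seed=13)
        res = rs.fit_cube(cube, irf, photon_threshold=1000)
        assert res.n_valid > 0
        assert np.nanmedian(res.tau_m) == pytest.approx(700.0, rel=0.08)

    def test_irf_shift_estimated(self, irf, decay_truth):
        cube = rs.simulate_decay_cube(decay_truth, irf, (8, 8), seed=5)
        pooled = rs.bin_3x3(cube).counts.reshape(-1, 256).sum(axis=0)
        assert estimate_irf_shift(pooled, irf) == 0
        # displaced IRF recovered to within one bin
        assert abs(estimate_irf_shift(pooled, irf.shifted(-4)) - 4) <= 1


class TestAggregateFlim:
    def _result(self, irf):
        truth = rs.DecayGroundTruth(400.0, 2500.0, 0.7, photons_target=2000.0)
        cube = rs.simulate_decay_cube(truth, irf, (10, 10), seed=30)
        return rs.fit_cube(cube, irf, photon_threshold=1000)

    def test_single_label_equals_global(self, irf):
        res = self._result(irf)
        table = rs.aggregate_flim(res, np.ones((10, 10), dtype=int))
        assert table.loc[0, "tau_m_mean"] == pytest.approx(
            float(np.nanmean(res.tau_m)))

    def test_disjoint_constant_labels(self, irf):
        res = self._result(irf)
        res.tau_m[:, :5], res.tau_m[:, 5:] = 111.0, 222.0
        labels = np.ones((10, 10), dtype=int)
        labels[:, 5:] = 2
        table = rs.aggregate_flim(res, labels).set_index("label")
        assert table.loc[1, "tau_m_mean"] == pytest.approx(111.0)
        assert table.loc[2, "tau_m_mean"] == pytest.approx(222.0)

    def test_label_weighted_mean_conserved(self, irf):
        res = self._result(irf)
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, size=(10, 10))
        table = rs.aggregate_flim(res, labels)
        weighted = (table["tau_m_mean"] * table["n_valid"]).sum() / table["n_valid"].sum()
        assert weighted == pytest.approx(float(np.nanmean(res.tau_m)))

    def test_empty_label_yields_nan_row(self, irf):
        res = self._result(irf)
        labels = np.ones((10, 10), dtype=int)
        labels[0, 0] = 7
        res.valid[0, 0] = False
        res.tau_m[0, 0] = np.nan
        table = rs.aggregate_flim(res, labels).set_index("label")
        assert np.isnan(table.loc[7, "tau_m_mean"])


@given(st.integers(0, 2 ** 16), st.floats(0.0, 1.0))
def test_tau_m_identity_property(seed, a1):
    """tau_m = a1 tau1 + a2 tau2 for any admissible parameter set."""
    rng = np.random.default_rng(seed)
    tau1 = rng.uniform(50, 1500)
    tau2 = rng.uniform(tau1, 8000)
    p = FlimFitParams(tau1, tau2, a1)
    assert p.tau_m == pytest.approx(a1 * tau1 + (1 - a1) * tau2, rel=1e-12)
    assert p.a1 + p.a2 == pytest.approx(1.0, abs=1e-15)
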
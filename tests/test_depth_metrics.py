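import numpy as np
import pytest

from deepmpm import AnalysisError, DegenerateInputError, InputError
from deepmpm.core_io import AcquisitionMeta, ImageStack, Roi
from deepmpm.depth_metrics import (
    DepthProfile,
    attenuation_signal,
    axial_resolution,
    bleaching_curve,
    depth_limit,
    fit_attenuation,
    snr_line_profile,
    snr_profile,
)
from deepmpm.synthetic import SceneConfig, default_feature_grid, make_depth_stack


def _profile(depths, snr, energy=None, n=3):
    z = np.asarray(depths, float)
    s = np.asarray(snr, float)
    return DepthProfile(
        depths_um=z,
        i_mean=s + 10.0,
        b_mean=np.full_like(z, 10.0),
        sigma_b=np.ones_like(z),
        snr=s,
        energy_nj=energy,
        order_n=n,
    )


class TestSnrProfile:
    def test_hand_arithmetic(self):
        """Plane with bright mean 40, background mean 10 and SD 3 -> SNR 10."""
        plane = np.full((4, 8), 40.0)
        # background half alternates 7/13: mean 10, population SD 3
        plane[:, 4::2] = 7.0
        plane[:, 5::2] = 13.0
        st = ImageStack(plane[None, None], "z", 1.0, 5.0)
        bg_roi = Roi.from_rect(0, 4, 4, 8, (4, 8))
        prof = snr_profile(st, 0, top_fraction=0.5, median_radius_px=0, background_roi=bg_roi)
        assert prof.i_mean[0] == pytest.approx(40.0)
        assert prof.b_mean[0] == pytest.approx(10.0)
        assert prof.sigma_b[0] == pytest.approx(3.0)
        assert prof.snr[0] == pytest.approx(10.0)

    def test_pure_background_gives_zero_snr(self):
        plane = np.tile([7.0, 13.0], (4, 4))
        st = ImageStack(plane[None, None], "z", 1.0, 5.0)
        bg_roi = Roi(np.ones((4, 8), bool))
        prof = snr_profile(st, 0, 1.0, 0, bg_roi)
        assert prof.snr[0] == pytest.approx(0.0)

    def test_zero_background_sd_degenerate(self):
        st = ImageStack(np.full((1, 1, 4, 4), 5.0), "z", 1.0, 5.0)
        with pytest.raises(DegenerateInputError):
            snr_profile(st, 0, 0.5, 0, Roi(np.ones((4, 4), bool)))

    def test_measured_snr_matches_generative_model(self):
        """Synthetic stacks: measured SNR within 10% of the analytic
        (signal - background) / sigma over seeded replicates."""
        rng = np.random.default_rng(0)
        signal, bg_level, read_sd = 200.0, 10.0, 2.0
        sigma = np.sqrt(bg_level + read_sd**2)  # shot + read noise in background
        rel_errs = []
        for _ in range(50):
            plane = np.full((40, 40), bg_level)
            plane[:, :20] += signal
            noisy = plane + np.sqrt(plane) * rng.standard_normal(plane.shape)
            noisy += read_sd * rng.standard_normal(plane.shape)
            noisy = np.clip(noisy, 0, None)
            st = ImageStack(noisy[None, None], "z", 1.0, 5.0)
            bg_roi = Roi.from_rect(0, 40, 20, 40, (40, 40))
            prof = snr_profile(st, 0, 0.4, 0, bg_roi)
            rel_errs.append(abs(prof.snr[0] - signal / sigma) / (signal / sigma))
        assert np.median(rel_errs) < 0.10


class TestSnrLineProfile:
    def test_trivial_levels(self):
        img = np.full((3, 5), 10.0)
        line = (np.zeros(5, int), np.arange(5))
        np.testing.assert_allclose(snr_line_profile(img, line, 10.0, 2.0), 0.0)
        np.testing.assert_allclose(snr_line_profile(img, line, 8.0, 2.0), 1.0)

    def test_hand_computed_path(self):
        img = np.arange(25.0).reshape(5, 5)
        line = (np.array([0, 1, 2, 3, 4]), np.array([0, 1, 2, 3, 4]))
        out = snr_line_profile(img, line, 2.0, 4.0)
        np.testing.assert_allclose(out, (np.array([0, 6, 12, 18, 24.0]) - 2.0) / 4.0)

    def test_degenerate_sigma(self):
        with pytest.raises(DegenerateInputError):
            snr_line_profile(np.ones((2, 2)), ([0], [0]), 0.0, 0.0)


class TestDepthLimit:
    def test_linear_interpolated_crossing(self):
        lim = depth_limit(_profile([0, 100, 200], [10, 5, 2]), 3.0)
        assert lim.depth_um == pytest.approx(500.0 / 3.0)
        assert lim.limited

    def test_profile_never_below_threshold(self):
        lim = depth_limit(_profile([0, 100, 200], [10, 8, 5]), 3.0)
        assert lim.depth_um == pytest.approx(200.0)
        assert not lim.limited

    def test_profile_never_detected(self):
        lim = depth_limit(_profile([0, 100], [2, 1]), 3.0)
        assert lim.depth_um is None

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            snr = np.abs(rng.normal(5, 4, size=12))
            prof = _profile(np.arange(12) * 10.0, snr)
            depths = []
            for thr in (2.0, 3.0, 5.0, 8.0):
                lim = depth_limit(prof, thr)
                depths.append(-1.0 if lim.depth_um is None else lim.depth_um)
            assert all(a >= b for a, b in zip(depths, depths[1:]))


class TestAxialResolution:
    def _stack_from_profiles(self, profiles, step=2.5):
        """Each profile becomes the z-series of one 2x2 feature patch."""
        n = len(profiles[0])
        planes = np.zeros((n, 4, 4 * len(profiles)))
        for j, prof in enumerate(profiles):
            planes[:, :2, 4 * j : 4 * j + 2] = np.asarray(prof)[:, None, None]
        st = ImageStack(planes[None], "z", 1.0, step)
        rois = [
            Roi.from_rect(0, 2, 4 * j, 4 * j + 2, planes.shape[1:], f"f{j}")
            for j in range(len(profiles))
        ]
        return st, rois

    def test_step_profile_hand_value(self):
        # 0 -> 1 step across one 2.5 um plane step at the profile end:
        # one-sided difference = 1 / 2.5 = 0.4 per um
        st, rois = self._stack_from_profiles([[0, 0, 0, 0, 1.0]])
        with pytest.warns(UserWarning):  # < 11 features
            summary = axial_resolution(st, 0, rois)
        assert summary.median == pytest.approx(0.4)

    def test_constant_profile_excluded(self):
        st, rois = self._stack_from_profiles([[0, 0, 0, 0, 1.0], [2, 2, 2, 2, 2.0]])
        with pytest.warns(UserWarning, match="flat"):
            summary = axial_resolution(st, 0, rois)
        assert summary.n_features == 1

    def test_gaussian_profile_matches_analytic_slope(self):
        """Normalised Gaussian of SD sigma_z: max |d/dz| = exp(-1/2)/sigma_z."""
        sigma_z, step = 6.0, 0.25
        z = np.arange(-30, 30 + step, step)
        prof = np.exp(-(z**2) / (2 * sigma_z**2))
        st, rois = self._stack_from_profiles([100.0 * prof], step=step)
        with pytest.warns(UserWarning):
            summary = axial_resolution(st, 0, rois)
        assert summary.median == pytest.approx(np.exp(-0.5) / sigma_z, rel=0.05)

    def test_slope_decreases_with_broader_axial_psf(self):
        medians = []
        for sigma_ax in (1.5, 3.0, 6.0):
            feats = [
                {"y_px": y, "x_px": x, "amplitude": 300.0, "sigma_um": 0.8, "z_um": 50.0}
                for y in (24, 48, 72)
                for x in (24, 48, 72)
            ]
            cfg = SceneConfig(
                seed=5,
                n_planes=41,
                z_step_um=2.5,
                psf_sigma_um=(0.35, sigma_ax),
                feature_layout=feats,
                shot_noise=False,
                read_sd=0.5,
            )
            st, _ = make_depth_stack(cfg)
            rois = [
                Roi.from_rect(f["y_px"] - 2, f["y_px"] + 3, f["x_px"] - 2, f["x_px"] + 3,
                              st.frame_shape)
                for f in feats
            ]
            with pytest.warns(UserWarning):
                summary = axial_resolution(st, 0, rois)
            medians.append(summary.median)
        assert medians[0] > medians[1] > medians[2]


class TestAttenuation:
    def test_constant_power_exponential_signal(self):
        z = np.arange(0, 400, 20.0)
        i_mean = 100.0 * np.exp(-3 * z / 200.0) + 10.0
        prof = DepthProfile(z, i_mean, np.full_like(z, 10.0), np.ones_like(z),
                            np.ones_like(z), energy_nj=np.full_like(z, 2.0), order_n=3)
        s = attenuation_signal(prof)
        np.testing.assert_allclose(s, np.exp(-z / 200.0), rtol=1e-10)

    def test_schedule_invariance(self):
        """Identical tissue under two different excitation ramps yields the
        same normalised S(z)."""
        z = np.arange(0, 400, 20.0)
        tissue = np.exp(-3 * z / 150.0)
        for ramp in (np.full_like(z, 2.0), 2.0 * np.exp(z / 300.0)):
            i_mean = 50.0 * ramp**3 * tissue + 10.0
            prof = DepthProfile(z, i_mean, np.full_like(z, 10.0), np.ones_like(z),
                                np.ones_like(z), energy_nj=ramp, order_n=3)
            s = attenuation_signal(prof)
            np.testing.assert_allclose(s, np.exp(-z / 150.0), rtol=1e-9)

    def test_equivalence_with_raw_cubic_fit(self):
        """Fitting S(z) with exp(-z/l_e) equals fitting (I-B)/P^3 with
        exp(-3 z/l_e)."""
        from scipy.optimize import curve_fit

        z = np.arange(0, 400, 20.0)
        p = 2.0 * np.exp(z / 400.0)
        i_mean = 50.0 * p**3 * np.exp(-3 * z / 180.0) + 10.0
        prof = DepthProfile(z, i_mean, np.full_like(z, 10.0), np.ones_like(z),
                            np.ones_like(z), energy_nj=p, order_n=3)
        s = attenuation_signal(prof)
        fit = fit_attenuation(z, s, order_n=3)

        raw = (i_mean - 10.0) / p**3
        (_, le_raw), _ = curve_fit(lambda zz, a, le: a * np.exp(-3 * zz / le), z, raw,
                                   p0=[raw[0], 100.0])
        assert fit.l_e_um == pytest.approx(le_raw, rel=1e-6)
        assert fit.l_e_um == pytest.approx(180.0, rel=1e-6)

    def test_noiseless_exponential_recovered_exactly(self):
        z = np.arange(0, 400, 20.0)
        fit = fit_attenuation(z, np.exp(-z / 200.0), order_n=3)
        assert fit.l_e_um == pytest.approx(200.0, rel=1e-9)

    def test_generative_stack_recovery(self):
        cfg = SceneConfig(seed=2, l_e_um=150.0, shot_noise=False, read_sd=0.5)
        st, _ = make_depth_stack(cfg)
        bg = Roi.from_rect(0, 10, 0, 10, st.frame_shape)
        prof = snr_profile(st, 0, 0.01, 1, bg)
        s = attenuation_signal(prof)
        fit = fit_attenuation(prof.depths_um, s, order_n=3)
        assert fit.l_e_um == pytest.approx(150.0, rel=0.02)

    def test_two_layer_recovery_within_ten_percent(self):
        cfg = SceneConfig(
            seed=3,
            l_e_um=[300.0, 80.0],
            layer_boundaries_um=[200.0],
            shot_noise=False,
            read_sd=0.5,
            n_planes=40,
            z_step_um=10.0,
        )
        st, _ = make_depth_stack(cfg)
        bg = Roi.from_rect(0, 10, 0, 10, st.frame_shape)
        prof = snr_profile(st, 0, 0.01, 1, bg)
        s = attenuation_signal(prof)
        top = fit_attenuation(prof.depths_um, s, fit_window_um=(0, 200), order_n=3)
        deep = fit_attenuation(prof.depths_um, s, fit_window_um=(200, 390), order_n=3)
        assert top.l_e_um == pytest.approx(300.0, rel=0.10)
        assert deep.l_e_um == pytest.approx(80.0, rel=0.10)

    def test_masked_points_below_background(self):
        z = np.arange(0, 100, 10.0)
        i_mean = np.full_like(z, 5.0)
        i_mean[:5] = 50.0
        prof = DepthProfile(z, i_mean, np.full_like(z, 10.0), np.ones_like(z),
                            np.ones_like(z), energy_nj=np.ones_like(z), order_n=3)
        with pytest.warns(UserWarning, match="masked"):
            s = attenuation_signal(prof)
        assert np.isnan(s[5:]).all()


class TestBleaching:
    def _movie(self, scale_series, cell_val=200.0, bg=5.0):
        frames = []
        for c in scale_series:
            img = np.full((32, 32), bg)
            img[8:24, 8:24] = bg + cell_val * c
            frames.append(img)
        return ImageStack(np.stack(frames)[None], "t", 1.0, 1.0)

    def test_constant_movie_zero_decline(self):
        movie = self._movie(np.ones(5))
        roi = Roi(np.ones((32, 32), bool))
        dark = Roi.from_rect(0, 4, 0, 4, (32, 32))
        curve = bleaching_curve(movie, 0, roi, dark, threshold_method="huang")
        np.testing.assert_allclose(curve.percent_decline, 0.0, atol=1e-9)

    def test_mono_exponential_fade_25_percent_at_scan_25(self):
        k = np.arange(26)
        scale = np.exp(-k * np.log(4.0 / 3.0) / 25.0)  # exactly 0.75 at k=25
        movie = self._movie(scale)
        roi = Roi(np.ones((32, 32), bool))
        dark = Roi.from_rect(0, 4, 0, 4, (32, 32))
        curve = bleaching_curve(movie, 0, roi, dark, threshold_method="huang")
        assert curve.decline_at(25) == pytest.approx(25.0, abs=0.5)

    def test_intensity_scale_invariance(self):
        scale = np.linspace(1.0, 0.6, 8)
        roi = Roi(np.ones((32, 32), bool))
        dark = Roi.from_rect(0, 4, 0, 4, (32, 32))
        m1 = self._movie(scale)
        m2 = m1.with_pixels(2.0 * m1.pixels)
        c1 = bleaching_curve(m1, 0, roi, dark)
        c2 = bleaching_curve(m2, 0, roi, dark)
        np.testing.assert_allclose(c1.percent_decline, c2.percent_decline, atol=1e-6)

    def test_needs_two_time_points(self):
        movie = self._movie([1.0])
        roi = Roi(np.ones((32, 32), bool))
        with pytest.raises(InputError):
            bleaching_curve(movie, 0, roi, roi)
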
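import numpy as np
import pytest

import lockinsim as L
from lockinsim import PatternNotDetectedError, ReconSettings
from lockinsim.reconstruct import separate_bands, shift_band

EQUISPACED = np.deg2rad([0.0, 120.0, 240.0])


class TestSeparateBands:
    def test_round_trip_from_known_bands(self):
        """Frames built from known bands are separated back exactly."""
        rng = np.random.default_rng(3)
        shape = (32, 32)
        b = rng.normal(size=(3, *shape)) + 1j * rng.normal(size=(3, *shape))
        b[0] = np.conj(b[2])  # -1 order mirrors +1 for real images
        M = np.exp(1j * np.outer(EQUISPACED, np.array([-1, 0, 1])))
        fts = np.tensordot(M, b, axes=(1, 0))
        frames = np.fft.ifft2(fts).real
        rec = separate_bands(frames, EQUISPACED)
        # compare through the mixing model (frames were made real, which
        # symmetrises the bands); reconstruct the frame spectra instead
        fts_rec = np.tensordot(M, rec, axes=(1, 0))
        np.testing.assert_allclose(fts_rec, np.fft.fft2(frames), atol=1e-8)

    def test_zero_modulation_gives_empty_first_orders(self, opt128):
        illum = L.default_illumination(opt128)
        illum.m[:] = 0.0
        scene = L.make_scene("crossed_filaments", {"n": 6}, seed=2, shape=(128, 128))
        raw, _ = L.render_sim_raw(scene, L.SimulationRecipe(optical=opt128, illum=illum))
        bands = separate_bands(raw.plane()[0], illum.phases[0])
        e1 = np.sum(np.abs(bands[2]) ** 2)
        e0 = np.sum(np.abs(bands[1]) ** 2)
        assert e1 < 1e-10 * e0

    def test_zeroth_band_is_phase_mean_spectrum(self, filament_sim, illum128):
        _, raw, _ = filament_sim
        bands = separate_bands(raw.plane()[0], illum128.phases[0])
        np.testing.assert_allclose(
            bands[1], np.fft.fft2(raw.plane()[0].mean(axis=0)), atol=1e-8
        )


class TestShiftBand:
    def test_zero_shift_is_identity_on_padded_grid(self):
        rng = np.random.default_rng(4)
        band = np.fft.fft2(rng.random((32, 32)))
        out = shift_band(band, np.array([0.0, 0.0]), upsample=1)
        np.testing.assert_allclose(out, band, atol=1e-12)

    def test_shift_then_inverse_shift_restores(self):
        rng = np.random.default_rng(5)
        band = np.fft.fft2(rng.random((32, 32)))
        s = np.array([0.123, -0.077])
        out = shift_band(shift_band(band, s, upsample=1), -s, upsample=1)
        rms = np.sqrt(np.mean(np.abs(out - band) ** 2))
        assert rms < 1e-10 * np.sqrt(np.mean(np.abs(band) ** 2))

    def test_delta_peak_lands_at_shifted_frequency(self):
        n, u = 64, 2
        kp = np.array([6 / n, 10 / n])  # existing peak
        yy, xx = np.mgrid[0:n, 0:n]
        field = np.exp(2j * np.pi * (kp[0] * yy + kp[1] * xx))
        band = np.fft.fft2(field)
        k0 = np.array([0.11, 0.04])
        out = shift_band(band, k0, upsample=u)
        iy, ix = np.unravel_index(np.argmax(np.abs(out)), out.shape)
        f = np.fft.fftfreq(n * u, d=1.0 / u)
        target = kp + k0
        assert abs(f[iy] - target[0]) <= 1.0 / n
        assert abs(f[ix] - target[1]) <= 1.0 / n

    def test_shift_beyond_padded_nyquist_rejected(self):
        band = np.zeros((32, 32), dtype=complex)
        with pytest.raises(ValueError, match="Nyquist"):
            shift_band(band, np.array([0.4, 0.0]), upsample=1, k_extent=0.3)


class TestWienerCombine:
    def test_single_zero_order_band_reduces_to_wiener_deconvolution(self, opt128, filament_sim):
        _, raw, wf = filament_sim
        spec = np.fft.fft2(wf)
        settings = ReconSettings(apodization="none", upsample=1)
        sr = L.wiener_combine(
            [(spec, 0, np.array([0.0, 0.0]), 1.0)], opt128, settings
        )
        expected = opt128.otf * spec / (opt128.otf**2 + settings.wiener_w**2)
        np.testing.assert_allclose(sr, expected, atol=1e-8)

    def test_support_bounded_by_extended_cutoff(self, opt256, illum256, bead_sim):
        """The apodized SR spectrum is exactly zero outside k_cutoff+|k0|."""
        _, raw, _ = bead_sim
        plane = raw.plane()
        settings = ReconSettings()
        shifted = []
        for d in range(3):
            orders = separate_bands(plane[d], illum256.phases[d])
            for i, n in enumerate((-1, 0, 1)):
                spec = shift_band(orders[i], -n * illum256.k0[d], upsample=2,
                                  k_extent=opt256.k_cutoff)
                shifted.append((spec, n, illum256.k0[d], float(illum256.m[d])))
        sr_spec = L.wiener_combine(shifted, opt256, settings)
        ky = np.fft.fftfreq(512, d=0.5)[:, None]
        kx = np.fft.fftfreq(512, d=0.5)[None, :]
        kmax = opt256.k_cutoff + np.hypot(*illum256.k0.T).max()
        outside = np.hypot(ky, kx) > kmax
        assert np.all(sr_spec[outside] == 0)


class TestFullReconstruction:
    def test_bead_fwhm_shrinks_vs_widefield(self, opt256, illum256, bead_sim):
        scene, raw, wf = bead_sim
        res = L.reconstruct_wiener(
            raw, opt256, params=illum256, settings=ReconSettings(apodization="none")
        )
        c = np.array(scene.params["centers"][0])
        f_wf = L.fwhm(wf, tuple(c), 0.0, 65.0)
        f_sr = L.fwhm(res.sr_image, tuple(2 * c), 0.0, res.pixel_nm)
        assert f_sr <= 0.62 * f_wf

    def test_nine_frames_required(self, opt128):
        bad = L.SIMRawStack(np.zeros((1, 1, 1, 3, 5, 128, 128)), optical=opt128)
        with pytest.raises(ValueError, match="9 frames"):
            L.reconstruct_wiener(bad, opt128)

    def test_unmodulated_stack_raises_not_degrades(self, opt128):
        illum = L.default_illumination(opt128)
        illum.m[:] = 0.0
        scene = L.make_scene("crossed_filaments", {"n": 6}, seed=2, shape=(128, 128))
        raw, _ = L.render_sim_raw(scene, L.SimulationRecipe(optical=opt128, illum=illum))
        with pytest.raises(PatternNotDetectedError):
            L.reconstruct_wiener(raw, opt128)

    def test_deterministic_given_seeded_input(self, opt128, illum128, filament_sim):
        _, raw, _ = filament_sim
        a = L.reconstruct_wiener(raw, opt128, params=illum128)
        b = L.reconstruct_wiener(raw, opt128, params=illum128)
        assert np.array_equal(a.sr_image, b.sr_image)

    def test_linearity_of_engine(self, opt128, illum128, filament_sim):
        _, raw, _ = filament_sim
        scaled = L.SIMRawStack(3.0 * raw.data, optical=opt128)
        a = L.reconstruct_wiener(raw, opt128, params=illum128)
        b = L.reconstruct_wiener(scaled, opt128, params=illum128)
        np.testing.assert_allclose(b.sr_image, 3.0 * a.sr_image, rtol=1e-8, atol=1e-10)

    def test_lockin_agrees_with_wiener_absent_background(self, opt128, illum128, filament_sim):
        """With no background to remove, the OTF-equalised lock-in path
        reproduces the plain Wiener result on structure pixels (the default
        estimator deliberately trades part of the unmodulated in-focus
        component for stronger suppression, so it is compared separately)."""
        _, raw, wf = filament_sim
        from lockinsim.lockin import LockinSettings

        rw = L.reconstruct_wiener(raw, opt128, params=illum128)
        settings = ReconSettings(lockin=LockinSettings(equalize_otf=True))
        rl = L.reconstruct_lockin(raw, opt128, params=illum128, settings=settings)
        mask = np.kron(wf > 0.1 * wf.max(), np.ones((2, 2), dtype=bool))
        r = np.corrcoef(rw.sr_image[mask], rl.sr_image[mask])[0, 1]
        assert r > 0.95
        rl_def = L.reconstruct_lockin(raw, opt128, params=illum128)
        r_def = np.corrcoef(rw.sr_image[mask], rl_def.sr_image[mask])[0, 1]
        assert r_def > 0.9

    def test_lockin_improves_sbr_under_background(self, opt128, illum128, filament_sim):
        _, raw, wf = filament_sim
        stack = L.inject_background(raw, wf, 1.0, optical=opt128)
        rw = L.reconstruct_wiener(stack, opt128, params=illum128)
        rl = L.reconstruct_lockin(stack, opt128, params=illum128)
        mask = np.kron(wf > 0.1 * wf.max(), np.ones((2, 2), dtype=bool))
        assert L.sbr(rl.sr_image, mask=mask).sbr_db > L.sbr(rw.sr_image, mask=mask).sbr_db

    def test_background_only_stack_reconstructs_to_near_zero(self, opt128, illum128):
        """Scene empty, background > 0: lock-in output collapses while the
        plain Wiener image keeps the haze."""
        from lockinsim.lockin import LockinSettings

        empty = L.make_scene("crossed_filaments", {"n": 0}, seed=0, shape=(128, 128))
        donor = L.make_scene("crossed_filaments", {"n": 6}, seed=2, shape=(128, 128))
        _, wf = L.render_sim_raw(donor, L.SimulationRecipe(optical=opt128, illum=illum128))
        raw, _ = L.render_sim_raw(empty, L.SimulationRecipe(optical=opt128, illum=illum128))
        stack = L.inject_background(raw, wf, 1.0, optical=opt128)
        rw = L.reconstruct_wiener(stack, opt128, params=illum128)
        # no smoothing: a perfectly phase-uniform input is pure DC and the
        # unsmoothed estimate captures it exactly
        settings = ReconSettings(lockin=LockinSettings(sigma_px=0))
        rl = L.reconstruct_lockin(stack, opt128, params=illum128, settings=settings)
        assert np.percentile(rl.sr_image, 99) < 0.05 * np.percentile(rw.sr_image, 99)

    def test_resolution_extension_in_spectrum(self, opt256, illum256, bead_sim):
        """The SR spectrum carries real energy beyond the widefield cutoff."""
        _, raw, wf = bead_sim
        res = L.reconstruct_lockin(raw, opt256, params=illum256)
        rs_sr = L.radial_spectrum(res.sr_image)
        rs_wf = L.radial_spectrum(wf)
        kc = opt256.k_cutoff
        u = res.settings.upsample
        sel = (rs_sr.k * u > kc * 1.05) & (rs_sr.k * u < kc + np.hypot(*illum256.k0[0]))
        # > 10x the noise floor in amplitude, i.e. +1 in log10
        assert np.nanmean(rs_sr.log_amplitude[sel]) > rs_sr.noise_floor + 1.0
        assert rs_sr.cutoff * u > rs_wf.cutoff


class TestProcessStack:
    def test_single_plane_matches_direct_call(self, opt128, illum128, filament_sim):
        _, raw, _ = filament_sim
        stack, prov = L.process_stack(raw, opt128, mode="wiener")
        direct = L.reconstruct_wiener(raw, opt128, params=L.estimate_parameters(raw.plane(), opt128))
        np.testing.assert_allclose(stack[0, 0, 0], direct.sr_image, atol=1e-10)

    def test_mean_match_equalises_plane_means(self, opt128, illum128):
        scene = L.make_scene("crossed_filaments", {"n": 6}, seed=2, shape=(128, 128))
        frames = []
        for gain in (1.0, 2.0, 4.0):
            raw, _ = L.render_sim_raw(scene, L.SimulationRecipe(optical=opt128, illum=illum128))
            frames.append(gain * raw.data[0, 0, 0])
        data = np.stack(frames)[None, None]  # (c=1, t=1, z=3, a, p, y, x)
        stack = L.SIMRawStack(data, optical=opt128)
        out, _ = L.process_stack(
            stack, opt128, mode="wiener",
            settings=L.ReconSettings(intensity_correction="mean_match"),
        )
        means = out[0, 0].mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=1e-6)

    def test_two_plane_volume_sectioning(self, opt128, illum128):
        scene3 = L.make_scene(
            "volume_filaments",
            {"n_planes": 2, "n_per_plane": 5, "z_step_um": 1.8},
            seed=4, shape=(128, 128),
        )
        recipe = L.SimulationRecipe(optical=opt128, illum=illum128, seed=4)
        vol = L.render_volume_stack(scene3, recipe, [0.0, 1.8])
        for i, (stack, z) in enumerate(vol):
            res = L.reconstruct_lockin(stack, opt128, params=illum128)
            up = np.kron(scene3.truth[i] > 0.3, np.ones((2, 2), dtype=bool))
            other = np.kron(scene3.truth[1 - i] > 0.3, np.ones((2, 2), dtype=bool)) & ~up
            ratio = res.sr_image[up].mean() / max(res.sr_image[other].mean(), 1e-12)
            assert ratio > 3.0


class TestEngineOracle:
    def test_pipeline_matches_direct_dft_reference(self, opt64):
        """FFT engine vs literal direct-DFT reimplementation on 64x64."""
        from reference_engine import reference_reconstruct

        illum = L.default_illumination(opt64, m=0.9)
        scene = L.make_scene("crossed_filaments", {"n": 4}, seed=6, shape=(64, 64))
        raw, _ = L.render_sim_raw(scene, L.SimulationRecipe(optical=opt64, illum=illum))
        fast = L.reconstruct_wiener(raw, opt64, params=illum).sr_image
        slow = reference_reconstruct(raw.plane(), illum, opt64)
        rms = np.sqrt(np.mean((fast - slow) ** 2))
        assert rms <= 1e-6 * max(1.0, np.sqrt(np.mean(slow**2)))
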
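"""Optoacoustic reconstruction: filtering, motion rejection, back-projection,
fluence correction and display enhancement."""

import numpy as np
import pytest
from scipy.special import i0

from tropus.containers import ReconImage, SignalSet
from tropus.geometry import full_scale_config, make_ring_geometry
from tropus.msot import (
    MotionRejectionError,
    backproject_dual_sos,
    bandpass,
    bessel_fluence,
    correct_fluence,
    enhance_and_composite,
    reconstruct_stack,
    reject_motion_frames,
)
from tropus.phantoms import Phantom, STUDY_GROUPS, WATER_SOS, generate_phantom
from tropus.simulate import simulate_optoacoustic
from tropus.spectra import CHROMOPHORES, default_spectra


def _tone_set(freq, fs=40e6, n=2030, n_el=4):
    geometry = make_ring_geometry(n_el, 40.0)
    config = full_scale_config(n_samples=n)
    t = np.arange(n) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (1, n_el, 1))
    return SignalSet(mode="msot", data=data, config=config, geometry=geometry, wavelength_nm=800.0)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        s = bandpass(_tone_set(3e6))
        mid = slice(500, 1500)
        assert np.abs(s.data[0, 0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        s = _tone_set(3e6)
        s.data = s.data * 0 + 1.0
        out = bandpass(s)
        assert np.abs(out.data.mean()) < 1e-3

    def test_out_of_band_attenuated_20db(self):
        s = bandpass(_tone_set(10e6))
        mid = slice(500, 1500)
        assert np.abs(s.data[0, 0, mid]).max() < 10 ** (-20 / 20)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(_tone_set(3e6), low=0.1e6, high=30e6)


class TestMotionRejection:
    def test_identical_frames_all_kept(self, rng):
        geometry = make_ring_geometry(4, 40.0)
        config = full_scale_config(n_samples=64)
        frame = rng.standard_normal((1, 4, 64))
        s = SignalSet(
            mode="msot", data=np.repeat(frame, 5, axis=0), config=config,
            geometry=geometry, wavelength_nm=800.0,
        )
        kept, rejected = reject_motion_frames(s)
        assert len(kept) == 5 and len(rejected) == 0

    def test_labeled_corruption_rejected_exactly(self, setup_small):
        geometry, config, grid = setup_small
        ph = generate_phantom(STUDY_GROUPS["exvivo_control"], 0, seed=2, grid=grid)
        frames, corrupted = simulate_optoacoustic(
            ph, geometry, config, n_repeats=20, motion_fraction=0.1, seed=13
        )
        s = bandpass(frames[800.0])
        kept, rejected = reject_motion_frames(s)
        np.testing.assert_array_equal(np.sort(rejected), np.nonzero(corrupted)[0])
        assert len(kept) + len(rejected) == 20

    def test_all_rejected_is_explicit_error(self, rng):
        geometry = make_ring_geometry(4, 40.0)
        config = full_scale_config(n_samples=64)
        s = SignalSet(
            mode="msot", data=rng.standard_normal((4, 4, 64)), config=config,
            geometry=geometry, wavelength_nm=800.0,
        )
        with pytest.raises(MotionRejectionError, match="threshold"):
            reject_motion_frames(s, threshold=1.1)


class TestBackprojection:
    def _point_phantom(self, grid, body, iy, ix):
        conc = np.zeros((len(CHROMOPHORES), *grid.shape))
        conc[CHROMOPHORES.index("hb"), iy, ix] = 1.0
        return Phantom(
            grid=grid, sos_map=np.full(grid.shape, WATER_SOS),
            concentration_maps=conc, scatterers=np.zeros((0, 3)),
            body_mask=body, liver_mask=np.zeros(grid.shape, dtype=bool),
        )

    def test_homogeneous_point_localization(self, setup128):
        geometry, config, grid = setup128
        body = np.zeros(grid.shape, dtype=bool)
        iy, ix = 40, 55
        body[iy - 3 : iy + 4, ix - 3 : ix + 4] = True
        ph = self._point_phantom(grid, body, iy, ix)
        frames, _ = simulate_optoacoustic(
            ph, geometry, config, n_repeats=1, noise_sd=0.0, c_tissue=WATER_SOS,
        )
        s = bandpass(frames[800.0])
        img = backproject_dual_sos(s, body, WATER_SOS, WATER_SOS, grid)
        py, px = np.unravel_index(np.argmax(np.abs(img.pixels)), img.pixels.shape)
        assert np.hypot(py - iy, px - ix) <= 1.0

    def test_dual_sos_mask_misspecification(self, setup128):
        geometry, config, grid = setup128
        xx, yy = grid.meshgrid()
        body = xx**2 + yy**2 <= 15.0**2
        iy = ix = grid.ny // 2
        ph = self._point_phantom(grid, body, iy, ix)
        ph.sos_map[body] = 1400.0
        frames, _ = simulate_optoacoustic(
            ph, geometry, config, n_repeats=1, noise_sd=0.0, c_tissue=1400.0
        )
        s = bandpass(frames[800.0])
        good = backproject_dual_sos(s, body, WATER_SOS, 1400.0, grid)
        bad = backproject_dual_sos(s, body, WATER_SOS, WATER_SOS, grid)
        py, px = np.unravel_index(np.argmax(np.abs(good.pixels)), good.pixels.shape)
        assert np.hypot(py - iy, px - ix) <= 1.0
        py, px = np.unravel_index(np.argmax(np.abs(bad.pixels)), bad.pixels.shape)
        assert np.hypot(py - iy, px - ix) >= 2.0

    def test_linearity_through_bandpass_and_bp(self, setup_small, rng):
        geometry, config, grid = setup_small
        body = np.zeros(grid.shape, dtype=bool)
        body[20:30, 20:30] = True
        data = rng.standard_normal((1, geometry.n_elements, config.n_samples))
        s = SignalSet(mode="msot", data=data, config=config, geometry=geometry, wavelength_nm=800.0)
        s3 = SignalSet(mode="msot", data=3.0 * data, config=config, geometry=geometry, wavelength_nm=800.0)
        img1 = backproject_dual_sos(bandpass(s), body, WATER_SOS, 1540.0, grid)
        img3 = backproject_dual_sos(bandpass(s3), body, WATER_SOS, 1540.0, grid)
        np.testing.assert_allclose(img3.pixels, 3.0 * img1.pixels, rtol=1e-9, atol=1e-12)

    def test_sos_out_of_range_rejected(self, setup_small):
        geometry, config, grid = setup_small
        body = np.zeros(grid.shape, dtype=bool)
        body[10:20, 10:20] = True
        data = np.zeros((1, geometry.n_elements, config.n_samples))
        s = SignalSet(mode="msot", data=data, config=config, geometry=geometry, wavelength_nm=800.0)
        with pytest.raises(ValueError, match="plausible"):
            backproject_dual_sos(s, body, 1200.0, 1540.0, grid)


class TestFluence:
    def _disc(self, grid, r=15.0):
        xx, yy = grid.meshgrid()
        return xx**2 + yy**2 <= r**2

    def test_zero_attenuation_limit_is_identity(self, setup128):
        _, _, grid = setup128
        body = self._disc(grid)
        img = ReconImage(pixels=np.ones(grid.shape), pixel_size=grid.pixel_size, origin=grid.origin)
        out = correct_fluence(img, body, mu_eff=1e-9)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-6)

    def test_center_correction_factor(self, setup128):
        _, _, grid = setup128
        body = self._disc(grid)
        mu = 0.2
        phi = bessel_fluence(body, grid, mu)
        R = np.sqrt(body.sum() * grid.pixel_size**2 / np.pi)
        # nearest pixel centre sits ~0.35 mm from the exact centroid
        assert phi[grid.ny // 2, grid.nx // 2] == pytest.approx(1.0 / i0(mu * R), rel=3e-3)

    def test_model_consistency_uniform_absorber(self, setup128):
        _, _, grid = setup128
        body = self._disc(grid)
        phi = bessel_fluence(body, grid, 0.15)
        img = ReconImage(pixels=body * phi, pixel_size=grid.pixel_size, origin=grid.origin)
        out = correct_fluence(img, body, 0.15)
        vals = out.pixels[body]
        assert vals.std() / vals.mean() < 0.05

    def test_sign_preserved_in_mask(self, setup128, rng):
        _, _, grid = setup128
        body = self._disc(grid)
        px = rng.standard_normal(grid.shape)
        img = ReconImage(pixels=px, pixel_size=grid.pixel_size, origin=grid.origin)
        out = correct_fluence(img, body, 0.3)
        assert np.all(np.sign(out.pixels[body]) == np.sign(px[body]))
        np.testing.assert_array_equal(out.pixels[~body], px[~body])

    def test_degenerate_mask_rejected(self, setup128):
        _, _, grid = setup128
        body = np.zeros(grid.shape, dtype=bool)
        body[0, :5] = True
        img = ReconImage(pixels=np.zeros(grid.shape), pixel_size=grid.pixel_size)
        with pytest.raises(ValueError, match="mask"):
            correct_fluence(img, body, 0.15)


class TestEnhanceComposite:
    def test_constant_image_has_zero_vesselness(self, setup128):
        _, _, grid = setup128
        xx, yy = grid.meshgrid()
        body = xx**2 + yy**2 <= 15.0**2
        img = ReconImage(pixels=np.ones(grid.shape), pixel_size=grid.pixel_size, origin=grid.origin)
        from skimage.filters import frangi

        assert frangi(img.pixels, sigmas=[1.0], black_ridges=False).max() == 0

    def test_vessel_disks_detected(self, setup128):
        _, _, grid = setup128
        xx, yy = grid.meshgrid()
        body = xx**2 + yy**2 <= 18.0**2
        centers = [(-6.0, 2.0), (5.0, 6.0), (2.0, -8.0)]
        px = np.zeros(grid.shape)
        px[body] = 0.2
        for cx, cy in centers:
            px[(xx - cx) ** 2 + (yy - cy) ** 2 <= 0.8**2] = 1.0
        img = ReconImage(pixels=px, pixel_size=grid.pixel_size, origin=grid.origin)
        comp = enhance_and_composite(img, body)
        # the three dominant composite maxima sit on the vessel disks
        work = comp.pixels.copy()
        found = []
        for _ in range(3):
            iy, ix = np.unravel_index(np.argmax(work), work.shape)
            found.append((grid.origin[0] + ix * grid.pixel_size, grid.origin[1] + iy * grid.pixel_size))
            work[max(iy - 4, 0) : iy + 5, max(ix - 4, 0) : ix + 5] = -np.inf
        for fx, fy in found:
            dist = min(np.hypot(fx - cx, fy - cy) for cx, cy in centers)
            assert dist <= 2 * grid.pixel_size + 0.8

    def test_background_exactly_zero(self, setup128, rng):
        _, _, grid = setup128
        xx, yy = grid.meshgrid()
        body = xx**2 + yy**2 <= 15.0**2
        img = ReconImage(pixels=rng.random(grid.shape), pixel_size=grid.pixel_size, origin=grid.origin)
        comp = enhance_and_composite(img, body)
        assert np.all(comp.pixels[~body] == 0)


class TestReconstructStack:
    def test_stack_axis_and_missing_wavelength(self, setup_small):
        geometry, config, grid = setup_small
        ph = generate_phantom(STUDY_GROUPS["exvivo_control"], 0, seed=2, grid=grid)
        frames, _ = simulate_optoacoustic(ph, geometry, config, n_repeats=1, noise_sd=0.0)
        stack = reconstruct_stack(frames, ph.body_mask, grid)
        assert stack.images.shape[0] == 11
        partial = {k: v for k, v in frames.items() if k != 920.0}
        with pytest.raises(ValueError, match="920"):
            reconstruct_stack(partial, ph.body_mask, grid)

    def test_lipid_inclusion_spectrum_cosine(self, setup128):
        geometry, config, grid = setup128
        xx, yy = grid.meshgrid()
        body = xx**2 + yy**2 <= 12.0**2
        inc = (xx - 3.0) ** 2 + (yy + 2.0) ** 2 <= 2.0**2
        conc = np.zeros((len(CHROMOPHORES), *grid.shape))
        conc[CHROMOPHORES.index("lipid")][inc] = 1.0
        ph = Phantom(
            grid=grid, sos_map=np.full(grid.shape, WATER_SOS), concentration_maps=conc,
            scatterers=np.zeros((0, 3)), body_mask=body, liver_mask=inc,
        )
        frames, _ = simulate_optoacoustic(
            ph, geometry, config, n_repeats=1, noise_sd=0.0, c_tissue=WATER_SOS
        )
        stack = reconstruct_stack(frames, body, grid, c_tissue=WATER_SOS)
        lipid = default_spectra().resample(stack.wavelengths)[:, CHROMOPHORES.index("lipid")]
        spec = stack.images[:, inc].mean(axis=1)
        cos = spec @ lipid / (np.linalg.norm(spec) * np.linalg.norm(lipid))
        assert cos > 0.99
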
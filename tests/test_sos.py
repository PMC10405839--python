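"""Transmission tomography: references, TOF picking, travel-time inversion
and waveform-inversion refinement."""

import numpy as np
import pytest

from tropus.containers import Grid, SignalSet
from tropus.phantoms import Phantom, WATER_SOS
from tropus.sos import (
    WaveformModel,
    acquire_reference,
    estimate_tof,
    forward_waveforms,
    fwi_reconstruct,
    initial_sos_from_tof,
    sos_image,
    SlownessGrid,
)
from tropus.simulate import simulate_sta
from tropus.spectra import CHROMOPHORES


@pytest.fixture(scope="module")
def reference(setup128):
    geometry, config, _ = setup128
    return acquire_reference(geometry, config)


def _synthesize(reference, shifts=0.0, amps2=None, dtau=0.0):
    """STA block whose opposite-arc traces are shifted reference wavelets."""
    cfg = reference.config
    n = reference.geometry.n_elements
    t = cfg.times
    data = np.zeros((n, n, cfg.n_samples))
    shifts = np.broadcast_to(np.asarray(shifts, dtype=float), (reference.n_pairs,))
    for i, (tx, rx) in enumerate(reference.pairs):
        tr = reference.pulse(t - reference.tof[i] - shifts[i])
        if amps2:
            tr = tr + amps2 * reference.pulse(t - reference.tof[i] - shifts[i] - dtau)
        data[tx, rx] = reference.amplitude[i] * tr
    return SignalSet(mode="sta", data=data, config=cfg, geometry=reference.geometry)


class TestReference:
    def test_diametric_water_tof(self, reference):
        d = np.linalg.norm(
            reference.geometry.element_positions[0]
            - reference.geometry.element_positions[64]
        )
        assert d == pytest.approx(80.0)
        i = np.nonzero((reference.pairs[:, 0] == 0) & (reference.pairs[:, 1] == 64))[0][0]
        assert reference.tof[i] == pytest.approx(80.0e-3 / 1523.0, rel=1e-12)
        assert reference.tof[i] * 1e6 == pytest.approx(52.53, abs=0.01)

    def test_opposite_arc_coverage(self, reference, setup128):
        geometry, _, _ = setup128
        assert reference.n_pairs == geometry.n_elements * 43
        counts = np.bincount(reference.pairs[:, 0])
        assert np.all(counts == 43)

    def test_amplitude_decreases_with_distance(self, reference):
        pos = reference.geometry.element_positions
        d = np.linalg.norm(pos[reference.pairs[:, 0]] - pos[reference.pairs[:, 1]], axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(reference.amplitude[order]) <= 1e-12)


class TestEstimateTof:
    def test_subsample_shift_accuracy(self, reference):
        shift = 1.25 * reference.config.dt
        tofm = estimate_tof(_synthesize(reference, shifts=shift), reference)
        assert tofm.validity.all()
        err = (tofm.tof - (reference.tof + shift)) / reference.config.dt
        assert np.abs(err).max() < 0.05

    def test_zero_shift_recovers_reference(self, reference):
        tofm = estimate_tof(_synthesize(reference), reference)
        err = (tofm.tof - reference.tof) / reference.config.dt
        assert np.abs(err).max() < 0.05

    def test_overlapping_double_arrival_picks_first(self, reference):
        dtau = 2.0 / reference.config.center_frequency
        tofm = estimate_tof(_synthesize(reference, amps2=0.8, dtau=dtau), reference)
        err = (tofm.tof[tofm.validity] - reference.tof[tofm.validity]) / reference.config.dt
        # first arrival, not the energy-weighted mean (which would sit
        # ~0.44 * dtau = 3.5 samples late)
        assert np.abs(err).max() < 0.3

    def test_all_zero_trace_marked_invalid(self, reference):
        s = _synthesize(reference)
        s.data[reference.pairs[0, 0], reference.pairs[0, 1]] = 0.0
        tofm = estimate_tof(s, reference)
        assert not tofm.validity[0]
        assert tofm.validity[1:].all()


class TestTravelTimeInversion:
    def test_null_data_gives_water(self, reference, setup128):
        _, config, grid = setup128
        tofm = estimate_tof(_synthesize(reference), reference)
        init = initial_sos_from_tof(tofm, reference.geometry, grid, config.water_sos)
        np.testing.assert_allclose(init.sos, config.water_sos, atol=0.5)

    def test_disc_inclusion_recovery_within_2pct(self, setup128, reference):
        geometry, config, grid = setup128
        xx, yy = grid.meshgrid()
        disc = xx**2 + yy**2 <= 10.0**2
        sos = np.full(grid.shape, WATER_SOS)
        sos[disc] = 1495.0
        ph = Phantom(
            grid=grid, sos_map=sos,
            concentration_maps=np.zeros((len(CHROMOPHORES), *grid.shape)),
            scatterers=np.zeros((0, 3)), body_mask=disc,
            liver_mask=np.zeros(grid.shape, dtype=bool),
        )
        sta = simulate_sta(ph, geometry, config, noise_sd=0.0)
        tofm = estimate_tof(sta, reference)
        init = initial_sos_from_tof(tofm, geometry, grid, WATER_SOS, support=disc)
        est = init.sos[disc].mean()
        assert abs(est - 1495.0) / 1495.0 < 0.02

    def test_adjoint_identity(self, reference, setup128, rng):
        from tropus._rays import build_path_matrix

        geometry, _, grid = setup128
        pos = geometry.element_positions
        pairs = reference.pairs[:200]
        way = np.stack([pos[pairs[:, 0]], pos[pairs[:, 1]]], axis=1)
        L, _ = build_path_matrix(way, grid)
        x = rng.standard_normal(L.shape[1])
        y = rng.standard_normal(L.shape[0])
        lhs = float((L @ x) @ y)
        rhs = float(x @ (L.T @ y))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    def test_insufficient_valid_pairs_rejected(self, reference, setup128):
        _, config, grid = setup128
        tofm = estimate_tof(_synthesize(reference), reference)
        tofm.validity[: int(0.9 * len(tofm.validity))] = False
        with pytest.raises(ValueError, match="20%"):
            initial_sos_from_tof(tofm, reference.geometry, grid, config.water_sos)


class TestForwardWaveforms:
    def test_homogeneous_single_path_shift(self, reference, setup128):
        _, config, grid = setup128
        slowness = np.full(grid.shape, 1.0 / 1500.0)
        sg = SlownessGrid(slowness=slowness, grid=grid, water_slowness=1 / config.water_sos)
        est, start = forward_waveforms(sg, reference, n_paths=1)
        # rays cross the grid (slowness 1/1500) and continue in water outside
        model = WaveformModel(reference, grid, n_paths=1)
        tau = model.path_tofs(slowness)[:, 0]
        t_win = config.acquisition_delay + (start[:, None] + np.arange(est.shape[1])) * config.dt
        expected = reference.amplitude[:, None] * reference.pulse(t_win - tau[:, None])
        np.testing.assert_allclose(est, expected, atol=1e-12)
        # and the analytic line integral matches the matrix path lengths
        pos = reference.geometry.element_positions
        i = 0
        d = np.linalg.norm(pos[reference.pairs[i, 0]] - pos[reference.pairs[i, 1]])
        assert tau[i] >= d * 1e-3 / config.water_sos

    def test_water_slowness_reproduces_reference(self, reference, setup128):
        _, config, grid = setup128
        sg = SlownessGrid(
            slowness=np.full(grid.shape, 1.0 / config.water_sos),
            grid=grid, water_slowness=1.0 / config.water_sos,
        )
        est, start = forward_waveforms(sg, reference, n_paths=1)
        t_win = config.acquisition_delay + (start[:, None] + np.arange(est.shape[1])) * config.dt
        ref_win = reference.amplitude[:, None] * reference.pulse(t_win - reference.tof[:, None])
        np.testing.assert_allclose(est, ref_win, atol=1e-10 * np.abs(ref_win).max())

    def test_fan_earliest_energy_at_fastest_path(self, reference, setup128):
        _, config, grid = setup128
        xx, yy = grid.meshgrid()
        slow_map = np.full(grid.shape, 1.0 / config.water_sos)
        # small slow inclusion: narrower than the Fresnel fan half-width, so
        # the outer fan paths bypass it while the straight ray crosses it
        slow_map[xx**2 + yy**2 <= 2.0**2] = 1.0 / 1450.0
        sg = SlownessGrid(slowness=slow_map, grid=grid, water_slowness=1 / config.water_sos)
        model = WaveformModel(reference, grid, n_paths=7)
        tau = model.path_tofs(slow_map)
        i = np.nonzero((reference.pairs[:, 0] == 0) & (reference.pairs[:, 1] == 64))[0][0]
        # the straight (central) path crosses the slow inclusion; the outer
        # fan paths bypass it and carry the earliest energy
        mid = model.n_paths // 2
        assert tau[i].min() < tau[i, mid] - config.dt
        assert tau[i].min() == pytest.approx(reference.tof[i], abs=0.5 * config.dt)

        def crossing(trace):
            return np.nonzero(np.abs(trace) > 0.01 * np.abs(trace).max())[0][0]

        est_fan = model.traces(slow_map)[i]
        straight = WaveformModel(reference, grid, n_paths=1)
        est_straight = straight.traces(slow_map)[i]
        water = SlownessGrid(
            slowness=np.full(grid.shape, 1.0 / config.water_sos),
            grid=grid, water_slowness=1.0 / config.water_sos,
        )
        est_water = model.traces(water.slowness)[i]
        # earliest energy at the fastest (water-speed) path's arrival time
        assert abs(crossing(est_fan) - crossing(est_water)) <= 2
        assert crossing(est_straight) - crossing(est_fan) >= 2


class TestFwi:
    def test_gradient_matches_finite_differences(self, rng):
        from tropus.geometry import make_ring_geometry, scaled_config

        geometry = make_ring_geometry(16, 40.0)
        config = scaled_config()
        grid = Grid.centered(12, 4.0)
        ref = acquire_reference(geometry, config)
        model = WaveformModel(ref, grid, n_paths=3)
        x = 1.0 / 1523 + 2e-5 * rng.standard_normal(grid.ny * grid.nx)
        x_true = 1.0 / 1523 + 2e-5 * rng.standard_normal(grid.ny * grid.nx)
        M = model.traces(x_true)
        valid = np.ones(ref.n_pairs)
        _, grad = model.loss_and_grad(x, M, valid)
        h = 1e-9
        for j in rng.choice(grid.ny * grid.nx, 20, replace=False):
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            fd = (model.loss(xp, M, valid) - model.loss(xm, M, valid)) / (2 * h)
            denom = max(abs(fd), abs(grad[j]), 1e-12)
            assert abs(fd - grad[j]) / denom < 1e-4

    def test_truth_init_is_stationary(self, reference, setup128):
        _, config, grid = setup128
        truth = SlownessGrid(
            slowness=np.full(grid.shape, 1.0 / config.water_sos),
            grid=grid, water_slowness=1.0 / config.water_sos,
        )
        measured = _synthesize(reference)
        slow, state = fwi_reconstruct(measured, truth, reference, n_iterations=3)
        signal_scale = float(np.mean(measured.data[measured.data != 0] ** 2))
        assert state.loss_history[0] < 1e-12 * signal_scale + 1e-20
        np.testing.assert_allclose(slow.slowness, truth.slowness, rtol=1e-9)

    def test_loss_history_non_increasing(self, setup128, reference, control_phantom, control_sta):
        geometry, config, grid = setup128
        tofm = estimate_tof(control_sta, reference)
        init = initial_sos_from_tof(
            tofm, geometry, grid, config.water_sos, support=control_phantom.body_mask
        )
        slow, state = fwi_reconstruct(
            control_sta, init, reference, n_iterations=8,
            support=control_phantom.body_mask, tof_matrix=tofm,
        )
        assert np.all(np.diff(state.loss_history) <= 0)
        img = sos_image(slow)
        assert img.mode == "sos" and img.units == "m/s"
        assert np.isfinite(img.pixels).all()
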
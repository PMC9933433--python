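"""Dipole-velocity assembly, correlation estimators and IR spectra."""

import numpy as np
import pytest

from aptir import (
    AtomicConfiguration,
    AtomPartition,
    DipoleVelocitySeries,
    IRSpectrumParams,
    SpectrumSettings,
    Trajectory,
    autocorrelation,
    decompose_spectrum,
    dipole_velocity,
    ir_spectrum,
    nyquist_interval,
    velocities_from_positions,
)
from aptir.synthetic import (
    ToyForceField,
    generate_trajectory,
    generate_water_box,
    make_dipole_backend,
    ToyDipoleModel,
)
from aptir.units import C_CM_PER_FS


class TestDipoleVelocity:
    def test_identity_tensor_single_atom(self):
        p = np.full((5, 1, 3, 3), 0.0)
        p[:] = 0.7 * np.eye(3)
        v = np.zeros((5, 1, 3))
        v[:, 0, 0] = 1.0
        series = dipole_velocity(p, v, dt=1.0)
        np.testing.assert_allclose(series.values, [[0.7, 0, 0]] * 5, atol=1e-15)

    def test_zero_velocities_zero_series(self):
        p = np.random.default_rng(0).standard_normal((4, 2, 3, 3))
        series = dipole_velocity(p, np.zeros((4, 2, 3)), dt=0.5)
        assert np.all(series.values == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dipole_velocity(np.zeros((4, 2, 3, 3)), np.zeros((4, 3, 3)), dt=1.0)

    def test_matches_time_derivative_of_dipole(self):
        """Σ Pᵢvᵢ equals the central time difference of M(t) computed
        directly from the backend, to discretisation error."""
        box = generate_water_box(4, seed=8)
        traj, _ = generate_trajectory(box, ToyForceField(), 0.2, 400, 300.0, seed=9)
        backend = make_dipole_backend(ToyDipoleModel())
        apts = np.stack(
            [backend.analytic_apt_frame(f).tensors for f in traj.frames]
        )
        series = dipole_velocity(apts, traj.velocities, traj.dt)
        m = np.stack([backend.evaluate(f) for f in traj.frames])
        md_num = (m[2:] - m[:-2]) / (2 * traj.dt)
        err = np.abs(series.values[1:-1] - md_num).max()
        assert err < 5e-4 * np.abs(series.values).max() + 1e-9


class TestVelocitiesFromPositions:
    def test_linear_motion_exact_interior(self):
        u = np.array([[0.03, -0.01, 0.02]])
        frames = [
            AtomicConfiguration(["O"], u * t) for t in range(6)
        ]
        vel = velocities_from_positions(Trajectory(frames, dt=1.0))
        np.testing.assert_allclose(vel[1:-1], np.tile(u, (4, 1, 1)), atol=1e-12)

    def test_periodic_crossing_is_continuous(self):
        """An atom crossing the boundary must not produce an L-sized jump;
        compare against the trajectory's exact integrator velocities."""
        box = generate_water_box(2, seed=12)
        traj, _ = generate_trajectory(box, ToyForceField(), 0.5, 600, 400.0, seed=13)
        wrapped_frames = []
        for f in traj.frames:
            c = f.copy()
            frac = c.positions @ np.linalg.inv(c.cell)
            c.positions = (frac % 1.0) @ c.cell  # wrap into the cell
            wrapped_frames.append(c)
        wrapped = Trajectory(wrapped_frames, traj.dt)
        vel = velocities_from_positions(wrapped)
        err = np.abs(vel[1:-1] - traj.velocities[1:-1]).max()
        assert err < 5e-3  # finite-difference error only, no cell-sized jumps

    def test_two_frames_rejected(self):
        frames = [AtomicConfiguration(["O"], [[0, 0, 0]]) for _ in range(2)]
        with pytest.raises(ValueError, match="3 frames"):
            velocities_from_positions(Trajectory(frames, dt=1.0))


class TestAutocorrelation:
    @pytest.mark.parametrize("n", [64, 1000, 4096])
    def test_fft_equals_direct_estimator(self, n):
        rng = np.random.default_rng(n)
        series = DipoleVelocitySeries(rng.standard_normal((n, 3)), dt=1.0)
        settings = SpectrumSettings(max_lag_fs=float(n - 1))
        _, fft = autocorrelation(series, settings, method="fft")
        _, direct = autocorrelation(series, settings, method="direct")
        assert np.abs(fft - direct).max() <= 1e-10 * np.abs(direct).max()

    def test_white_noise_concentrates_at_lag_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8000, 3))
        series = DipoleVelocitySeries(x, dt=1.0)
        lags, acf = autocorrelation(series, SpectrumSettings(max_lag_fs=50.0))
        assert acf[0] == pytest.approx((x**2).sum(1).mean(), rel=1e-12)
        assert np.abs(acf[1:]).max() < 0.1 * acf[0]

    def test_constant_series(self):
        c = np.array([0.3, -1.2, 0.5])
        series = DipoleVelocitySeries(np.tile(c, (256, 1)), dt=1.0)
        lags, acf = autocorrelation(series, SpectrumSettings(max_lag_fs=60.0))
        # biased estimator: ⟨c·c⟩ (N−k)/N at lag k
        n = 256
        expected = (c @ c) * (n - np.arange(len(acf))) / n
        np.testing.assert_allclose(acf, expected, rtol=1e-12)

    def test_cosine_closed_form(self):
        n, dt, a = 4096, 1.0, 1.3
        nu0 = 1000.0 * C_CM_PER_FS  # 1000 cm⁻¹ in 1/fs
        t = np.arange(n) * dt
        x = np.zeros((n, 3))
        x[:, 0] = a * np.cos(2 * np.pi * nu0 * t)
        series = DipoleVelocitySeries(x, dt)
        lags, acf = autocorrelation(series, SpectrumSettings(max_lag_fs=200.0))
        # biased estimator carries the (N−k)/N triangle factor
        tri = (n - np.arange(len(lags))) / n
        expected = tri * a**2 / 2 * np.cos(2 * np.pi * nu0 * lags)
        np.testing.assert_allclose(acf, expected, atol=0.01 * a**2)


class TestIRSpectrum:
    def test_single_cosine_single_peak(self):
        n, dt = 8192, 1.0
        nu0 = 1000.0
        t = np.arange(n) * dt
        x = np.zeros((n, 3))
        x[:, 0] = np.cos(2 * np.pi * nu0 * C_CM_PER_FS * t)
        spec = ir_spectrum(DipoleVelocitySeries(x, dt))
        peak = spec.wavenumbers[np.argmax(spec.intensity)]
        resolution = spec.wavenumbers[1] - spec.wavenumbers[0]
        assert abs(peak - nu0) <= 2 * resolution
        # single peak: away from it the spectrum is small
        away = np.abs(spec.wavenumbers - nu0) > 150
        assert np.abs(spec.intensity[away]).max() < 0.05

    @pytest.mark.parametrize("mode_index", [0, 1, 2])
    def test_harmonic_water_peaks_at_hessian_modes(self, mode_index):
        """A trajectory started along one normal mode (zero temperature, so
        no rotational structure) gives a dipole-velocity spectrum peaking at
        that mode's analytic-Hessian wavenumber."""
        from aptir.units import ATOMIC_MASSES

        box = generate_water_box(1, seed=20)
        ff = ToyForceField()
        modes = ff.normal_mode_wavenumbers(box)
        m3 = np.repeat([ATOMIC_MASSES[s] for s in box.species], 3)
        mw = ff.hessian(box) / np.sqrt(np.outer(m3, m3))
        vals, vecs = np.linalg.eigh(mw)
        idx = np.where(vals > 1e-8)[0][mode_index]
        cfg = box.copy()
        cfg.positions = cfg.positions + 0.05 * (
            vecs[:, idx] / np.sqrt(m3)
        ).reshape(-1, 3)
        traj, _ = generate_trajectory(cfg, ff, 0.25, 8192, 0.0, seed=0)
        backend = make_dipole_backend(ToyDipoleModel())
        apts = np.stack(
            [backend.analytic_apt_frame(f).tensors for f in traj.frames]
        )
        series = dipole_velocity(apts, traj.velocities, traj.dt)
        spec = ir_spectrum(
            series, settings=SpectrumSettings(max_wavenumber=4500.0)
        )
        target = modes[mode_index]
        found = spec.wavenumbers[np.argmax(spec.intensity)]
        resolution = spec.wavenumbers[1] - spec.wavenumbers[0]
        assert abs(found - target) < max(25.0, 2 * resolution)

    def test_nyquist_violation_raises(self):
        series = DipoleVelocitySeries(np.zeros((128, 3)) + 1e-3, dt=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ir_spectrum(series, settings=SpectrumSettings(max_wavenumber=4000.0))

    def test_absolute_units_scale_with_inverse_volume(self):
        rng = np.random.default_rng(5)
        series = DipoleVelocitySeries(rng.standard_normal((512, 3)), dt=1.0)
        s1 = ir_spectrum(series, IRSpectrumParams(300.0, 1000.0))
        s2 = ir_spectrum(series, IRSpectrumParams(300.0, 2000.0))
        np.testing.assert_allclose(s1.intensity, 2.0 * s2.intensity, rtol=1e-12)
        assert s1.absolute_units

    def test_parseval_unwindowed(self):
        """∫ power dν̃ recovers the time-domain mean square of Ṁ within 1%
        for the unwindowed, full-lag estimator."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal((2048, 3))
        series = DipoleVelocitySeries(x, dt=1.0)
        settings = SpectrumSettings(
            window="none", max_lag_fs=2047.0, zero_padding=4
        )
        lags, acf = autocorrelation(series, settings)
        from aptir.spectrum import _spectrum_from_acf

        wn, power = _spectrum_from_acf(acf, 1.0, settings)
        integral = np.trapezoid(power, wn * C_CM_PER_FS)  # back to 1/fs grid
        # cosine terms integrate to zero over [0, Nyquist], leaving the
        # lag-0 term: ∫ S dν = ⟨|Ṁ|²⟩ / 2
        assert integral == pytest.approx(acf[0] / 2.0, rel=0.01)

    def test_multi_trajectory_averaging(self):
        rng = np.random.default_rng(13)
        many = [
            DipoleVelocitySeries(rng.standard_normal((512, 3)), dt=1.0)
            for _ in range(3)
        ]
        avg = ir_spectrum(many, IRSpectrumParams(300.0, 1000.0))
        singles = [ir_spectrum(s, IRSpectrumParams(300.0, 1000.0)) for s in many]
        np.testing.assert_allclose(
            avg.intensity,
            np.mean([s.intensity for s in singles], axis=0),
            rtol=1e-10,
        )


class TestDecomposition:
    def _setup(self):
        rng = np.random.default_rng(30)
        t, n = 600, 6
        apts = rng.standard_normal((t, n, 3, 3))
        vel = rng.standard_normal((t, n, 3))
        return apts, vel

    def test_single_group_equals_total(self):
        apts, vel = self._setup()
        part = AtomPartition(6, {"all": np.arange(6)})
        out = decompose_spectrum(apts, vel, part, dt=1.0)
        np.testing.assert_allclose(
            out["auto"]["all"].intensity, out["total"].intensity, atol=1e-12
        )
        assert not out["cross"]

    def test_sum_rule_pointwise(self):
        """Σ auto + 2 Σ cross reconstructs the total spectrum pointwise."""
        apts, vel = self._setup()
        part = AtomPartition(
            6, {"O": np.array([0, 3]), "H": np.array([1, 2, 4, 5])}
        )
        out = decompose_spectrum(apts, vel, part, dt=1.0)
        recon = (
            out["auto"]["O"].intensity
            + out["auto"]["H"].intensity
            + 2.0 * out["cross"][("O", "H")].intensity
        )
        total = out["total"].intensity
        assert np.abs(recon - total).max() <= 1e-8 * np.abs(total).max()

    def test_zero_velocity_group_vanishes(self):
        apts, vel = self._setup()
        vel[:, 3:] = 0.0
        part = AtomPartition(6, {"a": np.arange(3), "b": np.arange(3, 6)})
        out = decompose_spectrum(apts, vel, part, dt=1.0)
        assert np.abs(out["auto"]["b"].intensity).max() == 0.0
        assert np.abs(out["cross"][("a", "b")].intensity).max() == 0.0

    def test_projector_split_sums_to_identity(self):
        """Directional projectors on the same atoms form a valid split and
        obey the sum rule."""
        apts, vel = self._setup()
        px = np.zeros((6, 3, 3))
        px[:, 0, 0] = 1.0
        pyz = np.tile(np.eye(3), (6, 1, 1)) - px
        part = AtomPartition(
            6,
            {"x": np.arange(6), "yz": np.arange(6)},
            {"x": px, "yz": pyz},
        )
        out = decompose_spectrum(apts, vel, part, dt=1.0)
        recon = (
            out["auto"]["x"].intensity
            + out["auto"]["yz"].intensity
            + 2.0 * out["cross"][("x", "yz")].intensity
        )
        assert np.abs(recon - out["total"].intensity).max() <= 1e-8 * np.abs(
            out["total"].intensity
        ).max()

    def test_overlapping_groups_without_projectors_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AtomPartition(4, {"a": np.arange(3), "b": np.arange(2, 4)})

    def test_incomplete_cover_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            AtomPartition(4, {"a": np.arange(2)})


class TestNyquist:
    def test_closed_form(self):
        # 1/(2cν̃) at 3500 cm⁻¹ ≈ 4.765 fs (commonly rounded to ~4.5–5 fs)
        assert nyquist_interval(3500.0) == pytest.approx(4.7652, abs=2e-3)

    def test_halving_doubles_interval(self):
        assert nyquist_interval(1750.0) == pytest.approx(
            2.0 * nyquist_interval(3500.0), rel=1e-12
        )

    @pytest.mark.parametrize("nu", [10.0, 321.0, 3500.0])
    def test_scaling_property(self, nu):
        assert nyquist_interval(2 * nu) == pytest.approx(
            nyquist_interval(nu) / 2.0, rel=1e-12
        )

    def test_positive_required(self):
        with pytest.raises(ValueError):
            nyquist_interval(0.0)
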
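"""Synthetic water generator: boxes, dynamics, analytic dipole oracles."""

import numpy as np
import pytest

from aptir import FDSettings, compute_apt_config
from aptir.synthetic import (
    ToyDipoleModel,
    ToyForceField,
    generate_trajectory,
    generate_water_box,
    make_dipole_backend,
    make_labelled_dataset,
)
from aptir.units import ATOMIC_MASSES, C_CM_PER_FS

from conftest import richardson_derivative


class TestWaterBox:
    @pytest.mark.parametrize("n,expected_atoms", [(1, 3), (16, 48), (128, 384)])
    def test_atom_counts(self, n, expected_atoms):
        assert generate_water_box(n, seed=0).n_atoms == expected_atoms

    def test_density_sets_cell(self):
        box = generate_water_box(128, seed=0)
        volume = abs(np.linalg.det(box.cell))
        # 128 molecules at ambient density: ~3837 Å³
        assert volume == pytest.approx(3837.0, rel=0.01)

    def test_minimum_oo_separation(self):
        box = generate_water_box(32, seed=5)
        o = box.positions[::3]
        delta = o[None] - o[:, None]
        frac = delta @ np.linalg.inv(box.cell)
        frac -= np.round(frac)
        dist = np.linalg.norm(frac @ box.cell, axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() > 2.5

    def test_deterministic(self):
        b1 = generate_water_box(8, seed=4)
        b2 = generate_water_box(8, seed=4)
        np.testing.assert_array_equal(b1.positions, b2.positions)

    def test_impossible_density_raises(self):
        with pytest.raises(RuntimeError, match="density"):
            generate_water_box(8, density=20.0, seed=0)


class TestToyDipole:
    def test_fixed_variant_apt_is_charge_identity(self, small_box):
        backend = make_dipole_backend(ToyDipoleModel(variant="fixed"))
        frame = backend.analytic_apt_frame(small_box)
        q = np.tile([-0.8, 0.4, 0.4], small_box.n_atoms // 3)
        np.testing.assert_allclose(
            frame.tensors, q[:, None, None] * np.eye(3), atol=1e-14
        )

    def test_neutral_system_sum_rule(self, small_box, fluct_backend):
        frame = fluct_backend.analytic_apt_frame(small_box)
        np.testing.assert_allclose(frame.tensors.sum(axis=0), 0.0, atol=1e-12)

    def test_analytic_apt_matches_richardson_oracle(self, small_box, fluct_backend):
        """Closed-form ∂M/∂r (with charge-gradient terms) against a
        Richardson-extrapolated numerical derivative, to 1e-8."""
        frame = fluct_backend.analytic_apt_frame(small_box)
        rng = np.random.default_rng(0)
        for i in rng.choice(small_box.n_atoms, size=4, replace=False):
            for zeta in range(3):
                for xi in range(3):
                    def m_of(x, i=i, zeta=zeta, xi=xi):
                        cfg = small_box.copy()
                        cfg.positions[i, zeta] = x
                        return fluct_backend.evaluate(cfg)[xi]

                    oracle = richardson_derivative(
                        m_of, small_box.positions[i, zeta]
                    )
                    assert abs(frame.tensors[i, xi, zeta] - oracle) < 1e-8

    def test_smooth_under_small_displacements(self, small_box, fluct_backend):
        """No branch jumps: sub-Å displacements move M continuously."""
        m0 = fluct_backend.evaluate(small_box)
        cfg = small_box.copy()
        cfg.positions[0] += 1e-6
        assert np.linalg.norm(fluct_backend.evaluate(cfg) - m0) < 1e-4


class TestDynamics:
    @pytest.mark.parametrize("mode_index", [0, 1, 2])
    def test_single_molecule_vacf_peaks_at_normal_modes(self, mode_index):
        """A zero-temperature trajectory displaced along one Hessian
        eigenvector oscillates at that mode's wavenumber: the velocity
        autocorrelation spectrum peaks there (no rotational structure)."""
        box = generate_water_box(1, seed=3)
        ff = ToyForceField()
        modes = ff.normal_mode_wavenumbers(box)
        m3 = np.repeat([ATOMIC_MASSES[s] for s in box.species], 3)
        vals, vecs = np.linalg.eigh(
            ff.hessian(box) / np.sqrt(np.outer(m3, m3))
        )
        idx = np.where(vals > 1e-8)[0][mode_index]
        cfg = box.copy()
        cfg.positions = cfg.positions + 0.05 * (
            vecs[:, idx] / np.sqrt(m3)
        ).reshape(-1, 3)
        traj, _ = generate_trajectory(cfg, ff, 0.25, 8192, 0.0, seed=0)
        v = traj.velocities.reshape(traj.n_frames, -1)
        acf = np.array(
            [np.einsum("tc,tc->", v[: len(v) - k], v[k:]) for k in range(3000)]
        )
        spec = np.abs(np.fft.rfft(acf * np.hanning(6000)[3000:], n=32768))
        freq = np.fft.rfftfreq(32768, d=0.25) / C_CM_PER_FS
        assert abs(freq[np.argmax(spec)] - modes[mode_index]) < 25.0

    def test_zero_temperature_equilibrium_is_static(self):
        box = generate_water_box(1, seed=3)
        traj, _ = generate_trajectory(box, ToyForceField(), 0.5, 50, 0.0, seed=0)
        # forces at the template geometry vanish to round-off only
        assert np.abs(traj.velocities).max() < 1e-12
        np.testing.assert_allclose(
            traj.frames[-1].positions, traj.frames[0].positions, atol=1e-9
        )

    def test_deterministic(self):
        box = generate_water_box(4, seed=3)
        t1, _ = generate_trajectory(box, ToyForceField(), 0.5, 100, 300.0, seed=9)
        t2, _ = generate_trajectory(box, ToyForceField(), 0.5, 100, 300.0, seed=9)
        np.testing.assert_array_equal(t1.velocities, t2.velocities)
        np.testing.assert_array_equal(
            t1.frames[-1].positions, t2.frames[-1].positions
        )

    def test_unstable_timestep_rejected(self):
        box = generate_water_box(1, seed=3)
        with pytest.raises(ValueError, match="unstable"):
            generate_trajectory(box, ToyForceField(), 8.0, 10, 300.0, seed=0)

    def test_energy_conservation(self):
        """Symplectic integration: chunk-averaged total energy drifts by
        less than 1e-4 relative over the run at a 1 fs step."""
        box = generate_water_box(8, seed=6)
        ff = ToyForceField()
        traj, _ = generate_trajectory(box, ff, 1.0, 1500, 300.0, seed=7)
        masses = np.array([ATOMIC_MASSES[s] for s in box.species])[:, None]

        def energy(k):
            pot, _ = ff.energy_forces(traj.frames[k])
            return pot + 0.5 * (masses * traj.velocities[k] ** 2).sum()

        first = np.mean([energy(k) for k in range(150)])
        last = np.mean([energy(k) for k in range(1350, 1500)])
        assert abs(last - first) / abs(first) < 1e-4


class TestLabelledDataset:
    def test_counts_scale_with_configs_and_atoms(self):
        ds = make_labelled_dataset(3, 4, seed=0, decorrelation_steps=30)
        assert len(ds) == 3
        assert ds.n_apts == 3 * 12

    def test_noise_free_labels_are_analytic(self, fluct_backend):
        ds = make_labelled_dataset(2, 2, seed=1, decorrelation_steps=30)
        for cfg, apt in ds.records:
            np.testing.assert_allclose(
                apt.tensors,
                fluct_backend.analytic_apt_frame(cfg).tensors,
                atol=1e-13,
            )

    def test_fd_labels_close_to_analytic(self, fluct_backend):
        ds_fd = make_labelled_dataset(
            1, 2, seed=1, labels="fd", decorrelation_steps=30
        )
        cfg, apt = ds_fd.records[0]
        exact = fluct_backend.analytic_apt_frame(cfg).tensors
        assert np.abs(apt.tensors - exact).max() < 1e-6

    def test_label_noise_amplitude(self):
        ds0 = make_labelled_dataset(2, 4, seed=1, decorrelation_steps=30)
        ds1 = make_labelled_dataset(2, 4, seed=1, decorrelation_steps=30, noise=0.01)
        diff = np.concatenate(
            [
                (a1.tensors - a0.tensors).ravel()
                for (_, a0), (_, a1) in zip(ds0.records, ds1.records)
            ]
        )
        assert diff.std() == pytest.approx(0.01, rel=0.15)


def test_hessian_symmetry_and_positive_modes():
    box = generate_water_box(1, seed=3)
    ff = ToyForceField()
    h = ff.hessian(box)
    np.testing.assert_allclose(h, h.T, atol=1e-10)
    modes = ff.normal_mode_wavenumbers(box)
    assert len(modes) == 3
    assert np.all(modes > 0)
    # design targets: bend near 1600 cm⁻¹, stretches near 3500 cm⁻¹
    assert 1400 < modes[0] < 1800
    assert 3200 < modes[1] < 3700 and 3200 < modes[2] < 3700
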
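"""Force field, taper, integrator and thermostat contracts."""

import numpy as np
import pytest

from espec import (ForceFieldParams, Frame, SimulationConfig, WaterTopology,
                   classical_forces, equilibrate, kinetic_temperature,
                   maxwell_boltzmann_velocities, taper, toy_cluster,
                   verlet_step)
from espec.core_io import E2_COULOMB, MASS_H
from espec.water_qcmd import taper_derivative


def brute_force_energy(pos, topo, ff):
    """Independent site-by-site energy sum (oracle for classical_forces)."""
    n = topo.n_molecules
    e = 0.0
    for m in range(n):
        O, H1, H2 = pos[3 * m], pos[3 * m + 1], pos[3 * m + 2]
        for H in (H1, H2):
            e += 0.5 * ff.k_stretch * (np.linalg.norm(H - O) - ff.r_OH) ** 2
        d1, d2 = H1 - O, H2 - O
        th = np.arccos(d1 @ d2 / (np.linalg.norm(d1) * np.linalg.norm(d2)))
        e += 0.5 * ff.k_bend * (th - ff.theta_HOH) ** 2
    q = [topo.charge_O, topo.charge_H, topo.charge_H]
    for a in range(n):
        for b in range(a + 1, n):
            r_oo = np.linalg.norm(pos[3 * b] - pos[3 * a])
            if r_oo >= ff.r_cut:
                continue
            s = float(taper(r_oo, ff.r_cut, ff.taper_width))
            u = 4 * ff.eps_OO * ((ff.sigma_OO / r_oo) ** 12
                                 - (ff.sigma_OO / r_oo) ** 6)
            for i in range(3):
                for j in range(3):
                    r = np.linalg.norm(pos[3 * b + j] - pos[3 * a + i])
                    u += E2_COULOMB * q[i] * q[j] / r
            e += s * u
    return e


class TestForces:
    def test_energy_matches_brute_force(self, ff, water8):
        topo = WaterTopology(8)
        _, U = classical_forces(water8, topo, ff)
        assert U == pytest.approx(brute_force_energy(water8.positions, topo, ff),
                                  rel=1e-12)

    def test_coulomb_closed_form_for_distant_pair(self, ff):
        # two waters far beyond sigma: energy is the tapered 3x3 Coulomb sum
        topo = WaterTopology(2)
        rng = np.random.default_rng(5)
        base = np.array([[0.0, 0, 0], [0.96, 0.3, 0], [-0.3, 0.93, 0]])
        pos = np.vstack([base, base + [7.5, 0.1, 0.2]])
        _, U = classical_forces(Frame(0.0, pos), topo, ff)
        assert U == pytest.approx(brute_force_energy(pos, topo, ff), rel=1e-12)

    def test_newtons_third_law(self, ff, water8):
        topo = WaterTopology(8)
        F, _ = classical_forces(water8, topo, ff)
        assert np.abs(F.sum(axis=0)).max() < 1e-8
        torque = np.cross(water8.positions, F).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_pair_beyond_cutoff_does_not_interact(self, ff):
        topo = WaterTopology(2)
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [-0.33, 0.94, 0]])
        far = base + [ff.r_cut + 0.1, 0.0, 0.0]
        both = np.vstack([base, far])
        F, U = classical_forces(Frame(0.0, both), topo, ff)
        F1, U1 = classical_forces(Frame(0.0, base), WaterTopology(1), ff)
        assert U == pytest.approx(2 * U1, abs=1e-12)
        assert np.allclose(F[:3], F1, atol=1e-12)

    def test_forces_match_numerical_gradient(self, ff, water8):
        topo = WaterTopology(8)
        F, _ = classical_forces(water8, topo, ff)
        h = 1e-6
        for site, axis in ((0, 0), (7, 1), (14, 2)):
            p = water8.positions.copy()
            p[site, axis] += h
            _, up = classical_forces(Frame(0.0, p), topo, ff)
            p[site, axis] -= 2 * h
            _, um = classical_forces(Frame(0.0, p), topo, ff)
            assert F[site, axis] == pytest.approx(-(up - um) / (2 * h),
                                                  abs=1e-5)


class TestTaper:
    def test_endpoints_and_derivative_continuity(self, ff):
        rc, w = ff.r_cut, ff.taper_width
        assert taper(rc - w, rc, w) == pytest.approx(1.0, abs=1e-12)
        assert taper(rc, rc, w) == pytest.approx(0.0, abs=1e-12)
        eps = 1e-7
        for r0 in (rc - w, rc):
            num = (taper(r0 + eps, rc, w) - taper(r0 - eps, rc, w)) / (2 * eps)
            ana = taper_derivative(r0 + 1e-12, rc, w)
            assert num == pytest.approx(float(ana), abs=1e-5)
        # derivative is zero approaching both edges from outside
        assert taper_derivative(rc - w - 1e-9, rc, w) == 0.0
        assert taper_derivative(rc + 1e-9, rc, w) == 0.0


class TestVerlet:
    def test_harmonic_energy_bounded_no_drift(self):
        # 1D harmonic oscillator, dt = T/100: the velocity-Verlet energy
        # error is bounded and oscillatory with relative amplitude
        # ~(w*dt)^2/8 ~ 5e-4, with no secular drift
        m, k = 1.0, 4.0 * np.pi**2  # period 1 fs
        x = np.array([[1.0, 0.0, 0.0]])
        v = np.zeros((1, 3))
        masses = np.array([m])

        def force(p):
            return -k * p, float(0.5 * k * (p**2).sum())

        f, u = force(x)
        dt = 0.01
        energies = []
        for _ in range(1000):
            x, v, f, u = verlet_step(x, v, f, masses, dt, force)
            energies.append(0.5 * m * (v**2).sum() + u)
        e = np.array(energies)
        e0 = 0.5 * k
        omega_dt = np.sqrt(k / m) * dt
        assert np.abs(e - e0).max() / e0 < omega_dt**2 / 4
        # no secular trend: total fitted change over the run stays far below
        # the oscillation amplitude (fit leakage from windowing aside)
        drift = np.polyfit(np.arange(len(e)), e, 1)[0]
        assert abs(drift) * len(e) < 1e-5 * e0

    def test_zero_force_uniform_motion(self):
        x = np.array([[0.0, 0.0, 0.0]])
        v = np.array([[1.0, -2.0, 0.5]])
        masses = np.array([3.0])

        def force(p):
            return np.zeros_like(p), 0.0

        f, u = force(x)
        for _ in range(10):
            x, v, f, u = verlet_step(x, v, f, masses, 0.5, force)
        assert np.allclose(x, np.array([[1.0, -2.0, 0.5]]) * 5.0, atol=1e-14)

    def test_time_reversibility(self, ff, water8):
        topo = WaterTopology(8)
        masses = topo.masses
        x = water8.positions.copy()
        v = maxwell_boltzmann_velocities(masses, 100.0, seed=4)

        def force(p):
            return classical_forces(Frame(0.0, p), topo, ff)

        f, u = force(x)
        x0 = x.copy()
        for _ in range(100):
            x, v, f, u = verlet_step(x, v, f, masses, 0.5, force)
        v = -v
        for _ in range(100):
            x, v, f, u = verlet_step(x, v, f, masses, 0.5, force)
        assert np.abs(x - x0).max() < 1e-10

    def test_momentum_conserved_per_step(self, ff, water8):
        topo = WaterTopology(8)
        masses = topo.masses
        x = water8.positions.copy()
        v = maxwell_boltzmann_velocities(masses, 200.0, seed=9)

        def force(p):
            return classical_forces(Frame(0.0, p), topo, ff)

        f, u = force(x)
        p0 = (masses[:, None] * v).sum(axis=0)
        for _ in range(20):
            x, v, f, u = verlet_step(x, v, f, masses, 0.5, force)
        p1 = (masses[:, None] * v).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-8

    def test_nonfinite_force_rejected(self):
        with pytest.raises(FloatingPointError):
            verlet_step(np.zeros((1, 3)), np.zeros((1, 3)),
                        np.array([[np.nan, 0, 0]]), np.array([1.0]), 0.5,
                        lambda p: (np.zeros_like(p), 0.0))


class TestThermostat:
    def test_cold_start_reaches_target_window(self, water8):
        """Velocity rescaling drives an 0 K start into the target window."""
        cfg = SimulationConfig(n_molecules=8, temperature=200.0, quantum=False,
                               seed=3)
        topo = WaterTopology(8)
        start = Frame(0.0, water8.positions,
                      velocities=np.zeros((24, 3)))
        out = equilibrate(cfg, start, topo, n_steps=4000)
        # measure over a short follow-up NVE stretch
        masses = topo.masses
        T = kinetic_temperature(out.velocities, masses)
        assert 120.0 < T < 300.0

    def test_already_at_target_barely_rescaled(self, water8):
        cfg = SimulationConfig(n_molecules=8, temperature=200.0, quantum=False,
                               seed=3)
        topo = WaterTopology(8)
        v = maxwell_boltzmann_velocities(topo.masses, 200.0, seed=3)
        start = Frame(0.0, water8.positions, velocities=v)
        out = equilibrate(cfg, start, topo, n_steps=500)
        T = kinetic_temperature(out.velocities, topo.masses)
        assert 100.0 < T < 350.0


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt_fs=-0.5)
        with pytest.raises(ValueError):
            SimulationConfig(store_stride=0)
        with pytest.raises(ValueError):
            SimulationConfig(box_edge=10.0)
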
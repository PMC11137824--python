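"""Flexible SPC water force field and the mixed quantum-classical loop.

Classical water: harmonic OH stretch + harmonic HOH bend inside each
molecule, O-O Lennard-Jones and site-site Coulomb between molecules, the
intermolecular terms smoothly switched off by a cubic-Hermite taper applied
per molecule pair (on the O-O distance, keeping charge groups intact).
Dynamics: velocity Verlet at 0.5 fs; equilibration by periodic velocity
rescaling to the target temperature, production in the microcanonical
ensemble.  In the coupled loop the ground state of the excess electron is
re-solved each step on the dynamics grid and its Hellmann-Feynman force is
added to the classical force, so the nuclei move adiabatically on the
ground-state electronic surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import E2_COULOMB, Frame, KB_EV_K, Trajectory, WaterTopology
from .electron_grid import (ElectronStates, GridSpec, PseudopotentialParams,
                            build_potential_grid, default_pseudopotential,
                            hellmann_feynman_forces, solve_states)

_KCAL_MOL_EV = 0.0433641


@dataclass(frozen=True)
class ForceFieldParams:
    """Flexible SPC parameters (A, eV, rad units).

    Defaults: SPC geometry and charges; harmonic stretch/bend constants
    placing the OH stretch near 3650 cm^-1 and the bend near 1600 cm^-1;
    O-O Lennard-Jones of SPC; 9 A cutoff with a 1 A taper.
    """

    r_OH: float = 1.0
    theta_HOH: float = np.deg2rad(109.47)
    k_stretch: float = 48.0      # eV/A^2, V = 1/2 k (r - r0)^2 per bond
    k_bend: float = 3.29         # eV/rad^2, V = 1/2 k (theta - theta0)^2
    eps_OO: float = 0.1554 * _KCAL_MOL_EV
    sigma_OO: float = 3.166
    charge_O: float = -0.82
    r_cut: float = 9.0
    taper_width: float = 1.0

    @property
    def charge_H(self) -> float:
        return -self.charge_O / 2.0


def taper(r, rc: float, width: float):
    """Cubic-Hermite switch: 1 below rc - width, 0 above rc, C1 continuous."""
    r = np.asarray(r, dtype=float)
    s = np.clip((r - (rc - width)) / width, 0.0, 1.0)
    return 1.0 - 3.0 * s**2 + 2.0 * s**3


def taper_derivative(r, rc: float, width: float):
    r = np.asarray(r, dtype=float)
    s = (r - (rc - width)) / width
    inside = (s > 0.0) & (s < 1.0)
    return np.where(inside, (-6.0 * s + 6.0 * s**2) / width, 0.0)


def _min_image(d: np.ndarray, box: float | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def classical_forces(frame: Frame, topology: WaterTopology,
                     params: ForceFieldParams) -> tuple[np.ndarray, float]:
    """Analytic forces (eV/A) and potential energy (eV) of the water bath.

    Fully vectorized over molecules and molecule pairs; intermolecular terms
    are multiplied by the taper of the pair's O-O distance (charge groups
    switch off as a whole) and vanish beyond the cutoff.
    """
    pos = frame.positions
    box = frame.box_edge
    n = topology.n_molecules
    forces = np.zeros_like(pos)
    energy = 0.0

    # --- intramolecular: two harmonic stretches + one harmonic bend
    O, H1, H2 = pos[0::3], pos[1::3], pos[2::3]
    d1 = _min_image(H1 - O, box)
    d2 = _min_image(H2 - O, box)
    r1 = np.linalg.norm(d1, axis=1)
    r2 = np.linalg.norm(d2, axis=1)
    if np.any(r1 < 1e-6) or np.any(r2 < 1e-6):
        raise FloatingPointError("overlapping O/H sites")
    energy += 0.5 * params.k_stretch * np.sum((r1 - params.r_OH) ** 2
                                              + (r2 - params.r_OH) ** 2)
    f1 = -params.k_stretch * ((r1 - params.r_OH) / r1)[:, None] * d1
    f2 = -params.k_stretch * ((r2 - params.r_OH) / r2)[:, None] * d2
    forces[1::3] += f1
    forces[2::3] += f2
    forces[0::3] -= f1 + f2
    cos_t = np.clip(np.einsum("ij,ij->i", d1, d2) / (r1 * r2), -1.0, 1.0)
    theta = np.arccos(cos_t)
    energy += 0.5 * params.k_bend * np.sum((theta - params.theta_HOH) ** 2)
    dU = params.k_bend * (theta - params.theta_HOH)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
    g1 = (d2 / (r1 * r2)[:, None] - (cos_t / r1**2)[:, None] * d1) \
        / (-sin_t)[:, None]
    g2 = (d1 / (r1 * r2)[:, None] - (cos_t / r2**2)[:, None] * d2) \
        / (-sin_t)[:, None]
    forces[1::3] -= dU[:, None] * g1
    forces[2::3] -= dU[:, None] * g2
    forces[0::3] += dU[:, None] * (g1 + g2)

    if n < 2:
        return forces, float(energy)

    # --- intermolecular: molecule pairs within the tapered cutoff
    ia, ib = np.triu_indices(n, k=1)
    dOO = _min_image(pos[3 * ib] - pos[3 * ia], box)
    rOO = np.linalg.norm(dOO, axis=1)
    keep = rOO < params.r_cut
    ia, ib, dOO, rOO = ia[keep], ib[keep], dOO[keep], rOO[keep]
    if len(ia) == 0:
        return forces, float(energy)
    S = taper(rOO, params.r_cut, params.taper_width)
    dS = taper_derivative(rOO, params.r_cut, params.taper_width)

    u_pair = np.zeros(len(ia))           # untapered pair energies
    f_sites = np.zeros((len(ia), 6, 3))  # untapered forces, sites of a then b
    # O-O Lennard-Jones
    sr6 = (params.sigma_OO / rOO) ** 6
    u_pair += 4.0 * params.eps_OO * (sr6**2 - sr6)
    du_lj = 4.0 * params.eps_OO * (-12.0 * sr6**2 + 6.0 * sr6) / rOO
    f_lj = -(du_lj / rOO)[:, None] * dOO
    f_sites[:, 3] += f_lj
    f_sites[:, 0] -= f_lj
    # site-site Coulomb, 9 combinations per pair
    q = (topology.charge_O, topology.charge_H, topology.charge_H)
    for i in range(3):
        for j in range(3):
            d = _min_image(pos[3 * ib + j] - pos[3 * ia + i], box)
            r = np.linalg.norm(d, axis=1)
            if np.any(r < 1e-6):
                raise FloatingPointError("overlapping sites")
            u_c = E2_COULOMB * q[i] * q[j] / r
            u_pair += u_c
            f_c = (u_c / r**2)[:, None] * d
            f_sites[:, 3 + j] += f_c
            f_sites[:, i] -= f_c
    energy += float(np.sum(S * u_pair))
    f_sites *= S[:, None, None]
    # taper gradient acts along the O-O axis
    f_taper = -(dS * u_pair / rOO)[:, None] * dOO
    for i in range(3):
        np.add.at(forces, 3 * ia + i, f_sites[:, i])
        np.add.at(forces, 3 * ib + i, f_sites[:, 3 + i])
    np.add.at(forces, 3 * ib, f_taper)
    np.add.at(forces, 3 * ia, -f_taper)
    return forces, float(energy)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def verlet_step(positions: np.ndarray, velocities: np.ndarray,
                forces: np.ndarray, masses: np.ndarray, dt: float,
                force_fn) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One velocity-Verlet step; returns (x, v, F, U) at t + dt."""
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force")
    inv_m = 1.0 / masses[:, None]
    v_half = velocities + 0.5 * dt * forces * inv_m
    x_new = positions + dt * v_half
    f_new, u_new = force_fn(x_new)
    v_new = v_half + 0.5 * dt * f_new * inv_m
    return x_new, v_new, f_new, u_new


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * np.sum(masses[:, None] * velocities**2))


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray,
                        remove_com: bool = True) -> float:
    v = velocities
    if remove_com:
        p = (masses[:, None] * v).sum(axis=0)
        v = v - p / masses.sum()
    ndof = 3 * len(masses) - (3 if remove_com else 0)
    return 2.0 * kinetic_energy(v, masses) / (ndof * KB_EV_K)


def maxwell_boltzmann_velocities(masses: np.ndarray, T: float,
                                 seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((len(masses), 3)) * np.sqrt(
        KB_EV_K * T / masses)[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


# ---------------------------------------------------------------------------
# Simulation configuration and the coupled loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of one dynamics run (desk-scale defaults).

    ``dt_fs`` is the integration step (0.5 fs), ``temperature`` the target
    kinetic temperature (200 K clusters / 300 K bulk), ``store_stride`` how
    many steps separate stored frames of the dense trajectory.  The electron
    is solved on ``dynamics_grid`` every step when ``quantum`` is on.
    """

    n_molecules: int = 8
    temperature: float = 200.0
    dt_fs: float = 0.5
    n_steps: int = 2000
    store_stride: int = 1
    box_edge: float | None = None
    dynamics_grid: GridSpec = field(default_factory=lambda: GridSpec(18.17, 16))
    quantum: bool = True
    seed: int = 0
    rescale_every: int = 50
    solver_tol: float = 1e-9

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("time step must be positive")
        if self.store_stride < 1:
            raise ValueError("storage stride must be >= 1")
        if self.box_edge is not None and self.box_edge <= 2 * 9.0:
            raise ValueError("box must exceed twice the cutoff")


@dataclass
class SimulationState:
    frame: Frame
    forces: np.ndarray
    potential: float
    electron: ElectronStates | None = None

    def total_energy(self, masses: np.ndarray) -> float:
        e = kinetic_energy(self.frame.velocities, masses) + self.potential
        if self.electron is not None:
            e += self.electron.energies[0]
        return e


def _coupled_force_fn(topology, ff, grid, pp, box, tol, psi_cache):
    """Force closure: classical + Hellmann-Feynman quantum force."""
    def fn(x):
        fr = Frame(0.0, x, box_edge=box)
        f, u = classical_forces(fr, topology, ff)
        V = build_potential_grid(fr, topology, grid, pp)
        st = solve_states(V, grid, K=0, tol=tol, v0=psi_cache.get("block"))
        psi_cache["block"] = st.block
        psi_cache["states"] = st
        f += hellmann_feynman_forces(fr, topology, st, pp)
        return f, u + st.energies[0]
    return fn


def run_qcmd(config: SimulationConfig, initial: Frame,
             topology: WaterTopology,
             ff: ForceFieldParams | None = None,
             pp: PseudopotentialParams | None = None,
             ) -> tuple[Trajectory, pd.DataFrame]:
    """NVE production run; returns the dense stored trajectory and the
    per-stored-frame energy ledger (kinetic, classical potential, electron
    ground-state energy, total, kinetic temperature)."""
    ff = ff or ForceFieldParams()
    pp = pp or default_pseudopotential()
    masses = topology.masses
    box = initial.box_edge
    if initial.velocities is None:
        initial = replace(initial, velocities=maxwell_boltzmann_velocities(
            masses, config.temperature, config.seed))

    psi_cache: dict = {}
    if config.quantum:
        grid = _centered_grid(config.dynamics_grid, initial, topology)
        force_fn = _coupled_force_fn(topology, ff, grid, pp, box,
                                     config.solver_tol, psi_cache)
    else:
        def force_fn(x):
            return classical_forces(Frame(0.0, x, box_edge=box), topology, ff)

    x, v = initial.positions.copy(), initial.velocities.copy()
    f, u = force_fn(x)
    stored_x, stored_v, ledger = [x.copy()], [v.copy()], []

    def log_row(step):
        ke = kinetic_energy(v, masses)
        e_el = (psi_cache["states"].energies[0]
                if config.quantum else 0.0)
        ledger.append({"step": step, "time_fs": step * config.dt_fs,
                       "kinetic_eV": ke,
                       "classical_potential_eV": u - e_el,
                       "electron_E0_eV": e_el,
                       "total_eV": ke + u,
                       "temperature_K": kinetic_temperature(v, masses)})

    log_row(0)
    for step in range(1, config.n_steps + 1):
        x, v, f, u = verlet_step(x, v, f, masses, config.dt_fs, force_fn)
        if step % config.store_stride == 0:
            stored_x.append(x.copy())
            stored_v.append(v.copy())
            log_row(step)
    traj = Trajectory(np.stack(stored_x), config.dt_fs * config.store_stride,
                      topology=topology, velocities=np.stack(stored_v),
                      box_edge=box, tag="classical")
    return traj, pd.DataFrame(ledger)


def _centered_grid(grid: GridSpec, frame: Frame,
                   topology: WaterTopology) -> GridSpec:
    """Center the electron grid on the water center of mass (first frame).

    The grid then stays fixed for the whole NVE segment: a per-step floating
    grid would make the Hamiltonian explicitly time dependent and spoil
    energy conservation.
    """
    m = topology.masses
    com = (m[:, None] * frame.positions).sum(axis=0) / m.sum()
    return grid.recentered(com)


def equilibrate(config: SimulationConfig, initial: Frame,
                topology: WaterTopology,
                ff: ForceFieldParams | None = None,
                pp: PseudopotentialParams | None = None,
                n_steps: int | None = None) -> Frame:
    """Velocity-rescaling thermostat toward the target temperature.

    Rescales every ``config.rescale_every`` steps, then returns the final
    frame (thermostat released) ready for NVE production.
    """
    ff = ff or ForceFieldParams()
    pp = pp or default_pseudopotential()
    masses = topology.masses
    n_steps = n_steps if n_steps is not None else config.n_steps
    box = initial.box_edge
    if initial.velocities is None:
        initial = replace(initial, velocities=maxwell_boltzmann_velocities(
            masses, config.temperature, config.seed))
    psi_cache: dict = {}
    if config.quantum:
        grid = _centered_grid(config.dynamics_grid, initial, topology)
        force_fn = _coupled_force_fn(topology, ff, grid, pp, box,
                                     config.solver_tol, psi_cache)
    else:
        def force_fn(x):
            return classical_forces(Frame(0.0, x, box_edge=box), topology, ff)
    x, v = initial.positions.copy(), initial.velocities.copy()
    f, u = force_fn(x)
    for step in range(1, n_steps + 1):
        x, v, f, u = verlet_step(x, v, f, masses, config.dt_fs, force_fn)
        if step % config.rescale_every == 0:
            T_now = kinetic_temperature(v, masses)
            if T_now > 1e-6:
                v *= np.sqrt(config.temperature / T_now)
            else:  # cold start: reseed from the Maxwell-Boltzmann distribution
                v = maxwell_boltzmann_velocities(masses, config.temperature,
                                                 config.seed + step)
    return Frame(n_steps * config.dt_fs, x, velocities=v, box_edge=box)
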
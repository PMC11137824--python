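"""Seeded generators of inputs with known statistical structure.

These fixtures make every other module testable without a production
simulation: single-mode harmonic trajectories with closed-form statistics
(the filter oracle), relaxed toy water clusters for mechanics and plumbing,
and toy excitation tables with prescribed gap distributions for the
spectral-statistics recovery tests.  Toy clusters validate code paths, not
physics at scale: they must never be mistaken for production ensembles.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (ExcitationTable, Frame, KB_EV_K, Trajectory,
                      WaterTopology)
from .water_qcmd import ForceFieldParams, classical_forces


# ---------------------------------------------------------------------------
# Harmonic-mode trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicSpec:
    """One classical harmonic mode.

    ``nu_fs`` in cycles/fs (use ``wavenumber_to_fs`` for cm^-1 input),
    ``mass`` in eV*fs^2/A^2.  ``deterministic`` mode emits A*cos(2 pi nu t);
    ``thermal`` mode draws amplitude and phase per replica from the
    classical Boltzmann distribution at ``T``.
    """

    nu_fs: float
    mass: float
    temperature: float
    duration_fs: float
    dt_fs: float
    seed: int = 0
    mode: str = "deterministic"
    amplitude: float = 0.1

    def __post_init__(self):
        if self.dt_fs >= 1.0 / (2.0 * self.nu_fs):
            raise ValueError("time step violates the Nyquist limit")
        if self.mode not in ("deterministic", "thermal"):
            raise ValueError("mode must be deterministic or thermal")


def harmonic_series(spec: HarmonicSpec,
                    n_replicas: int = 1) -> np.ndarray:
    """(n_replicas, n_steps) displacement series x(t) of the mode."""
    t = np.arange(0.0, spec.duration_fs, spec.dt_fs)
    omega = 2.0 * np.pi * spec.nu_fs
    if spec.mode == "deterministic":
        x = spec.amplitude * np.cos(omega * t)
        return np.tile(x, (n_replicas, 1))
    rng = np.random.default_rng(spec.seed)
    # classical thermal oscillator: x = a cos + b sin with a, b ~ N(0, kT/m w^2)
    sig = np.sqrt(KB_EV_K * spec.temperature / (spec.mass * omega**2))
    a = rng.normal(0.0, sig, n_replicas)
    b = rng.normal(0.0, sig, n_replicas)
    return (a[:, None] * np.cos(omega * t)[None, :]
            + b[:, None] * np.sin(omega * t)[None, :])


def harmonic_trajectory(spec: HarmonicSpec) -> Trajectory:
    """Single-'site' Trajectory carrying the mode on the x coordinate."""
    x = harmonic_series(spec)[0]
    pos = np.zeros((len(x), 1, 3))
    pos[:, 0, 0] = x
    return Trajectory(pos, spec.dt_fs, tag="classical")


# ---------------------------------------------------------------------------
# Toy water clusters
# ---------------------------------------------------------------------------

def _water_monomer(ff: ForceFieldParams) -> np.ndarray:
    """One water at the force-field equilibrium geometry, O at origin."""
    t = ff.theta_HOH / 2.0
    return np.array([[0.0, 0.0, 0.0],
                     [ff.r_OH * np.sin(t), 0.0, ff.r_OH * np.cos(t)],
                     [-ff.r_OH * np.sin(t), 0.0, ff.r_OH * np.cos(t)]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def toy_cluster(n: int, seed: int = 0,
                ff: ForceFieldParams | None = None,
                f_tol: float = 0.05, max_steps: int = 5000) -> Frame:
    """Relaxed toy (H2O)_n cluster.

    Waters start on a jittered spherical shell with random orientations and
    are steepest-descent relaxed on the classical force field until the
    maximum force component drops below ``f_tol`` (eV/A).  Deterministic in
    the seed.  Raises ``RuntimeError`` if relaxation stalls.
    """
    if n < 2:
        raise ValueError("cluster needs at least two molecules")
    ff = ff or ForceFieldParams()
    rng = np.random.default_rng(seed)
    topo = WaterTopology(n)
    mono = _water_monomer(ff)
    # Fibonacci shell sized to near-liquid O-O spacing, with jitter
    radius = 1.7 * n ** (1.0 / 3.0)
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * idx
    centers = radius * np.stack([np.sin(phi) * np.cos(theta),
                                 np.sin(phi) * np.sin(theta),
                                 np.cos(phi)], axis=1)
    centers += rng.normal(0.0, 0.15, centers.shape)
    pos = np.empty((3 * n, 3))
    for i in range(n):
        pos[3 * i:3 * i + 3] = centers[i] + mono @ _random_rotation(rng).T
    # steepest descent with a simple adaptive step
    step = 2e-3
    frame = Frame(0.0, pos)
    forces, energy = classical_forces(frame, topo, ff)
    for _ in range(max_steps):
        fmax = np.abs(forces).max()
        if fmax < f_tol:
            return Frame(0.0, frame.positions)
        trial = Frame(0.0, frame.positions + step * forces)
        try:
            f_new, e_new = classical_forces(trial, topo, ff)
        except FloatingPointError:
            step *= 0.5
            continue
        if e_new < energy:
            frame, forces, energy = trial, f_new, e_new
            step = min(step * 1.2, 5e-2)
        else:
            step *= 0.5
            if step < 1e-9:
                break
    raise RuntimeError("cluster relaxation failed to reach the force tolerance")


def cavity_cluster(n: int, seed: int = 0, radius: float | None = None,
                   ff: ForceFieldParams | None = None,
                   jitter: float = 0.12) -> Frame:
    """(H2O)_n shell with one OH of every molecule aimed at the center.

    The standard starting motif for excess-electron runs: a pre-formed
    cavity whose dangling hydrogens create the electron trap, which the
    coupled dynamics then equilibrates.  Geometry is built by construction
    (no relaxation, so the inward orientation survives); ``jitter`` (A)
    randomizes positions slightly.  Deterministic in the seed.
    """
    if n < 2:
        raise ValueError("cluster needs at least two molecules")
    ff = ff or ForceFieldParams()
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = max(2.9, 1.45 * n ** (1.0 / 3.0))
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    th = np.pi * (1 + np.sqrt(5.0)) * idx
    centers = radius * np.stack([np.sin(phi) * np.cos(th),
                                 np.sin(phi) * np.sin(th),
                                 np.cos(phi)], axis=1)
    centers += rng.normal(0.0, jitter, centers.shape)
    pos = np.empty((3 * n, 3))
    t = ff.theta_HOH
    for i in range(n):
        O = centers[i]
        inward = -O / np.linalg.norm(O)
        p = rng.standard_normal(3)
        p -= (p @ inward) * inward
        p /= np.linalg.norm(p)
        pos[3 * i] = O
        pos[3 * i + 1] = O + ff.r_OH * inward
        pos[3 * i + 2] = O + ff.r_OH * (np.cos(t) * inward + np.sin(t) * p)
    return Frame(0.0, pos)


# ---------------------------------------------------------------------------
# Toy excitation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyExcitationSpec:
    """Gap distributions for a synthetic transition table.

    Transition k of each configuration draws its energy from
    Normal(means[k-1], sds[k-1]); rows are re-sorted per configuration so
    gaps stay ordered in k.  ``f_rule`` is 'unit' (f = 1) or 'dipole'
    (isotropic random dipoles of the given magnitude).
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]
    n_configs: int
    seed: int = 0
    f_rule: str = "unit"
    dipole_magnitude: float = 1.0

    def __post_init__(self):
        if len(self.means) != len(self.sds):
            raise ValueError("means and sds must align")
        if any(s < 0 for s in self.sds):
            raise ValueError("gap SDs must be nonnegative")
        if self.n_configs < 1:
            raise ValueError("need at least one configuration")


def toy_excitation_table(spec: ToyExcitationSpec,
                         tag: str = "toy") -> ExcitationTable:
    rng = np.random.default_rng(spec.seed)
    K = len(spec.means)
    rows = []
    for c in range(spec.n_configs):
        gaps = rng.normal(spec.means, spec.sds)
        gaps = np.sort(np.maximum(gaps, 1e-6))
        for k in range(1, K + 1):
            row = {"config": c, "k": k, "dE_eV": gaps[k - 1]}
            if spec.f_rule == "dipole":
                mu = rng.standard_normal(3)
                mu *= spec.dipole_magnitude / np.linalg.norm(mu)
                row.update(mu_x=mu[0], mu_y=mu[1], mu_z=mu[2])
            else:
                row["f"] = 1.0
            rows.append(row)
    return ExcitationTable(pd.DataFrame(rows), tag=tag)
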
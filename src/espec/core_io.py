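"""Domain types, unit conventions and trajectory/table I/O.

Every public interface of the package exchanges quantities in a single unit
system: angstrom (length), femtosecond (time), electron-volt (energy) and
kelvin (temperature).  Masses are therefore carried in eV*fs^2/A^2 and charges
in units of the elementary charge, with the Coulomb coupling e^2/(4*pi*eps0)
expressed in eV*A.  The electron-structure code may convert to atomic units
internally, but nothing crosses a module boundary in anything else.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Unit system and physical constants (CODATA 2018)
# ---------------------------------------------------------------------------

#: Planck constant, eV*fs
H_EV_FS = 4.135667696
#: Reduced Planck constant, eV*fs
HBAR_EV_FS = 0.6582119569
#: Boltzmann constant, eV/K
KB_EV_K = 8.617333262e-5
#: Speed of light, A/fs
C_A_FS = 2997.92458
#: Electron rest mass, eV*fs^2/A^2  (m_e c^2 / c^2)
M_E = 510998.95000 / C_A_FS**2
#: Coulomb coupling e^2/(4 pi eps0), eV*A
E2_COULOMB = 14.399645478
#: Bohr radius, A
BOHR_A = 0.529177210903
#: Hartree energy, eV
HARTREE_EV = 27.211386245988
#: Atomic mass unit, eV*fs^2/A^2
AMU = 931494102.42 / C_A_FS**2

#: Conversion: wavenumber (cm^-1) -> frequency nu (fs^-1, cycles per fs)
WAVENUMBER_TO_FS = C_A_FS * 1e-8  # c in cm/fs

MASS_O = 15.999 * AMU
MASS_H = 1.008 * AMU


@dataclass(frozen=True)
class UnitSystem:
    """Bundle of the package's unit conventions and constants.

    Provided mostly for introspection and for the round-trip conversion
    helpers; modules import the module-level constants directly.
    """

    length = "angstrom"
    time = "fs"
    energy = "eV"
    temperature = "K"
    h: float = H_EV_FS
    hbar: float = HBAR_EV_FS
    k_B: float = KB_EV_K
    m_e: float = M_E
    e2: float = E2_COULOMB

    @staticmethod
    def angstrom_to_bohr(x):
        return np.asarray(x) / BOHR_A

    @staticmethod
    def bohr_to_angstrom(x):
        return np.asarray(x) * BOHR_A

    @staticmethod
    def ev_to_hartree(x):
        return np.asarray(x) / HARTREE_EV

    @staticmethod
    def hartree_to_ev(x):
        return np.asarray(x) * HARTREE_EV


UNITS = UnitSystem()


# ---------------------------------------------------------------------------
# Topology and frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterTopology:
    """Water-only topology with per-molecule O,H,H site ordering.

    Site ``3*i`` is the oxygen of molecule ``i`` and sites ``3*i+1``,
    ``3*i+2`` its hydrogens.
    """

    n_molecules: int
    charge_O: float = -0.82
    charge_H: float = 0.41

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("topology needs at least one molecule")
        if abs(self.charge_O + 2 * self.charge_H) > 1e-12:
            raise ValueError("per-molecule charges must sum to zero")

    @property
    def n_sites(self) -> int:
        return 3 * self.n_molecules

    @property
    def symbols(self) -> list[str]:
        return ["O", "H", "H"] * self.n_molecules

    @property
    def masses(self) -> np.ndarray:
        return np.tile([MASS_O, MASS_H, MASS_H], self.n_molecules)

    @property
    def charges(self) -> np.ndarray:
        return np.tile([self.charge_O, self.charge_H, self.charge_H],
                       self.n_molecules)

    def molecule_sites(self, i: int) -> slice:
        return slice(3 * i, 3 * i + 3)

    @property
    def oxygen_indices(self) -> np.ndarray:
        return np.arange(self.n_molecules) * 3

    @property
    def hydrogen_indices(self) -> np.ndarray:
        o = self.oxygen_indices
        return np.sort(np.concatenate([o + 1, o + 2]))


@dataclass
class Frame:
    """One snapshot: positions (A), optional velocities (A/fs), optional box."""

    time_fs: float
    positions: np.ndarray
    velocities: np.ndarray | None = None
    box_edge: float | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sites, 3)")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")
        if self.box_edge is not None and self.box_edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Uniformly spaced, time-ordered frames stored as dense arrays.

    ``positions`` has shape (n_frames, n_sites, 3); time stamps are
    synthesized from ``t0`` and ``dt_fs`` so uniform spacing holds by
    construction (the moving-window filter requires it).
    """

    positions: np.ndarray
    dt_fs: float
    topology: WaterTopology | None = None
    velocities: np.ndarray | None = None
    box_edge: float | None = None
    t0: float = 0.0
    tag: str = "classical"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_sites, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.dt_fs <= 0:
            raise ValueError("frame spacing must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")
        if (self.topology is not None
                and self.positions.shape[1] != self.topology.n_sites):
            raise ValueError("site count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt_fs * np.arange(self.n_frames)

    def frame(self, i: int) -> Frame:
        v = None if self.velocities is None else self.velocities[i]
        return Frame(self.times[i], self.positions[i], v, self.box_edge)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def strided(self, stride: int) -> "Trajectory":
        """Every ``stride``-th frame (spectral sub-sampling)."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        v = None if self.velocities is None else self.velocities[::stride]
        return replace(self, positions=self.positions[::stride],
                       velocities=v, dt_fs=self.dt_fs * stride)


# ---------------------------------------------------------------------------
# Excitation tables
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("config", "k", "dE_eV")
_DIPOLE_COLS = ("mu_x", "mu_y", "mu_z")


@dataclass
class ExcitationTable:
    """Per-configuration vertical transitions feeding spectrum assembly.

    One row per (configuration, transition k): transition energy ``dE_eV``
    plus either a transition-dipole vector (e*A) or a precomputed oscillator
    strength ``f``.  Tables with only ``f`` are flagged ``f_only``.
    """

    df: pd.DataFrame
    tag: str = ""

    def __post_init__(self):
        df = self.df
        for c in _REQUIRED_COLS:
            if c not in df.columns:
                raise ValueError(f"missing column {c!r}")
        has_mu = all(c in df.columns for c in _DIPOLE_COLS)
        has_f = "f" in df.columns
        if not (has_mu or has_f):
            raise ValueError("need dipole components or an f column")
        if (df["dE_eV"] <= 0).any():
            raise ValueError("transition energies must be positive")
        if df.duplicated(subset=["config", "k"]).any():
            raise ValueError("duplicate (configuration, k) pairs")
        df = df.sort_values(["config", "k"], kind="stable").reset_index(drop=True)
        for _, grp in df.groupby("config"):
            d = grp["dE_eV"].to_numpy()
            if np.any(np.diff(d) < -1e-9):
                raise ValueError("transition energies must be nondecreasing in k")
        if not has_f:
            mu2 = (df[list(_DIPOLE_COLS)].to_numpy() ** 2).sum(axis=1)
            df = df.assign(
                f=2.0 * M_E * df["dE_eV"].to_numpy() * mu2 / (3.0 * HBAR_EV_FS**2))
        if (df["f"] < -1e-12).any():
            raise ValueError("oscillator strengths must be nonnegative")
        object.__setattr__(self, "df", df)
        object.__setattr__(self, "f_only", not has_mu)

    @property
    def K(self) -> int:
        return int(self.df["k"].max())

    @property
    def n_configs(self) -> int:
        return self.df["config"].nunique()

    def energies(self, k: int | None = None) -> np.ndarray:
        if k is None:
            return self.df["dE_eV"].to_numpy()
        return self.df.loc[self.df["k"] == k, "dE_eV"].to_numpy()

    def strengths(self, k: int | None = None) -> np.ndarray:
        if k is None:
            return self.df["f"].to_numpy()
        return self.df.loc[self.df["k"] == k, "f"].to_numpy()


def read_excitation_table(path: str | Path, tag: str = "") -> ExcitationTable:
    """Read a delimited (TSV/CSV) excitation table; see :class:`ExcitationTable`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    return ExcitationTable(df, tag=tag or path.stem)


def write_excitation_table(table: ExcitationTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.df.to_csv(path, sep=sep, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ trajectories
# ---------------------------------------------------------------------------
# Minimal extended-XYZ support written in-house: the environment's MD readers
# do not cover velocity columns and per-frame Lattice/Time comments in the
# extended-XYZ dialect, and the reader must synthesize uniform time stamps.

_VALID_ELEMENTS = {"O", "H"}


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as extended-XYZ (box and time in the comment line)."""
    symbols = (traj.topology.symbols if traj.topology is not None
               else ["X"] * traj.n_sites)
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{traj.n_sites}\n")
            props = "species:S:1:pos:R:3"
            if fr.velocities is not None:
                props += ":vel:R:3"
            comment = f'Properties={props} Time={fr.time_fs:.6f}'
            if fr.box_edge is not None:
                b = fr.box_edge
                comment += (f' Lattice="{b:.6f} 0 0 0 {b:.6f} 0 0 0 {b:.6f}"')
            fh.write(comment + "\n")
            for s in range(traj.n_sites):
                x, y, z = fr.positions[s]
                row = f"{symbols[s]:2s} {x:15.6f} {y:15.6f} {z:15.6f}"
                if fr.velocities is not None:
                    vx, vy, vz = fr.velocities[s]
                    row += f" {vx:15.8f} {vy:15.8f} {vz:15.8f}"
                fh.write(row + "\n")


def read_xyz_trajectory(path: str | Path,
                        topology: WaterTopology | None,
                        dt_fs: float,
                        tag: str = "classical") -> Trajectory:
    """Read an (extended-)XYZ trajectory with a constant atom count.

    Time stamps are synthesized from ``dt_fs`` (uniform spacing by
    construction); element symbols are validated against the water topology
    when one is given.
    """
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    box_edge = None
    n_expected = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                nat = int(header.split()[0])
            except ValueError as exc:
                raise ValueError(f"bad XYZ frame header: {header!r}") from exc
            if n_expected is None:
                n_expected = nat
            elif nat != n_expected:
                raise ValueError("inconsistent atom count between frames")
            comment = fh.readline()
            if 'Lattice="' in comment:
                lat = comment.split('Lattice="')[1].split('"')[0].split()
                box_edge = float(lat[0])
            pos = np.empty((nat, 3))
            vel = None
            for i in range(nat):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise ValueError("truncated atom row")
                sym = parts[0]
                if topology is not None:
                    if sym not in _VALID_ELEMENTS:
                        raise ValueError(f"non-water element {sym!r}")
                    if sym != topology.symbols[i]:
                        raise ValueError(
                            f"element {sym!r} at site {i} does not match "
                            f"topology order (expected {topology.symbols[i]!r})")
                pos[i] = [float(v) for v in parts[1:4]]
                if len(parts) >= 7:
                    if vel is None:
                        vel = np.empty((nat, 3))
                    vel[i] = [float(v) for v in parts[4:7]]
            frames_pos.append(pos)
            if vel is not None:
                frames_vel.append(vel)
    if not frames_pos:
        raise ValueError("empty trajectory file")
    if topology is not None and n_expected != topology.n_sites:
        raise ValueError("atom count does not match topology")
    velocities = (np.stack(frames_vel)
                  if len(frames_vel) == len(frames_pos) else None)
    return Trajectory(np.stack(frames_pos), dt_fs, topology=topology,
                      velocities=velocities, box_edge=box_edge, tag=tag)


# ---------------------------------------------------------------------------
# HDF5 trajectory store (dense 0.5 fs trajectories are impractical as text)
# ---------------------------------------------------------------------------

def save_trajectory_h5(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=traj.positions,
                          compression="gzip", compression_opts=4)
        if traj.velocities is not None:
            h5.create_dataset("velocities", data=traj.velocities,
                              compression="gzip", compression_opts=4)
        h5.attrs["dt_fs"] = traj.dt_fs
        h5.attrs["t0"] = traj.t0
        h5.attrs["tag"] = traj.tag
        if traj.box_edge is not None:
            h5.attrs["box_edge"] = traj.box_edge
        if traj.topology is not None:
            h5.attrs["n_molecules"] = traj.topology.n_molecules
            h5.attrs["charge_O"] = traj.topology.charge_O


def load_trajectory_h5(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        pos = h5["positions"][...]
        vel = h5["velocities"][...] if "velocities" in h5 else None
        topo = None
        if "n_molecules" in h5.attrs:
            qo = float(h5.attrs.get("charge_O", -0.82))
            topo = WaterTopology(int(h5.attrs["n_molecules"]),
                                 charge_O=qo, charge_H=-qo / 2)
        return Trajectory(pos, float(h5.attrs["dt_fs"]), topology=topo,
                          velocities=vel,
                          box_edge=(float(h5.attrs["box_edge"])
                                    if "box_edge" in h5.attrs else None),
                          t0=float(h5.attrs["t0"]),
                          tag=str(h5.attrs["tag"]))
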
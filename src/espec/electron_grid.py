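"""One-electron pseudopotential Hamiltonian on a cubic grid.

The excess electron is described by a real wavefunction sampled on an
``M x M x M`` periodic cubic grid of edge ``L``.  The kinetic operator is
applied spectrally (FFT), the electron-water interaction is a sum of smooth
per-site terms: an erf-screened Coulomb tail matching the water model's
partial charges plus short-range Gaussian core repulsion.  The lowest
``K + 1`` eigenpairs give the ground state, the vertical transition energies
``dE_k = E_k - E_0``, transition dipoles and oscillator strengths that feed
the absorption-spectrum assembly; the Hellmann-Feynman average of the
potential gradient gives the quantum force on each water site during the
mixed quantum-classical dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.sparse.linalg import LinearOperator, lobpcg
from scipy.special import erf

from .core_io import E2_COULOMB, Frame, HBAR_EV_FS, M_E, WaterTopology

_SQRT_PI = np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Cubic grid: edge ``L`` (A), ``M`` points per dimension, center origin."""

    L: float
    M: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("grid edge must be positive")
        if self.M < 2 or (self.M & (self.M - 1)) != 0:
            raise ValueError("points per dimension must be a power of two")

    @property
    def spacing(self) -> float:
        return self.L / self.M

    @property
    def n_points(self) -> int:
        return self.M**3

    @property
    def weight(self) -> float:
        """Quadrature weight of one grid point (A^3)."""
        return self.spacing**3

    def axes(self) -> np.ndarray:
        """1D coordinates along one axis relative to the cube center."""
        return (np.arange(self.M) - self.M // 2) * self.spacing

    def points(self) -> np.ndarray:
        """(M^3, 3) Cartesian coordinates of all grid points."""
        ax = self.axes()
        X, Y, Z = np.meshgrid(ax + self.origin[0], ax + self.origin[1],
                              ax + self.origin[2], indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def recentered(self, center: np.ndarray) -> "GridSpec":
        return GridSpec(self.L, self.M, tuple(np.asarray(center, float)))


# ---------------------------------------------------------------------------
# Pseudopotential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteTerm:
    """Per-site electron-water term, all in eV/A units.

    V(r) = -q * e2 * erf(A r) / r  +  sum_j B_j * exp(-C_j r^2)

    ``q`` is the site partial charge in elementary charges (the leading minus
    sign carries the electron's negative charge), ``A`` the inverse screening
    length (1/A); beyond a few screening lengths the term is the bare
    Coulomb interaction -q*e2/r.
    """

    q: float
    A: float
    B: tuple[float, ...] = ()
    C: tuple[float, ...] = ()

    def value(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        # erf(A r)/r is finite (2A/sqrt(pi)) at r = 0
        small = r < 1e-12
        rs = np.where(small, 1.0, r)
        coul = np.where(small, 2.0 * self.A / _SQRT_PI,
                        erf(self.A * rs) / rs)
        v = -self.q * E2_COULOMB * coul
        for b, c in zip(self.B, self.C):
            v = v + b * np.exp(-c * r * r)
        return v

    def radial_derivative(self, r: np.ndarray) -> np.ndarray:
        """dV/dr, finite everywhere (-> 0 as r -> 0)."""
        r = np.asarray(r, dtype=float)
        small = r < 1e-8
        rs = np.where(small, 1.0, r)
        dcoul = (2.0 * self.A / _SQRT_PI * np.exp(-(self.A * rs) ** 2) / rs
                 - erf(self.A * rs) / rs**2)
        dcoul = np.where(small, 0.0, dcoul)
        dv = -self.q * E2_COULOMB * dcoul
        for b, c in zip(self.B, self.C):
            dv = dv - 2.0 * b * c * r * np.exp(-c * r * r)
        return dv


@dataclass(frozen=True)
class PseudopotentialParams:
    O: SiteTerm
    H: SiteTerm

    def term(self, element: str) -> SiteTerm:
        try:
            return getattr(self, element)
        except AttributeError as exc:
            raise KeyError(f"no pseudopotential term for site {element!r}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PseudopotentialParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = raw["sites"] if "sites" in raw else raw
        terms = {}
        for el in ("O", "H"):
            if el not in sites:
                raise KeyError(f"parameter file missing site type {el!r}")
            s = sites[el]
            terms[el] = SiteTerm(q=float(s["q"]), A=float(s["A"]),
                                 B=tuple(float(b) for b in s.get("B", [])),
                                 C=tuple(float(c) for c in s.get("C", [])))
        return cls(O=terms["O"], H=terms["H"])


def default_pseudopotential() -> PseudopotentialParams:
    """Shipped default electron-water parameter set (data/pseudopotential.yaml)."""
    return PseudopotentialParams.from_yaml(
        Path(__file__).parent / "data" / "pseudopotential.yaml")


def build_potential_grid(frame: Frame, topology: WaterTopology,
                         grid: GridSpec,
                         params: PseudopotentialParams) -> np.ndarray:
    """Total electron-water potential at every grid point, eV, shape (M,M,M).

    The sum runs over all sites of all molecules; the minimum-image
    convention is applied when the frame carries a periodic box.
    """
    pts = grid.points()
    V = np.zeros(grid.n_points)
    symbols = topology.symbols
    box = frame.box_edge
    for s in range(topology.n_sites):
        d = pts - frame.positions[s]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        V += params.term(symbols[s]).value(r)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite pseudopotential value on grid")
    return V.reshape(grid.M, grid.M, grid.M)


# ---------------------------------------------------------------------------
# Eigensolver
# ---------------------------------------------------------------------------

@dataclass
class ElectronStates:
    """Lowest eigenpairs of the grid Hamiltonian.

    ``energies`` ascending (eV); ``wavefunctions`` shape (K+1, M, M, M),
    real, L2-normalized with the grid quadrature weight; transition
    quantities are filled in by :func:`transition_dipoles` /
    :func:`oscillator_strengths`.
    """

    energies: np.ndarray
    wavefunctions: np.ndarray
    grid: GridSpec
    residuals: np.ndarray
    dipoles: np.ndarray | None = None
    strengths: np.ndarray | None = None
    block: np.ndarray | None = None  # raw solver block, for warm restarts

    @property
    def gaps(self) -> np.ndarray:
        return self.energies[1:] - self.energies[0]

    @property
    def K(self) -> int:
        return len(self.energies) - 1


def _kinetic_factors(grid: GridSpec) -> np.ndarray:
    k1 = 2.0 * np.pi * np.fft.fftfreq(grid.M, d=grid.spacing)
    KX, KY, KZ = np.meshgrid(k1, k1, k1, indexing="ij")
    return (HBAR_EV_FS**2 / (2.0 * M_E)) * (KX**2 + KY**2 + KZ**2)


def apply_hamiltonian(psi: np.ndarray, V: np.ndarray,
                      tk: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(tk * np.fft.fftn(psi)).real + V * psi


def solve_states(V: np.ndarray, grid: GridSpec, K: int,
                 tol: float = 1e-10, seed: int = 0,
                 v0: np.ndarray | None = None,
                 maxiter: int = 2000) -> ElectronStates:
    """Lowest ``K + 1`` eigenpairs of ``T + V`` by a blocked iterative solver.

    Uses LOBPCG with a block of at least ``max(K + 5, 4)`` vectors (the
    extra vectors resolve the near-degenerate p manifold) and an FFT
    kinetic-energy preconditioner.  The start block is seeded, optionally
    warm-started from ``v0`` (previous ground state or previous block), so
    reruns are deterministic.  Raises ``RuntimeError`` on non-convergence,
    reporting the residual norms reached.
    """
    M = grid.M
    n = M**3
    if K + 1 >= n:
        raise ValueError("requested more states than grid points")
    tk = _kinetic_factors(grid)
    Vf = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(Vf)):
        raise FloatingPointError("potential must be finite")

    def matvec(x):
        return apply_hamiltonian(x.reshape(M, M, M), Vf, tk).ravel()

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    # kinetic preconditioner: (T + shift)^-1 applied spectrally
    shift = max(1.0, float(np.ptp(Vf)) * 0.1)
    pk = 1.0 / (tk + shift)

    def precond(x):
        if x.ndim == 1:
            return np.fft.ifftn(pk * np.fft.fftn(x.reshape(M, M, M))).real.ravel()
        return np.stack([np.fft.ifftn(pk * np.fft.fftn(c.reshape(M, M, M)))
                         .real.ravel() for c in x.T], axis=1)

    prec = LinearOperator((n, n), matvec=precond, matmat=precond, dtype=float)
    # the ground state is non-degenerate, so a K=0 solve runs single-vector;
    # excited manifolds get 4 guard vectors to resolve near-degeneracies
    block = min(1 if K == 0 else K + 5, n - 1)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, block))
    if v0 is not None:
        v0 = np.asarray(v0)
        if v0.ndim == 1:
            X[:, 0] = v0.ravel()
        else:
            m = min(v0.shape[1], block)
            X[:, :m] = v0[:, :m]
    scale = max(1.0, float(np.abs(Vf).max()))
    import warnings
    with np.errstate(invalid="ignore", over="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*postprocessing.*")
        warnings.filterwarnings("ignore", message=".*Exited at iteration.*")
        vals, vecs = lobpcg(op, X, M=prec, tol=tol * scale,
                            maxiter=maxiter, largest=False)
    order_full = np.argsort(vals)
    vecs_full = vecs[:, order_full]
    order = order_full[: K + 1]
    vals = vals[order]
    vecs = vecs[:, order]
    # grid-quadrature normalization and deterministic global sign
    w = grid.weight
    psis = np.empty((K + 1, M, M, M))
    res = np.empty(K + 1)
    for i in range(K + 1):
        v = vecs[:, i]
        v = v / (np.linalg.norm(v) * np.sqrt(w))
        j = np.argmax(np.abs(v))
        if v[j] < 0:
            v = -v
        res[i] = np.linalg.norm(matvec(v) - vals[i] * v) * np.sqrt(w)
        psis[i] = v.reshape(M, M, M)
    if res.max() > max(1e-5, 1e3 * tol * scale):
        raise RuntimeError(
            f"eigensolver did not converge within {maxiter} iterations; "
            f"residual norms {res}")
    return ElectronStates(energies=vals, wavefunctions=psis, grid=grid,
                          residuals=res, block=vecs_full)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def _grid_coords(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = grid.axes()
    return np.meshgrid(ax + grid.origin[0], ax + grid.origin[1],
                       ax + grid.origin[2], indexing="ij")


def ground_state_centroid(states: ElectronStates) -> np.ndarray:
    """<psi_0| r |psi_0> in A."""
    X, Y, Z = _grid_coords(states.grid)
    rho = states.wavefunctions[0] ** 2 * states.grid.weight
    return np.array([np.sum(rho * X), np.sum(rho * Y), np.sum(rho * Z)])


def transition_dipoles(states: ElectronStates) -> np.ndarray:
    """mu_k0 = <psi_k| (r - r_centroid) |psi_0>, e*A, shape (K, 3).

    The origin sits at the ground-state centroid; between orthogonal states
    the dipoles are origin-independent, the gauge only fixes diagnostics.
    """
    X, Y, Z = _grid_coords(states.grid)
    c = ground_state_centroid(states)
    psi0 = states.wavefunctions[0]
    w = states.grid.weight
    mus = np.empty((states.K, 3))
    for k in range(1, states.K + 1):
        p = states.wavefunctions[k] * psi0 * w
        mus[k - 1] = [np.sum(p * (X - c[0])), np.sum(p * (Y - c[1])),
                      np.sum(p * (Z - c[2]))]
    states.dipoles = mus
    return mus


def oscillator_strengths(states: ElectronStates) -> np.ndarray:
    """f_k = 2 m_e dE_k |mu_k0|^2 / (3 hbar^2), dimensionless."""
    if states.dipoles is None:
        transition_dipoles(states)
    mu2 = np.einsum("kj,kj->k", states.dipoles, states.dipoles)
    f = 2.0 * M_E * states.gaps * mu2 / (3.0 * HBAR_EV_FS**2)
    states.strengths = f
    return f


def radius_of_gyration(states: ElectronStates) -> float:
    """sqrt(<psi_0| (r - <r>)^2 |psi_0>) in A."""
    X, Y, Z = _grid_coords(states.grid)
    rho = states.wavefunctions[0] ** 2 * states.grid.weight
    c = ground_state_centroid(states)
    var = (np.sum(rho * (X - c[0]) ** 2) + np.sum(rho * (Y - c[1]) ** 2)
           + np.sum(rho * (Z - c[2]) ** 2))
    return float(np.sqrt(var))


def hellmann_feynman_forces(frame: Frame, topology: WaterTopology,
                            states: ElectronStates,
                            params: PseudopotentialParams) -> np.ndarray:
    """Quantum force on each water site, eV/A, shape (n_sites, 3).

    F_site = -<psi_0| dV/dR_site |psi_0>; the site-term gradient is analytic
    and finite everywhere (the erf screening removes the Coulomb cusp), and
    the expectation value is a grid quadrature over |psi_0|^2.
    """
    grid = states.grid
    pts = grid.points()
    rho = (states.wavefunctions[0] ** 2).ravel() * grid.weight
    box = frame.box_edge
    forces = np.zeros((topology.n_sites, 3))
    symbols = topology.symbols
    for s in range(topology.n_sites):
        d = pts - frame.positions[s]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dv = params.term(symbols[s]).radial_derivative(r)
        rsafe = np.where(r < 1e-12, 1.0, r)
        # dV/dR = -V'(r) * rhat  =>  F = -<dV/dR> = +<V'(r) rhat>
        g = rho * dv / rsafe
        forces[s] = g @ d
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite Hellmann-Feynman force")
    return forces
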
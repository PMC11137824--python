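"""Structural observables and the OH-bond-scaling transform.

Covers the electron-centroid radial distribution functions (e-H, e-O), the
intramolecular OH-distance distribution, and the configuration transform
that rescales both OH bond lengths of every molecule by a constant factor
while leaving each molecule's center of mass, principal inertia axes and
HOH angle untouched (the probe used to connect OH-amplitude changes to
spectral shifts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_io import Frame, Trajectory, WaterTopology


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RDFSpec:
    """Bin width and range of a radial distribution function (A).

    ``normalization`` is ``bulk-density`` (periodic systems: ideal-gas count
    from N/V) or ``cluster-shell-count`` (finite systems: the uniform
    reference is the same frame's site count spread over the probed sphere).
    """

    bin_width: float = 0.1
    r_max: float = 8.0
    normalization: str = "bulk-density"

    def __post_init__(self):
        if self.bin_width <= 0 or self.r_max <= self.bin_width:
            raise ValueError("bad RDF binning")
        if self.normalization not in ("bulk-density", "cluster-shell-count"):
            raise ValueError("unknown normalization mode")


def electron_site_rdf(positions: np.ndarray, centroids: np.ndarray,
                      spec: RDFSpec,
                      box_edge: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """g(r) between one electron centroid per frame and a site selection.

    ``positions``: (n_frames, n_sel, 3) site coordinates; ``centroids``:
    (n_frames, 3).  Periodic mode requires ``r_max <= box/2``.
    Returns (bin centers, g).
    """
    positions = np.asarray(positions, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if box_edge is not None and spec.r_max > box_edge / 2 + 1e-9:
        raise ValueError("r_max exceeds half the box edge")
    edges = np.arange(0.0, spec.r_max + spec.bin_width, spec.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    d = positions - centroids[:, None, :]
    if box_edge is not None:
        d -= box_edge * np.round(d / box_edge)
    r = np.linalg.norm(d, axis=2).ravel()
    counts, _ = np.histogram(r, bins=edges)
    n_frames, n_sel = positions.shape[:2]
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if spec.normalization == "bulk-density":
        if box_edge is None:
            raise ValueError("bulk-density normalization needs a box")
        rho = n_sel / box_edge**3
        expected = rho * shell_vol * n_frames
    else:
        # uniform reference inside the probed sphere of the finite system
        v_tot = 4.0 / 3.0 * np.pi * spec.r_max**3
        expected = n_sel * shell_vol / v_tot * n_frames
    g = np.where(expected > 0, counts / expected, 0.0)
    return centers, g


# ---------------------------------------------------------------------------
# OH-distance distribution
# ---------------------------------------------------------------------------

@dataclass
class OHDistribution:
    centers: np.ndarray
    density: np.ndarray   # normalized to unit integral
    mean: float
    sd: float


def oh_distances(traj: Trajectory) -> np.ndarray:
    """All intramolecular OH bond lengths over all frames, flattened."""
    if traj.topology is None:
        raise ValueError("trajectory has no water topology")
    n = traj.topology.n_molecules
    o = traj.positions[:, 0::3]
    h1 = traj.positions[:, 1::3]
    h2 = traj.positions[:, 2::3]
    d1 = np.linalg.norm(h1 - o, axis=2)
    d2 = np.linalg.norm(h2 - o, axis=2)
    return np.concatenate([d1.ravel(), d2.ravel()])


def oh_distance_distribution(traj: Trajectory,
                             bin_width: float = 0.005) -> OHDistribution:
    r = oh_distances(traj)
    lo = max(r.min() - 5 * bin_width, 0.0)
    edges = np.arange(lo, r.max() + 6 * bin_width, bin_width)
    h, _ = np.histogram(r, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return OHDistribution(centers, h, float(r.mean()), float(r.std()))


# ---------------------------------------------------------------------------
# OH bond scaling
# ---------------------------------------------------------------------------

def _principal_frame(p: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center of mass and a deterministically signed principal-axis rotation.

    Axes are the inertia-tensor eigenvectors ordered by eigenvalue; signs
    are fixed from the molecular geometry (O->COM projection, H1->H2
    projection, right-handed third axis) so the frame varies continuously
    under small geometry changes.
    """
    com = (m[:, None] * p).sum(axis=0) / m.sum()
    q = p - com
    inertia = np.einsum("i,ij,ik->jk", m, q, q)
    I = np.trace(inertia) * np.eye(3) - inertia
    vals, vecs = np.linalg.eigh(I)
    a1, a2, a3 = vecs[:, 0], vecs[:, 1], vecs[:, 2]
    ref1 = q[0]            # O relative to COM: along the bisector
    ref2 = p[2] - p[1]     # H1 -> H2
    if a1 @ ref1 < 0:
        a1 = -a1
    if a2 @ ref2 < 0:
        a2 = -a2
    a3 = np.cross(a1, a2)
    return com, np.stack([a1, a2, a3], axis=1)


def scale_oh_bonds(frame: Frame, topology: WaterTopology,
                   f: float) -> Frame:
    """Scale both OH bond lengths of every molecule by ``f``.

    Bonds are scaled about the oxygen (the HOH angle is automatically
    unchanged), then the molecule is rigidly re-embedded so its center of
    mass and principal inertia axes equal the originals.  ``f = 1`` is the
    identity and applying ``f`` then ``1/f`` returns the input.
    """
    if f <= 0:
        raise ValueError("scale factor must be positive")
    masses = np.array([topology.masses[0], topology.masses[1],
                       topology.masses[2]])
    new_pos = frame.positions.copy()
    for mol in range(topology.n_molecules):
        sl = topology.molecule_sites(mol)
        p = frame.positions[sl]
        com0, R0 = _principal_frame(p, masses)
        q = p.copy()
        q[1] = q[0] + f * (q[1] - q[0])
        q[2] = q[0] + f * (q[2] - q[0])
        com1, R1 = _principal_frame(q, masses)
        new_pos[sl] = com0 + (q - com1) @ R1 @ R0.T
    return replace(frame, positions=new_pos, velocities=None)


def scale_trajectory(traj: Trajectory, f: float) -> Trajectory:
    frames = [scale_oh_bonds(traj.frame(i), traj.topology, f).positions
              for i in range(traj.n_frames)]
    return replace(traj, positions=np.stack(frames), velocities=None,
                   tag=f"scaled:{f:g}")


# ---------------------------------------------------------------------------
# Scaling ladder
# ---------------------------------------------------------------------------

@dataclass
class ScalingLadderReport:
    """Per-factor means and trends of the OH-scaling probe.

    ``e0_slope`` / ``gap_slope`` are least-squares slopes of the mean
    ground-state energy and the mean first gap against the scale factor,
    with standard errors; the monotonicity flags report strict ordering of
    the per-factor means.
    """

    factors: np.ndarray
    mean_e0: np.ndarray
    mean_gap1: np.ndarray
    e0_slope: float
    e0_slope_stderr: float
    gap_slope: float
    gap_slope_stderr: float
    e0_decreasing: bool
    gap_increasing: bool


def scaling_ladder(factors, mean_e0, mean_gap1) -> ScalingLadderReport:
    """Trend report over the bond-scaling ladder.

    ``mean_e0``: per-factor mean ground-state energy (eV); ``mean_gap1``:
    per-factor mean first transition energy (eV).
    """
    factors = np.asarray(factors, dtype=float)
    mean_e0 = np.asarray(mean_e0, dtype=float)
    mean_gap1 = np.asarray(mean_gap1, dtype=float)
    if len(factors) < 2:
        raise ValueError("need at least two scale factors")
    order = np.argsort(factors)
    factors, mean_e0, mean_gap1 = factors[order], mean_e0[order], mean_gap1[order]
    r0 = stats.linregress(factors, mean_e0)
    r1 = stats.linregress(factors, mean_gap1)
    return ScalingLadderReport(
        factors=factors, mean_e0=mean_e0, mean_gap1=mean_gap1,
        e0_slope=float(r0.slope), e0_slope_stderr=float(r0.stderr),
        gap_slope=float(r1.slope), gap_slope_stderr=float(r1.stderr),
        e0_decreasing=bool(np.all(np.diff(mean_e0) < 0)),
        gap_increasing=bool(np.all(np.diff(mean_gap1) > 0)))
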
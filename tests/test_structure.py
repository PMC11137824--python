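"""RDFs, OH-distance distributions and the bond-scaling transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from espec import (ForceFieldParams, Frame, RDFSpec, Trajectory,
                   WaterTopology, electron_site_rdf, oh_distance_distribution,
                   scale_oh_bonds, scaling_ladder)
from espec.core_io import KB_EV_K
from espec.structure import _principal_frame


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        box = 20.0
        n_frames, n_sites = 40, 500
        pos = rng.uniform(0, box, (n_frames, n_sites, 3))
        cent = rng.uniform(0, box, (n_frames, 3))
        spec = RDFSpec(bin_width=0.5, r_max=8.0)
        r, g = electron_site_rdf(pos, cent, spec, box_edge=box)
        counts = n_frames * n_sites * 4 * np.pi * r**2 * 0.5 * (n_sites / box**3) / n_sites
        sel = r > 1.0  # skip tiny-count inner bins
        assert np.abs(g[sel] - 1.0).max() < 0.15

    def test_single_site_lands_in_its_bin(self):
        pos = np.zeros((1, 1, 3))
        pos[0, 0] = [3.0, 0.0, 0.0]
        cent = np.zeros((1, 3))
        spec = RDFSpec(bin_width=0.2, r_max=5.0,
                       normalization="cluster-shell-count")
        r, g = electron_site_rdf(pos, cent, spec)
        assert np.count_nonzero(g) == 1
        assert abs(r[np.argmax(g)] - 3.0) < 0.2

    def test_rmax_beyond_half_box_rejected(self):
        with pytest.raises(ValueError):
            electron_site_rdf(np.zeros((1, 1, 3)), np.zeros((1, 3)),
                              RDFSpec(r_max=11.0), box_edge=20.0)

    def test_cluster_normalization_recovers_site_count(self):
        # uniform sites in the probed sphere: integral of g over the ideal
        # shell counts returns the total number of deposited sites
        rng = np.random.default_rng(1)
        n_sites = 2000
        u = rng.normal(size=(n_sites, 3))
        r = 6.0 * rng.uniform(0, 1, n_sites) ** (1 / 3)
        pos = (u / np.linalg.norm(u, axis=1)[:, None] * r[:, None])[None]
        spec = RDFSpec(bin_width=0.3, r_max=6.0,
                       normalization="cluster-shell-count")
        rb, g = electron_site_rdf(pos, np.zeros((1, 3)), spec)
        edges = np.arange(0.0, 6.0 + 0.3, 0.3)
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal = n_sites * shell / (4 / 3 * np.pi * 6.0**3)
        assert np.sum(g * ideal) == pytest.approx(n_sites, rel=0.01)


class TestOHDistribution:
    def test_rigid_geometry_is_delta(self):
        topo = WaterTopology(1)
        pos = np.array([[[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]])
        traj = Trajectory(np.repeat(pos, 5, axis=0), 0.5, topology=topo)
        d = oh_distance_distribution(traj)
        assert d.mean == pytest.approx(1.0, abs=1e-12)
        assert d.sd == pytest.approx(0.0, abs=1e-12)

    def test_thermal_sd_matches_equipartition(self):
        # OH lengths sampled from the classical Boltzmann distribution of the
        # harmonic stretch: SD = sqrt(kT / k_stretch)
        ff = ForceFieldParams()
        T = 300.0
        sd_want = np.sqrt(KB_EV_K * T / ff.k_stretch)
        rng = np.random.default_rng(2)
        n_frames = 4000
        topo = WaterTopology(1)
        pos = np.zeros((n_frames, 3, 3))
        r1 = rng.normal(ff.r_OH, sd_want, n_frames)
        r2 = rng.normal(ff.r_OH, sd_want, n_frames)
        pos[:, 1, 0] = r1
        pos[:, 2, 1] = r2
        traj = Trajectory(pos, 0.5, topology=topo)
        d = oh_distance_distribution(traj)
        assert d.sd == pytest.approx(sd_want, rel=0.05)


class TestScaleTransform:
    def water(self, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.deg2rad(109.47)
        pos = np.array([[0.0, 0, 0],
                        [np.sin(t / 2), 0, np.cos(t / 2)],
                        [-np.sin(t / 2), 0, np.cos(t / 2)]])
        if jitter:
            pos = pos + rng.normal(0, jitter, pos.shape)
        # random rigid placement
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([[1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                      [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                      [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        return pos @ R.T + rng.normal(0, 2.0, 3)

    def test_identity_factor(self):
        topo = WaterTopology(2)
        pos = np.vstack([self.water(seed=1), self.water(seed=2)])
        fr = Frame(0.0, pos)
        out = scale_oh_bonds(fr, topo, 1.0)
        assert np.abs(out.positions - pos).max() < 1e-12

    @pytest.mark.parametrize("f", [0.9, 1.1])
    def test_geometry_preserved(self, f):
        topo = WaterTopology(3)
        pos = np.vstack([self.water(jitter=0.03, seed=s) for s in (3, 4, 5)])
        fr = Frame(0.0, pos)
        out = scale_oh_bonds(fr, topo, f)
        masses = topo.masses[:3]
        for m in range(3):
            p0 = pos[3 * m:3 * m + 3]
            p1 = out.positions[3 * m:3 * m + 3]
            # OH lengths exactly scaled
            for h in (1, 2):
                assert (np.linalg.norm(p1[h] - p1[0])
                        == pytest.approx(f * np.linalg.norm(p0[h] - p0[0]),
                                         abs=1e-10))
            # HOH angle unchanged
            def ang(p):
                d1, d2 = p[1] - p[0], p[2] - p[0]
                return np.arccos(d1 @ d2 / np.linalg.norm(d1)
                                 / np.linalg.norm(d2))
            assert ang(p1) == pytest.approx(ang(p0), abs=1e-10)
            # COM and principal axes preserved
            com0, R0 = _principal_frame(p0, masses)
            com1, R1 = _principal_frame(p1, masses)
            assert np.abs(com1 - com0).max() < 1e-10
            assert np.abs(R1 - R0).max() < 1e-9

    def test_inverse_composition(self):
        topo = WaterTopology(2)
        pos = np.vstack([self.water(jitter=0.02, seed=6),
                         self.water(jitter=0.02, seed=7)])
        fr = Frame(0.0, pos)
        back = scale_oh_bonds(scale_oh_bonds(fr, topo, 1.1), topo, 1 / 1.1)
        assert np.abs(back.positions - pos).max() < 1e-9

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            scale_oh_bonds(Frame(0.0, np.zeros((3, 3))), WaterTopology(1), 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(f=st.floats(0.7, 1.4), seed=st.integers(0, 50))
    def test_round_trip_property(self, f, seed):
        """scale(f) then scale(1/f) is the identity for any thermal water."""
        topo = WaterTopology(1)
        pos = self.water(jitter=0.05, seed=seed)
        fr = Frame(0.0, pos)
        out = scale_oh_bonds(fr, topo, f)
        r0 = np.linalg.norm(pos[1] - pos[0])
        r1 = np.linalg.norm(out.positions[1] - out.positions[0])
        assert r1 == pytest.approx(f * r0, rel=1e-9)
        back = scale_oh_bonds(out, topo, 1.0 / f)
        assert np.abs(back.positions - pos).max() < 1e-8


class TestScalingLadder:
    def test_linear_trend_recovered(self):
        rng = np.random.default_rng(9)
        f = np.array([0.9, 0.95, 1.0, 1.05, 1.1])
        e0 = -2.0 - 1.5 * (f - 1.0) + rng.normal(0, 1e-4, 5)
        gap = 1.7 + 0.8 * (f - 1.0) + rng.normal(0, 1e-4, 5)
        rep = scaling_ladder(f, e0, gap)
        assert rep.e0_slope == pytest.approx(-1.5, abs=3 * rep.e0_slope_stderr + 0.01)
        assert rep.gap_slope == pytest.approx(0.8, abs=3 * rep.gap_slope_stderr + 0.01)
        assert rep.e0_decreasing and rep.gap_increasing

    def test_flat_ladder_has_no_trend(self):
        rep = scaling_ladder([0.9, 1.0, 1.1], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert rep.e0_slope == pytest.approx(0.0, abs=1e-12)
        assert not rep.e0_decreasing and not rep.gap_increasing

    def test_needs_two_factors(self):
        with pytest.raises(ValueError):
            scaling_ladder([1.0], [1.0], [1.0])
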
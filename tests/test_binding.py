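"""Binding analyses: site occupancy, Boltzmann-inversion map, permeation
events, binding-mode clustering."""

import numpy as np
import pytest

from sfps import Trajectory, cluster_binding_modes, detect_permeation_events, \
    free_energy_map, site_occupancy
from sfps.binding import (BindingSiteDefinition, SiteOverlapError,
                          analysis_window, default_site_definitions,
                          mode_feature_atoms)
from sfps.constants import thermal_energy
from sfps.descriptors import RZSeries

from conftest import make_free_beads


def ion_trajectory(deka_topology, positions):
    """Frames with every atom at its anchor and the ion moved around."""
    base = deka_topology.initial_coordinates()
    ion = deka_topology.indices(role="ion")[0]
    coords = np.tile(base, (len(positions), 1, 1))
    coords[:, ion, :] = positions
    return Trajectory(coords, deka_topology.box), ion


class TestSiteOccupancy:
    def test_fixed_ion_in_site_oc(self, deka_topology):
        traj, ion = ion_trajectory(deka_topology,
                                   np.tile([0.5, 0.5, 1.0], (8, 1)))
        frac, labels = site_occupancy(traj, deka_topology, ion)
        assert frac["Site_OC"] == 1.0
        assert all(v == 0.0 for k, v in frac.items() if k != "Site_OC")

    def test_ion_outside_every_site(self, deka_topology):
        traj, ion = ion_trajectory(deka_topology,
                                   np.tile([0.0, 0.0, 13.0], (5, 1)))
        frac, _ = site_occupancy(traj, deka_topology, ion)
        assert frac["unbound"] == 1.0

    def test_fractions_sum_to_one(self, deka_topology):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(-2, 2, 50),
                               rng.uniform(-2, 2, 50),
                               rng.uniform(-8, 11, 50)])
        traj, ion = ion_trajectory(deka_topology, pos)
        frac, _ = site_occupancy(traj, deka_topology, ion)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_uniform_sampling_equal_sites(self, deka_topology):
        """Uniform z over two equal-height sites -> equal occupancy."""
        rng = np.random.default_rng(1)
        n = 4000
        pos = np.column_stack([np.full(n, 0.5), np.full(n, 0.5),
                               rng.uniform(-2.0, 6.0, n)])
        traj, ion = ion_trajectory(deka_topology, pos)
        sites = [BindingSiteDefinition("lower", (-2.0, 2.0), 4.0),
                 BindingSiteDefinition("upper", (2.0, 6.0), 4.0)]
        frac, _ = site_occupancy(traj, deka_topology, ion, sites)
        se = 0.5 / np.sqrt(n)
        assert abs(frac["lower"] - frac["upper"]) < 6 * se

    def test_overlapping_sites_rejected(self, deka_topology):
        traj, ion = ion_trajectory(deka_topology, np.zeros((1, 3)))
        sites = [BindingSiteDefinition("a", (0.0, 3.0), 4.0),
                 BindingSiteDefinition("b", (2.0, 5.0), 4.0)]
        with pytest.raises(SiteOverlapError, match="a and b"):
            site_occupancy(traj, deka_topology, ion, sites)


class TestFreeEnergyMap:
    def test_single_bin(self):
        samples = np.tile([[2.0, 1.0]], (100, 1))
        m = free_energy_map(samples, bin_width=0.5, kT=0.616, cap=6.0)
        assert m.free_energy.min() == 0.0
        sampled = m.counts > 0
        assert sampled.sum() == 1
        assert np.all(m.free_energy[~sampled] == 6.0)

    def test_count_doubling_invariance(self):
        rng = np.random.default_rng(2)
        samples = rng.normal((3, 0), 0.8, (500, 2))
        m1 = free_energy_map(samples, 0.5)
        m2 = free_energy_map(np.vstack([samples, samples]), 0.5)
        s = m1.counts > 0
        assert np.allclose(m1.free_energy[s], m2.free_energy[s])

    def test_harmonic_well_recovery(self):
        """Boltzmann inversion of 1e6 samples from a planted 2-D harmonic
        well recovers U - min(U) with RMS <= 0.2 kcal/mol on well-sampled
        bins."""
        kT = thermal_energy(310.0)
        kR, kZ = 1.0, 1.5
        R0, Z0 = 4.0, 1.0
        rng = np.random.default_rng(5)
        n = 1_000_000
        samples = np.column_stack([
            rng.normal(R0, np.sqrt(kT / kR), n),
            rng.normal(Z0, np.sqrt(kT / kZ), n)])
        m = free_energy_map(samples, bin_width=0.5, kT=kT, cap=8.0)
        rc = 0.5 * (m.R_edges[:-1] + m.R_edges[1:])
        zc = 0.5 * (m.Z_edges[:-1] + m.Z_edges[1:])
        rr, zz = np.meshgrid(rc, zc, indexing="ij")
        U = 0.5 * kR * (rr - R0) ** 2 + 0.5 * kZ * (zz - Z0) ** 2
        well = m.counts >= 100
        diff = (m.free_energy - (U - U[well].min()))[well]
        rms = np.sqrt(np.mean(diff**2))
        assert rms <= 0.2

    def test_bad_kt_rejected(self):
        with pytest.raises(ValueError, match="kT"):
            free_energy_map(np.zeros((10, 2)), kT=0.0)


class TestPermeationEvents:
    def test_monotone_descent_single_event(self):
        z = np.linspace(8, -8, 60)
        events = detect_permeation_events(z, 0.0, dwell=5)
        assert len(events) == 1 and events[0][1] == "inward"

    def test_debounced_oscillation(self):
        z = np.array([1.0, -1.0] * 20)
        assert detect_permeation_events(z, 0.0, dwell=3) == []

    def test_three_planted_crossings(self):
        z = np.concatenate([np.full(10, 5.0), np.full(10, -5.0),
                            np.full(10, 5.0), np.full(10, -5.0)])
        events = detect_permeation_events(z, 0.0, dwell=5)
        assert [e[0] for e in events] == [10, 20, 30]
        assert [e[1] for e in events] == ["inward", "outward", "inward"]


class TestClusterBindingModes:
    def test_identical_frames_single_mode(self, deka_topology):
        traj, ion = ion_trajectory(deka_topology,
                                   np.tile([0.5, 0.5, 0.0], (20, 1)))
        modes = cluster_binding_modes(traj, deka_topology, ion,
                                      list(range(20)))
        assert len(modes) == 1
        assert modes[0].occupancy == 1.0
        assert modes[0].main

    def test_empty_bound_set_rejected(self, deka_topology):
        traj, ion = ion_trajectory(deka_topology, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no binding"):
            cluster_binding_modes(traj, deka_topology, ion, [])

    def test_two_planted_geometries_recovered(self, deka_topology):
        """60/40 split of two well-separated ion placements gives two
        clusters with exact memberships."""
        pos_a = np.tile([2.0, 0.0, 0.0], (60, 1))
        pos_b = np.tile([-2.0, -2.0, 1.0], (40, 1))
        traj, ion = ion_trajectory(deka_topology, np.vstack([pos_a, pos_b]))
        modes = cluster_binding_modes(traj, deka_topology, ion,
                                      list(range(100)), cutoff=1.5)
        assert len(modes) == 2
        assert modes[0].occupancy == pytest.approx(0.6)
        assert modes[1].occupancy == pytest.approx(0.4)
        assert modes[0].member_frames == list(range(60))
        assert modes[1].member_frames == list(range(60, 100))

    def test_three_modes_two_main(self, deka_topology):
        pos = np.vstack([np.tile([2.0, 0.0, 0.0], (50, 1)),
                         np.tile([-2.0, -2.0, 1.0], (30, 1)),
                         np.tile([0.0, 2.5, -1.0], (20, 1))])
        traj, ion = ion_trajectory(deka_topology, pos)
        modes = cluster_binding_modes(traj, deka_topology, ion,
                                      list(range(100)))
        assert len(modes) == 3
        assert [m.main for m in modes] == [True, True, False]

    def test_frame_order_permutation_invariant(self, deka_topology):
        rng = np.random.default_rng(8)
        pos = np.vstack([np.tile([2.0, 0.0, 0.0], (30, 1)),
                         np.tile([-2.0, -2.0, 1.0], (20, 1))])
        traj, ion = ion_trajectory(deka_topology, pos)
        frames = list(range(50))
        shuffled = frames.copy()
        rng.shuffle(shuffled)
        m1 = cluster_binding_modes(traj, deka_topology, ion, frames)
        m2 = cluster_binding_modes(traj, deka_topology, ion, shuffled)
        assert [set(m.member_frames) for m in m1] == \
            [set(m.member_frames) for m in m2]

    def test_occupancy_floor_flag(self, deka_topology):
        pos = np.vstack([np.tile([2.0, 0.0, 0.0], (97, 1)),
                         np.tile([-2.0, -2.0, 1.0], (3, 1))])
        traj, ion = ion_trajectory(deka_topology, pos)
        modes = cluster_binding_modes(traj, deka_topology, ion,
                                      list(range(100)),
                                      n_analyzed_frames=100)
        assert not modes[0].too_small_for_fep
        assert modes[1].too_small_for_fep


def test_analysis_window_last_75_percent():
    w = analysis_window(200)
    assert w[0] == 50 and w[-1] == 199


def test_feature_atoms_are_inner_ring_sidechains(deka_topology):
    atoms = mode_feature_atoms(deka_topology)
    roles = {deka_topology.atoms[i].role for i in atoms}
    assert roles == {"carboxylate-O", "sidechain-N"}
    assert len(atoms) == 5  # Asp pair + Glu pair + Lys NZ
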
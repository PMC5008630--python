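"""Hydrogen bonds, coordination shells, group-ion distances and the
Lys/Arg repulsion profile."""

import numpy as np
import pytest

from sfps import (Trajectory, coordination_count, group_cation_distance,
                  hbond_occupancy, ion_spec, repulsion_profile)
from sfps.constants import COULOMB
from sfps.interactions import (HBondCriteria, classify_mode_coordination,
                               _round_half_up)
from sfps.binding import BindingMode


def fixed_pair_trajectory(deka_topology, donor_idx, acceptor_idx, distances):
    base = deka_topology.initial_coordinates()
    coords = np.tile(base, (len(distances), 1, 1))
    for f, d in enumerate(distances):
        coords[f, donor_idx] = [0.0, 0.0, 10.0]
        coords[f, acceptor_idx] = [d, 0.0, 10.0]
    return Trajectory(coords, deka_topology.box)


class TestHBonds:
    def donor_acceptor(self, top):
        donor = top.indices(name="NZ")[0]
        acceptor = top.indices(role="carboxylate-O", chain="A",
                               resnum=183)[0]
        return donor, acceptor

    def test_occupancy_one_at_3A(self, deka_topology):
        d, a = self.donor_acceptor(deka_topology)
        traj = fixed_pair_trajectory(deka_topology, d, a, [3.0] * 6)
        rep = hbond_occupancy(traj, deka_topology, "name NZ",
                              f"role carboxylate-O and chain A and resnum 183")
        assert rep.occupancy >= 1.0 - 1e-12

    def test_occupancy_zero_at_4A(self, deka_topology):
        d, a = self.donor_acceptor(deka_topology)
        traj = fixed_pair_trajectory(deka_topology, d, a, [4.0] * 6)
        # move every *other* chain-A 183 oxygen far away so only the
        # planted pair is in play
        other = deka_topology.indices(role="carboxylate-O", chain="A",
                                      resnum=183)[1]
        traj.coordinates[:, other] = [0.0, 0.0, -12.0]
        rep = hbond_occupancy(traj, deka_topology, "name NZ",
                              "role carboxylate-O and chain A and resnum 183")
        assert rep.occupancy == 0.0

    def test_alternating_occupancy_half(self, deka_topology):
        d, a = self.donor_acceptor(deka_topology)
        traj = fixed_pair_trajectory(deka_topology, d, a, [3.0, 4.0] * 5)
        other = deka_topology.indices(role="carboxylate-O", chain="A",
                                      resnum=183)[1]
        traj.coordinates[:, other] = [0.0, 0.0, -12.0]
        rep = hbond_occupancy(traj, deka_topology, "name NZ",
                              "role carboxylate-O and chain A and resnum 183")
        assert rep.occupancy == pytest.approx(0.5)

    def test_monotone_in_cutoff(self, deka_topology):
        d, a = self.donor_acceptor(deka_topology)
        rng = np.random.default_rng(0)
        traj = fixed_pair_trajectory(deka_topology, d, a,
                                     rng.uniform(2.5, 5.0, 30))
        occ = [hbond_occupancy(traj, deka_topology, "name NZ",
                               "role carboxylate-O",
                               HBondCriteria(c)).occupancy
               for c in (2.8, 3.2, 3.6, 4.2)]
        assert all(a <= b + 1e-12 for a, b in zip(occ, occ[1:]))

    def test_bifurcate_flag(self, deka_topology):
        """Donor bridging acceptors of two residues sets the flag."""
        top = deka_topology
        d = top.indices(name="NZ")[0]
        a1 = top.indices(role="carboxylate-O", chain="A", resnum=183)[0]
        a2 = top.indices(role="carboxylate-O", chain="D", resnum=183)[0]
        base = top.initial_coordinates()
        coords = np.tile(base, (2, 1, 1))
        coords[:, d] = [0.0, 0.0, 10.0]
        coords[0, a1] = [3.0, 0.0, 10.0]
        coords[0, a2] = [-3.0, 0.0, 10.0]
        coords[1, a1] = [3.0, 0.0, 10.0]
        coords[1, a2] = [0.0, 0.0, -12.0]
        traj = Trajectory(coords, top.box)
        rep = hbond_occupancy(traj, top, "name NZ",
                              "role carboxylate-O and resnum 183")
        assert rep.bifurcate_per_frame.tolist() == [True, False]

    def test_empty_selection_rejected(self, deka_topology):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="non-empty"):
                hbond_occupancy(
                    Trajectory(np.zeros((1, deka_topology.n_atoms, 3)),
                               deka_topology.box),
                    deka_topology, "name NOPE", "name NZ")


class TestCoordination:
    def place_ion_and_oxygens(self, top, ion_dist_pairs):
        """Put the ion at origin (far above the pore) and selected
        oxygens at given distances."""
        base = top.initial_coordinates()
        coords = base.copy()
        ion = top.indices(role="ion")[0]
        coords[ion] = [0.0, 0.0, 11.0]
        for idx, dist in ion_dist_pairs:
            coords[idx] = [dist, 0.0, 11.0]
        return coords, ion

    def test_na_cutoff_cases(self, deka_topology):
        top = deka_topology
        waters = top.indices(role="water-O")
        coords, ion = self.place_ion_and_oxygens(
            top, [(waters[0], 2.50), (waters[1], 3.00)])
        counts = coordination_count(coords, top, ion, ion_spec("NA"))
        assert counts["water_O"] == 1  # 2.50 <= 2.69 < 3.00

    def test_k_counts_at_3A(self):
        from sfps import GeometryConfig, build_model_topology
        top = build_model_topology(
            "DEKA", GeometryConfig(ion_species="K", n_waters=10), seed=4)
        waters = top.indices(role="water-O")
        coords, ion = self.place_ion_and_oxygens(top, [(waters[0], 3.00)])
        counts = coordination_count(coords, top, ion, ion_spec("K"))
        assert counts["water_O"] == 1  # 3.00 <= 3.22

    def test_geometric_counting_beyond_chemical_max(self, deka_topology):
        top = deka_topology
        waters = top.indices(role="water-O")[:8]
        base = top.initial_coordinates()
        coords = base.copy()
        ion = top.indices(role="ion")[0]
        coords[ion] = [0.0, 0.0, 11.0]
        for i, w in enumerate(waters):
            ang = 2 * np.pi * i / 8
            coords[w] = [2.0 * np.cos(ang), 2.0 * np.sin(ang), 11.0]
        counts = coordination_count(coords, top, ion, ion_spec("NA"))
        assert counts["water_O"] == 8  # counting is geometric; max 6 is
        # a separate property of the IonSpec
        assert ion_spec("NA").max_coordination == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_distance_filter_oracle(self, deka_topology, seed):
        top = deka_topology
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-10, 10, (top.n_atoms, 3))
        ion = top.indices(role="ion")[0]
        spec = ion_spec("NA")
        counts = coordination_count(coords, top, ion, spec)
        expected = {"carboxylate_O": 0, "other_protein_O": 0, "water_O": 0}
        role_map = {"carboxylate-O": "carboxylate_O",
                    "hydroxyl-O": "other_protein_O",
                    "water-O": "water_O"}
        box = top.box
        for i, a in enumerate(top.atoms):
            if a.role not in role_map:
                continue
            best = min(np.linalg.norm(coords[i] - coords[ion]
                                      + [mx * box[0], my * box[1], 0.0])
                       for mx in (-1, 0, 1) for my in (-1, 0, 1))
            if best <= spec.coordination_cutoff:
                expected[role_map[a.role]] += 1
        for k, v in expected.items():
            assert counts[k] == v

    def test_species_mismatch_rejected(self, deka_topology):
        top = deka_topology
        ion = top.indices(role="ion")[0]  # an NA ion
        with pytest.raises(ValueError, match="species"):
            coordination_count(top.initial_coordinates(), top, ion,
                               ion_spec("K"))


class TestModeCoordination:
    def make_mode(self, frames):
        return BindingMode(rank=1, member_frames=frames, occupancy=1.0,
                           centroid=np.zeros(1), representative_frame=0,
                           restraint_center=np.zeros(3), feature_atoms=[0],
                           main=True)

    def test_round_half_up_tie(self):
        assert _round_half_up(2.5) == 3
        assert _round_half_up(2.49) == 2

    def test_tight_flag(self, deka_topology):
        top = deka_topology
        carbox = top.indices(role="carboxylate-O", resnum=180)
        base = top.initial_coordinates()
        ion = top.indices(role="ion")[0]
        coords = np.tile(base, (4, 1, 1))
        coords[:, ion] = [0.0, 0.0, 11.0]
        for i, c in enumerate(carbox):
            ang = 2 * np.pi * i / len(carbox)
            coords[:, c] = [2.2 * np.cos(ang), 2.2 * np.sin(ang), 11.0]
        traj = Trajectory(coords, top.box)
        summary = classify_mode_coordination(self.make_mode([0, 1, 2, 3]),
                                             traj, top, ion,
                                             ion_spec("NA"))
        assert summary["mean_carboxylate_O"] == pytest.approx(4.0)
        assert summary["tight_coordination"]

    def test_loose_flag(self, deka_topology):
        top = deka_topology
        base = top.initial_coordinates()
        ion = top.indices(role="ion")[0]
        coords = np.tile(base, (2, 1, 1))
        coords[:, ion] = [0.0, 0.0, 12.0]
        traj = Trajectory(coords, top.box)
        summary = classify_mode_coordination(self.make_mode([0, 1]), traj,
                                             top, ion, ion_spec("NA"))
        assert summary["mean_carboxylate_O"] == 0.0
        assert not summary["tight_coordination"]


class TestGroupCationDistance:
    def test_static_thresholds(self, deka_topology):
        top = deka_topology
        nz = top.indices(name="NZ")[0]
        ion = top.indices(role="ion")[0]
        base = top.initial_coordinates()
        coords = np.tile(base, (4, 1, 1))
        coords[:, nz] = [0.0, 0.0, 10.0]
        coords[:, ion] = [6.0, 0.0, 10.0]
        traj = Trajectory(coords, top.box)
        d, exceed = group_cation_distance(traj, top, "name NZ", ion)
        assert np.allclose(d, 6.0)
        assert exceed[5.5] == 1.0
        coords[:, ion] = [4.0, 0.0, 10.0]
        d, exceed = group_cation_distance(Trajectory(coords, top.box), top,
                                          "name NZ", ion)
        assert exceed[5.0] == 0.0

    def test_half_half(self, deka_topology):
        top = deka_topology
        nz = top.indices(name="NZ")[0]
        ion = top.indices(role="ion")[0]
        base = top.initial_coordinates()
        coords = np.tile(base, (10, 1, 1))
        coords[:, nz] = [0.0, 0.0, 10.0]
        coords[:5, ion] = [4.5, 0.0, 10.0]
        coords[5:, ion] = [6.0, 0.0, 10.0]
        _, exceed = group_cation_distance(Trajectory(coords, top.box), top,
                                          "name NZ", ion)
        assert exceed[5.0] == pytest.approx(0.5)


class TestRepulsionProfile:
    def test_coulomb_closed_form_no_solvent(self):
        """Single +1 site vs +1 ion, eps_r = 1: exactly 332.06/r."""
        grid = [5.0, 8.0, 10.0, 12.0]
        prof = repulsion_profile("lys", "NA", grid, dielectric=1.0)
        for d, e in zip(prof["distance_A"], prof["energy_kcal_mol"]):
            assert e == pytest.approx(COULOMB / d, abs=1e-6)

    def test_lys_more_repulsive_than_arg_at_4A(self):
        lys = repulsion_profile("lys", "NA", [4.0])
        arg = repulsion_profile("arg", "NA", [4.0])
        assert lys["energy_kcal_mol"][0] > arg["energy_kcal_mol"][0]

    def test_monotone_decay(self):
        prof = repulsion_profile("arg", "K", [8.0, 12.0])
        assert prof["energy_kcal_mol"][0] > prof["energy_kcal_mol"][1]

    def test_contact_grid_rejected(self):
        with pytest.raises(ValueError, match="contact"):
            repulsion_profile("lys", "NA", [1.0])
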
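"""Interaction-level analyses: hydrogen bonds, coordination shells,
cation-group distances and the Lys/Arg repulsion-versus-distance profile.

The coarse model has no hydrogens, so the hydrogen-bond criterion is a
heavy-atom donor-acceptor distance (default 3.5 A); an angle term exists
in the criteria object but is off by default.  Oxygen coordination uses
the species-specific cutoffs stored on the IonSpec (2.69 A for Na+,
3.22 A for K+), with counts reported by oxygen role: carboxylate,
other-protein (hydroxyl/backbone) and water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingMode
from .constants import COULOMB, thermal_energy
from .dynamics import BDProtocol, bd_steps
from .hamiltonian import ToySystem
from .system import (Atom, GeometryConfig, IonSpec, ModelTopology,
                     ROLE_CARBOXYLATE_O, ROLE_HYDROXYL_O, ROLE_ION,
                     ROLE_SIDECHAIN_N, ROLE_WATER_O, SOLVENT_CHAIN,
                     ion_spec)
from .trajio import AtomSelection, Trajectory, select_atoms


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = np.array(d, dtype=float)
    for ax in (0, 1):
        L = box[ax]
        d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass
class HBondCriteria:
    max_distance: float = 3.5   # heavy-atom donor-acceptor cutoff, A
    use_angle: bool = False     # no hydrogens in the coarse model

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("hydrogen-bond distance cutoff must be positive")


@dataclass
class HBondReport:
    occupancy: float
    per_frame: np.ndarray            # bool, any qualifying pair
    bifurcate_fraction: float
    bifurcate_per_frame: np.ndarray  # bool, acceptors from >= 2 residues


def hbond_occupancy(trajectory: Trajectory, topology: ModelTopology,
                    donors: AtomSelection | str,
                    acceptors: AtomSelection | str,
                    criteria: HBondCriteria | None = None) -> HBondReport:
    """Fraction of frames with at least one donor-acceptor contact.

    The *bifurcate* flag marks frames where the donor group simultaneously
    contacts acceptors belonging to at least two distinct residues.
    """
    criteria = criteria or HBondCriteria()
    if isinstance(donors, str):
        donors = select_atoms(topology, donors)
    if isinstance(acceptors, str):
        acceptors = select_atoms(topology, acceptors)
    if not donors.indices or not acceptors.indices:
        raise ValueError("donor and acceptor selections must be non-empty")
    di = np.asarray(donors.indices)
    ai = np.asarray(acceptors.indices)
    acc_res = np.array([(topology.atoms[a].chain, topology.atoms[a].resnum)
                        for a in ai])
    D = trajectory.coordinates[:, di, :][:, :, None, :]
    A = trajectory.coordinates[:, ai, :][:, None, :, :]
    r = np.linalg.norm(_min_image_xy(A - D, topology.box), axis=3)
    contact = r <= criteria.max_distance          # (F, nd, na)
    per_frame = contact.any(axis=(1, 2))
    acc_hit = contact.any(axis=1)                 # (F, na)
    bif = np.zeros(trajectory.n_frames, dtype=bool)
    for f in np.flatnonzero(acc_hit.any(axis=1)):
        residues = {tuple(acc_res[a]) for a in np.flatnonzero(acc_hit[f])}
        bif[f] = len(residues) >= 2
    n = max(trajectory.n_frames, 1)
    return HBondReport(float(per_frame.sum()) / n, per_frame,
                       float(bif.sum()) / n, bif)


# ---------------------------------------------------------------------------
# coordination shells
# ---------------------------------------------------------------------------

_OXYGEN_CATEGORY = {
    ROLE_CARBOXYLATE_O: "carboxylate_O",
    ROLE_HYDROXYL_O: "other_protein_O",
    ROLE_WATER_O: "water_O",
}


def coordination_count(frame: np.ndarray, topology: ModelTopology,
                       ion_index: int,
                       spec: IonSpec | None = None,
                       oxygen_indices: Sequence[int] | None = None) -> dict:
    """Count oxygens within the ion's coordinating cutoff, by category.

    Counting is purely geometric: all oxygens within the cutoff count,
    even beyond the species' chemical maximum (which is a separate flag on
    the IonSpec).
    """
    ion_atom = topology.atoms[ion_index]
    if spec is None:
        spec = ion_spec(ion_atom.name)
    elif ion_atom.role == ROLE_ION and ion_atom.name != spec.species:
        raise ValueError(
            f"ion-spec species {spec.species} does not match atom "
            f"{ion_atom.name}")
    if oxygen_indices is None:
        oxygen_indices = [i for i, a in enumerate(topology.atoms)
                          if a.role in _OXYGEN_CATEGORY]
    counts = {v: 0 for v in _OXYGEN_CATEGORY.values()}
    frame = np.asarray(frame, dtype=float)
    d = _min_image_xy(frame[list(oxygen_indices)] - frame[ion_index],
                      topology.box)
    r = np.linalg.norm(d, axis=1)
    for idx, dist in zip(oxygen_indices, r):
        if dist <= spec.coordination_cutoff:
            counts[_OXYGEN_CATEGORY[topology.atoms[idx].role]] += 1
    counts["total"] = sum(counts.values())
    return counts


def coordination_report(trajectory: Trajectory, topology: ModelTopology,
                        ion_index: int, spec: IonSpec | None = None,
                        frames: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-frame coordination counts for an ion over selected frames."""
    frames = list(frames) if frames is not None \
        else list(range(trajectory.n_frames))
    rows = []
    for f in frames:
        c = coordination_count(trajectory.coordinates[f], topology,
                               ion_index, spec)
        c["frame"] = f
        rows.append(c)
    cols = ["frame", "carboxylate_O", "other_protein_O", "water_O", "total"]
    return pd.DataFrame(rows, columns=cols)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def classify_mode_coordination(mode: BindingMode, trajectory: Trajectory,
                               topology: ModelTopology, ion_index: int,
                               spec: IonSpec | None = None) -> dict:
    """Mode-level coordination summary and the tight-coordination flag.

    The flag is true when the mean carboxylate-oxygen count over the
    mode's member frames, rounded half-up, is at least 3 (the geometry
    that intrinsically favours the small, low-coordination Na+ ion).
    """
    if not mode.member_frames:
        raise ValueError("binding mode has no member frames")
    rep = coordination_report(trajectory, topology, ion_index, spec,
                              mode.member_frames)
    mean_carb = float(rep["carboxylate_O"].mean())
    return {
        "mean_carboxylate_O": mean_carb,
        "mean_other_protein_O": float(rep["other_protein_O"].mean()),
        "mean_water_O": float(rep["water_O"].mean()),
        "tight_coordination": _round_half_up(mean_carb) >= 3,
    }


# ---------------------------------------------------------------------------
# cation-group distance
# ---------------------------------------------------------------------------


def group_cation_distance(trajectory: Trajectory, topology: ModelTopology,
                          group: AtomSelection | str, ion_index: int,
                          thresholds: Sequence[float] = (5.0, 5.5)):
    """Distance (A) from the charged-group centroid to the ion, per frame.

    The group position is the unweighted centroid of its charge-bearing
    sites.  Returns ``(distances, exceedance)`` where ``exceedance`` maps
    each threshold to the fraction of frames with distance > threshold.
    """
    if isinstance(group, str):
        group = select_atoms(topology, group)
    if not group.indices:
        raise ValueError("charged-group selection is empty")
    pts = trajectory.coordinates[:, group.indices, :]
    ref = pts[:, :1, :]
    centroid = (ref + _min_image_xy(pts - ref, topology.box)).mean(axis=1)
    ion = trajectory.coordinates[:, ion_index, :]
    d = np.linalg.norm(_min_image_xy(ion - centroid, topology.box), axis=1)
    exceed = {float(t): float(np.mean(d > t)) for t in thresholds}
    return d, exceed


# ---------------------------------------------------------------------------
# repulsion-versus-distance profile
# ---------------------------------------------------------------------------


def _sidechain_analog(kind: str, dielectric: float,
                      estar: bool = False,
                      flexible: bool = False) -> ModelTopology:
    """Isolated Lys- or Arg-like charged group anchored at the origin."""
    atoms: list[Atom] = []
    if kind == "lys":
        atoms.append(Atom(0, "NZ", "LYS", 1, "A", ROLE_SIDECHAIN_N, 1.0,
                          3.30, 0.17, anchor=np.zeros(3), tether_k=5.0,
                          fixed=not flexible))
    elif kind == "arg":
        qs = (0.90, 0.05, 0.05) if estar else (1 / 3, 1 / 3, 1 / 3)
        # planar triad perpendicular to the separation axis (x)
        offs = np.array([[0.0, 0.0, 1.0],
                         [0.0, 0.866, -0.5],
                         [0.0, -0.866, -0.5]]) * 1.15
        for i, (q, off) in enumerate(zip(qs, offs)):
            atoms.append(Atom(i, ("NH1", "NH2", "NE")[i], "ARG", 1, "A",
                              ROLE_SIDECHAIN_N, q, 3.30, 0.17,
                              anchor=off, tether_k=5.0,
                              fixed=not flexible))
    else:
        raise ValueError("group kind must be 'lys' or 'arg'")
    top = ModelTopology(atoms, np.array([60.0, 60.0, 60.0]), f"{kind}-analog")
    top.dielectric = dielectric
    return top


def repulsion_profile(kind: str, ion_species: str,
                      distances: Sequence[float],
                      protocol: BDProtocol | None = None,
                      seed: int = 0,
                      dielectric: float = 10.0,
                      n_waters: int = 0,
                      flexible: bool = False,
                      estar: bool = False) -> pd.DataFrame:
    """Mean group-ion electrostatic energy versus centroid separation.

    The ion is held at each grid distance from the charged-group centroid
    (on the x axis); with ``flexible=False`` (default) the group sites are
    rigid at their ideal geometry and the profile is the deterministic
    Coulomb sum, otherwise tethered group sites and any solvent are
    sampled with Brownian dynamics and the group-ion Coulomb energy is
    averaged over the run.
    """
    distances = [float(d) for d in distances]
    contact = 2.0
    if min(distances) <= contact:
        raise ValueError(
            f"grid distance {min(distances)} A is at or below the "
            f"Lennard-Jones contact distance ({contact} A)")
    spec = ion_spec(ion_species)
    rows = []
    rng = np.random.default_rng(seed)
    for dist in distances:
        base = _sidechain_analog(kind, dielectric, estar=estar,
                                 flexible=flexible)
        n0 = base.n_atoms
        atoms = list(base.atoms)
        ion_pos = np.array([dist, 0.0, 0.0])
        atoms.append(Atom(n0, spec.species, spec.species, 500, SOLVENT_CHAIN,
                          ROLE_ION, spec.charge, spec.sigma, spec.epsilon,
                          anchor=ion_pos, tether_k=200.0, fixed=not flexible))
        wrng = np.random.default_rng(seed + 1)
        for w in range(n_waters):
            pos = ion_pos + wrng.normal(scale=4.0, size=3)
            atoms.append(Atom(n0 + 1 + w, "OW", "WAT", 1000 + w,
                              SOLVENT_CHAIN, ROLE_WATER_O, 0.0, 3.10, 0.25,
                              anchor=pos))
        top = ModelTopology(atoms, base.box, base.variant)
        top.dielectric = dielectric
        group_idx = list(range(n0))
        ion_idx = n0

        def pair_electrostatics(coords: np.ndarray) -> float:
            d = coords[group_idx] - coords[ion_idx]
            r = np.linalg.norm(d, axis=1)
            q = np.array([atoms[g].charge for g in group_idx])
            return float(np.sum(COULOMB * q * spec.charge
                                / (dielectric * r)))

        coords0 = top.initial_coordinates()
        if not flexible and n_waters == 0:
            mean_e = pair_electrostatics(coords0)
        else:
            proto = protocol or BDProtocol(n_steps=5000, save_interval=10,
                                           seed=int(rng.integers(2**31)))
            system = ToySystem(top)
            frames = bd_steps(system.forces, coords0, proto.n_steps,
                              proto.timestep, thermal_energy(proto.temperature),
                              proto.friction,
                              np.random.default_rng(proto.seed),
                              mobile=~system.fixed,
                              save_interval=proto.save_interval)
            mean_e = float(np.mean([pair_electrostatics(f) for f in frames]))
        rows.append({"distance_A": dist, "energy_kcal_mol": mean_e})
    return pd.DataFrame(rows, columns=["distance_A", "energy_kcal_mol"])
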
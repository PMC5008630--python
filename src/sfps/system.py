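"""Coarse-grained pore models of the Na_vRh selectivity-filter mutants.

The model is a four-fold pseudo-symmetric pore built from beads:

* an *inner ring* (residue 180, one residue per chain A-D) carrying the
  DEKA/DERA-style motif: an Asp carboxylate-oxygen pair, a Glu carboxylate
  pair, a cationic side chain (Lys amino nitrogen or Arg guanidine triad)
  and an Ala placeholder, distributed over the four chains;
* an *outer ring* (residue 183, Glu in the wild type) of carboxylate pairs
  one helical turn further toward the extracellular side;
* fixed backbone anchor beads that define the pore scaffold;
* neutral water-oxygen beads confined to the box by soft walls;
* one or more permeant cations (Na+ or K+).

Chain assignment of the inner-ring motif: chain A = Glu180, chain B =
Asp180, chain C = the cationic residue (Lys/Arg) or Ser/placeholder, chain
D = Ala180.  The cationic side chain in chain C therefore faces Glu180
across the pore and has Glu183 of chains D and A as its nearest outer-ring
neighbours, matching the interaction pattern the analyses probe.

Bead Lennard-Jones radii are calibrated so that ion-oxygen contact
distances fall inside the quantum-chemistry-derived coordinating ranges
used by the coordination analysis (Na-O ~ 2.5 A, K-O ~ 3.0 A); see
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# role tags
# ---------------------------------------------------------------------------

ROLE_CARBOXYLATE_O = "carboxylate-O"
ROLE_SIDECHAIN_N = "sidechain-N"
ROLE_HYDROXYL_O = "hydroxyl-O"
ROLE_ION = "ion"
ROLE_WATER_O = "water-O"
ROLE_BACKBONE = "backbone"
ROLE_PLACEHOLDER = "placeholder"

ROLES = (
    ROLE_CARBOXYLATE_O,
    ROLE_SIDECHAIN_N,
    ROLE_HYDROXYL_O,
    ROLE_ION,
    ROLE_WATER_O,
    ROLE_BACKBONE,
    ROLE_PLACEHOLDER,
)

SOLVENT_CHAIN = "SOLVENT"
PROTEIN_CHAINS = ("A", "B", "C", "D")

VARIANTS = (
    "WT",
    "DEAA",
    "DEKA",
    "DERA",
    "DEKA-0.5e",
    "DEKA-0.05e",
    "DERA-estar",
    "DERA-E183D",
    "DERA-E183A",
)


class UnknownVariantError(ValueError):
    pass


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ion specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpec:
    """Permeant-cation parameters.

    ``coordination_cutoff`` is the ion-oxygen distance (A) below which an
    oxygen counts as coordinating (mean of the lower and upper limits of the
    QM/MM coordinating range); ``max_coordination`` is the chemical maximum
    of the first shell.
    """

    species: str
    charge: float
    sigma: float
    epsilon: float
    coordination_cutoff: float
    max_coordination: int


#: QM/MM coordinating-distance ranges (A) for first-shell ion-oxygen contacts.
COORDINATION_RANGES = {"NA": (2.39, 2.99), "K": (2.80, 3.65)}

_ION_SPECS = {
    # sigma/epsilon calibrated for the coarse beads, not atomistic values:
    # contact distances Na-O ~ 2.5 A and K-O ~ 3.0 A with sigma_O = 2.9 A.
    "NA": IonSpec("NA", +1.0, 1.50, 1.20, 2.69, 6),
    "K": IonSpec("K", +1.0, 2.40, 1.00, 3.22, 8),
}


def ion_spec(species: str) -> IonSpec:
    try:
        return _ION_SPECS[species.upper()]
    except KeyError:
        raise ValueError(
            f"unknown ion species {species!r}; known: {sorted(_ION_SPECS)}"
        ) from None


# ---------------------------------------------------------------------------
# atoms and topology
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    id: int
    name: str
    resname: str
    resnum: int
    chain: str
    role: str
    charge: float
    sigma: float
    epsilon: float
    #: harmonic tether: U = 0.5 * k * (|x - anchor| - length)^2
    anchor: Optional[np.ndarray] = None
    tether_k: float = 0.0
    tether_length: float = 0.0
    fixed: bool = False
    #: starting coordinates; defaults to the tether anchor
    initial: Optional[np.ndarray] = None


@dataclass
class ModelTopology:
    """Bead topology of one pore-model variant plus its solvent and ions."""

    atoms: list[Atom]
    box: np.ndarray
    variant: str
    dielectric: float = 10.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        for a in self.atoms:
            if a.sigma <= 0 or a.epsilon < 0:
                raise ValueError(f"atom {a.id}: need sigma > 0 and epsilon >= 0")
            if a.chain not in PROTEIN_CHAINS and a.chain != SOLVENT_CHAIN:
                raise ValueError(f"atom {a.id}: illegal chain {a.chain!r}")

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def sigmas(self) -> np.ndarray:
        return np.array([a.sigma for a in self.atoms])

    def epsilons(self) -> np.ndarray:
        return np.array([a.epsilon for a in self.atoms])

    def fixed_mask(self) -> np.ndarray:
        return np.array([a.fixed for a in self.atoms], dtype=bool)

    def roles(self) -> list[str]:
        return [a.role for a in self.atoms]

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def indices(self, role: str | None = None, chain: str | None = None,
                resnum: int | None = None, name: str | None = None) -> list[int]:
        """Indices of atoms matching all given attribute filters."""
        out = []
        for i, a in enumerate(self.atoms):
            if role is not None and a.role != role:
                continue
            if chain is not None and a.chain != chain:
                continue
            if resnum is not None and a.resnum != resnum:
                continue
            if name is not None and a.name != name:
                continue
            out.append(i)
        return out

    def initial_coordinates(self) -> np.ndarray:
        out = np.zeros((len(self.atoms), 3))
        for i, a in enumerate(self.atoms):
            if a.initial is not None:
                out[i] = a.initial
            elif a.anchor is not None:
                out[i] = a.anchor
        return out

    def group_charge(self, chain: str, resnum: int) -> float:
        return float(sum(a.charge for a in self.atoms
                         if a.chain == chain and a.resnum == resnum))


# ---------------------------------------------------------------------------
# geometry configuration
# ---------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    """Placement parameters of the coarse pore (all lengths in A)."""

    pore_radius: float = 3.5          # radius of the inner carboxylate ring
    backbone_radius: float = 6.0      # radius of the backbone scaffold
    inner_ring_z: float = 0.0
    outer_ring_z: float = 4.0
    outer_ring_radius: float = 5.0
    box: tuple[float, float, float] = (24.0, 24.0, 28.0)
    n_waters: int = 40
    n_ions: int = 1
    ion_species: str = "NA"
    ion_start_z: float = 0.0
    carboxylate_pair_halfsep: float = 1.1
    carboxylate_tether_k: float = 5.0
    sidechain_arm_length: float = 5.0  # Lys swing arm, anchor->NZ
    sidechain_tether_k: float = 2.0
    guanidine_site_radius: float = 1.15
    guanidine_tether_k: float = 5.0
    wall_k: float = 10.0               # soft z-wall on mobile beads
    wall_margin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pore_radius <= 0:
            raise GeometryError("pore radius must be positive")


_CHAIN_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}


def _mi_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image distance (periodic in x and y only)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d[:2] -= box[:2] * np.round(d[:2] / box[:2])
    return float(np.linalg.norm(d))

# bead parameters (name -> sigma, epsilon)
_SIG_O, _EPS_O = 2.90, 0.12     # carboxylate / hydroxyl oxygen
_SIG_N, _EPS_N = 3.30, 0.17     # amino / guanidine nitrogen site
_SIG_CB, _EPS_CB = 3.60, 0.10   # Ala placeholder bead
_SIG_BB, _EPS_BB = 3.50, 0.10   # backbone anchor bead
_SIG_W, _EPS_W = 3.10, 0.25     # water oxygen bead


def _ring_position(chain: str, radius: float, z: float,
                   angle_offset: float = 0.0) -> np.ndarray:
    ang = math.radians(_CHAIN_ANGLES[chain] + angle_offset)
    return np.array([radius * math.cos(ang), radius * math.sin(ang), z])


# inner-ring residue per chain for each variant
_INNER_RING = {
    "WT": {"A": "SER", "B": "SER", "C": "SER", "D": "SER"},
    "DEAA": {"A": "GLU", "B": "ASP", "C": "ALA", "D": "ALA"},
    "DEKA": {"A": "GLU", "B": "ASP", "C": "LYS", "D": "ALA"},
    "DERA": {"A": "GLU", "B": "ASP", "C": "ARG", "D": "ALA"},
}
_INNER_RING["DEKA-0.5e"] = _INNER_RING["DEKA"]
_INNER_RING["DEKA-0.05e"] = _INNER_RING["DEKA"]
_INNER_RING["DERA-estar"] = _INNER_RING["DERA"]
_INNER_RING["DERA-E183D"] = _INNER_RING["DERA"]
_INNER_RING["DERA-E183A"] = _INNER_RING["DERA"]

#: total charge of the chain-C residue-180 cationic group per variant
CATIONIC_GROUP_CHARGE = {
    "DEKA": 1.0,
    "DERA": 1.0,
    "DEKA-0.5e": 0.5,
    "DEKA-0.05e": 0.05,
    "DERA-estar": 1.0,
    "DERA-E183D": 1.0,
    "DERA-E183A": 1.0,
}


def build_model_topology(variant: str, geometry: GeometryConfig | None = None,
                         seed: int = 0) -> ModelTopology:
    """Build the coarse-grained topology of one pore variant.

    Parameters
    ----------
    variant
        One of ``WT, DEAA, DEKA, DERA, DEKA-0.5e, DEKA-0.05e, DERA-estar,
        DERA-E183D, DERA-E183A``.
    geometry
        Placement parameters; defaults are the bundled model geometry.
    seed
        Seeds the random placement of water beads.
    """
    if variant not in VARIANTS:
        raise UnknownVariantError(
            f"unknown variant {variant!r}; allowed: {', '.join(VARIANTS)}"
        )
    geo = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    aid = 0

    def add(name, resname, resnum, chain, role, charge, sigma, epsilon,
            anchor=None, k=0.0, length=0.0, fixed=False, initial=None):
        nonlocal aid
        atoms.append(Atom(aid, name, resname, resnum, chain, role, charge,
                          sigma, epsilon,
                          None if anchor is None else np.asarray(anchor, float),
                          k, length, fixed,
                          None if initial is None else np.asarray(initial, float)))
        aid += 1

    def add_carboxylate_pair(chain, resname, resnum, radius, z, names):
        # two oxygens split tangentially around the ideal ring position
        for sgn, nm in zip((-1.0, +1.0), names):
            pos = _ring_position(chain, radius, z)
            tangent = _ring_position(chain, 1.0, 0.0, 90.0)
            pos = pos + sgn * geo.carboxylate_pair_halfsep * tangent
            add(nm, resname, resnum, chain, ROLE_CARBOXYLATE_O, -0.5,
                _SIG_O, _EPS_O, anchor=pos, k=geo.carboxylate_tether_k)

    # --- backbone scaffold (fixed) ----------------------------------------
    for chain in PROTEIN_CHAINS:
        for resnum, z in ((180, geo.inner_ring_z), (183, geo.outer_ring_z)):
            pos = _ring_position(chain, geo.backbone_radius, z)
            add("CA", "BBN", resnum, chain, ROLE_BACKBONE, 0.0,
                _SIG_BB, _EPS_BB, anchor=pos, fixed=True)

    # --- inner ring (residue 180) -----------------------------------------
    inner = _INNER_RING[variant]
    qcat = CATIONIC_GROUP_CHARGE.get(variant, 0.0)
    for chain in PROTEIN_CHAINS:
        res = inner[chain]
        if res == "GLU":
            add_carboxylate_pair(chain, "GLU", 180, geo.pore_radius,
                                 geo.inner_ring_z, ("OE1", "OE2"))
        elif res == "ASP":
            add_carboxylate_pair(chain, "ASP", 180, geo.pore_radius,
                                 geo.inner_ring_z, ("OD1", "OD2"))
        elif res == "SER":
            pos = _ring_position(chain, geo.pore_radius, geo.inner_ring_z)
            add("OG", "SER", 180, chain, ROLE_HYDROXYL_O, 0.0,
                _SIG_O, _EPS_O, anchor=pos, k=geo.carboxylate_tether_k)
        elif res == "ALA":
            pos = _ring_position(chain, geo.pore_radius + 1.0, geo.inner_ring_z)
            add("CB", "ALA", 180, chain, ROLE_PLACEHOLDER, 0.0,
                _SIG_CB, _EPS_CB, anchor=pos, k=geo.carboxylate_tether_k)
        elif res == "LYS":
            # flexible swing arm: NZ tethered at arm length to the backbone
            # anchor, free to protrude toward the pore axis
            anchor = _ring_position(chain, geo.backbone_radius,
                                    geo.inner_ring_z + 1.0)
            start = _ring_position(
                chain, geo.backbone_radius - geo.sidechain_arm_length,
                geo.inner_ring_z + 1.0)
            add("NZ", "LYS", 180, chain, ROLE_SIDECHAIN_N, qcat,
                _SIG_N, _EPS_N, anchor=anchor, k=geo.sidechain_tether_k,
                length=geo.sidechain_arm_length, initial=start)
        elif res == "ARG":
            # guanidine triad near the outer-ring wall between chains D and
            # A, held planar (plane roughly facing the pore axis) by stiff
            # per-site tethers; charge split evenly, or concentrated on NH1
            # for the charge-redistributed e* variant
            center = _ring_position("C", geo.outer_ring_radius - 1.0,
                                    geo.inner_ring_z + 2.5, angle_offset=135.0)
            axial = np.array([0.0, 0.0, 1.0])
            tangent = _ring_position("C", 1.0, 0.0, angle_offset=135.0 + 90.0)
            if variant == "DERA-estar":
                site_q = (0.90, 0.05, 0.05)
            else:
                site_q = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
            offsets = (axial, -0.5 * axial + 0.866 * tangent,
                       -0.5 * axial - 0.866 * tangent)
            for nm, q, off in zip(("NH1", "NH2", "NE"), site_q, offsets):
                add(nm, "ARG", 180, chain, ROLE_SIDECHAIN_N, q,
                    _SIG_N, _EPS_N,
                    anchor=center + geo.guanidine_site_radius * off,
                    k=geo.guanidine_tether_k)

    # --- outer ring (residue 183) -----------------------------------------
    for chain in PROTEIN_CHAINS:
        res = "GLU"
        if chain == "D" and variant == "DERA-E183D":
            res = "ASP"
        elif chain == "D" and variant == "DERA-E183A":
            res = "ALA"
        if res == "GLU":
            add_carboxylate_pair(chain, "GLU", 183, geo.outer_ring_radius,
                                 geo.outer_ring_z, ("OE1", "OE2"))
        elif res == "ASP":
            # one CH2 shorter: carboxylate sits closer to the backbone
            add_carboxylate_pair(chain, "ASP", 183,
                                 geo.outer_ring_radius + 0.8,
                                 geo.outer_ring_z, ("OD1", "OD2"))
        else:
            pos = _ring_position(chain, geo.outer_ring_radius + 1.0,
                                 geo.outer_ring_z)
            add("CB", "ALA", 183, chain, ROLE_PLACEHOLDER, 0.0,
                _SIG_CB, _EPS_CB, anchor=pos, k=geo.carboxylate_tether_k)

    # --- ions ---------------------------------------------------------------
    resnum = 500
    for i in range(geo.n_ions):
        spec = ion_spec(geo.ion_species)
        # offset from the axis so the start does not clash with the
        # protruding cationic side chain
        pos = np.array([1.8, 1.8, geo.ion_start_z + 3.0 * i])
        add(spec.species, spec.species, resnum + i, SOLVENT_CHAIN, ROLE_ION,
            spec.charge, spec.sigma, spec.epsilon, anchor=pos)

    # --- water beads --------------------------------------------------------
    box = np.asarray(geo.box, float)
    zmax = box[2] / 2.0 - geo.wall_margin
    placed: list[np.ndarray] = []
    resnum = 1000
    attempts = 0
    while len(placed) < geo.n_waters and attempts < 20000:
        attempts += 1
        pos = np.array([rng.uniform(-box[0] / 2, box[0] / 2),
                        rng.uniform(-box[1] / 2, box[1] / 2),
                        rng.uniform(-zmax, zmax)])
        occupied = [a.initial if a.initial is not None else a.anchor
                    for a in atoms if a.anchor is not None]
        if all(_mi_dist(pos, q, box) > 2.6 for q in occupied):
            if all(_mi_dist(pos, p, box) > 2.6 for p in placed):
                placed.append(pos)
    if len(placed) < geo.n_waters:
        raise GeometryError("could not place the requested number of waters")
    for i, pos in enumerate(placed):
        add("OW", "WAT", resnum + i, SOLVENT_CHAIN, ROLE_WATER_O, 0.0,
            _SIG_W, _EPS_W, anchor=pos)

    top = ModelTopology(atoms, box, variant)
    # paranoid bookkeeping: the cationic group must sum to the variant spec
    if variant in CATIONIC_GROUP_CHARGE:
        want = CATIONIC_GROUP_CHARGE[variant]
        got = sum(a.charge for a in top.atoms
                  if a.chain == "C" and a.resnum == 180
                  and a.role == ROLE_SIDECHAIN_N)
        if abs(got - want) > 1e-12:
            raise RuntimeError("cationic-group charge bookkeeping violated")
    return top


def build_solvent_box(ion_species: str = "NA", n_waters: int = 26,
                      box: Sequence[float] = (13.0, 13.0, 13.0),
                      seed: int = 0) -> ModelTopology:
    """Small water-bead box with one ion at the center (the FEP bulk leg)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    atoms: list[Atom] = []
    spec = ion_spec(ion_species)
    atoms.append(Atom(0, spec.species, spec.species, 500, SOLVENT_CHAIN,
                      ROLE_ION, spec.charge, spec.sigma, spec.epsilon,
                      anchor=np.zeros(3)))
    placed: list[np.ndarray] = [np.zeros(3)]
    zmax = box[2] / 2.0 - 2.0
    attempts = 0
    while len(placed) - 1 < n_waters and attempts < 50000:
        attempts += 1
        pos = np.array([rng.uniform(-box[0] / 2, box[0] / 2),
                        rng.uniform(-box[1] / 2, box[1] / 2),
                        rng.uniform(-zmax, zmax)])
        if all(_mi_dist(pos, p, box) > 2.5 for p in placed):
            placed.append(pos)
            atoms.append(Atom(len(atoms), "OW", "WAT", 1000 + len(atoms),
                              SOLVENT_CHAIN, ROLE_WATER_O, 0.0,
                              _SIG_W, _EPS_W, anchor=pos))
    if len(placed) - 1 < n_waters:
        raise GeometryError("could not place the requested number of waters")
    return ModelTopology(atoms, box, f"bulk-{spec.species}")
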
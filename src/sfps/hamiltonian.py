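"""Toy Hamiltonian of the coarse pore model.

Energy terms (kcal/mol):

* Coulomb with a uniform relative dielectric,
  ``U = 332.06 * q_i q_j / (eps_r * r_ij)``, minimum-image in x and y;
* Lennard-Jones 12-6 with Lorentz-Berthelot mixing;
* harmonic tethers ``0.5 k (|x - a| - L)^2`` holding side-chain beads to
  their backbone anchors (L > 0 gives a freely swinging arm);
* soft harmonic z-walls confining mobile beads (membrane mimic);
* optional flat-bottom spherical restraints (zero inside the radius,
  harmonic outside) used by the FEP legs and by pre-equilibration.

Nonbonded interactions within one residue (same chain and residue number)
are excluded.  A single cutoff (default half the smaller lateral box
length) applies to both nonbonded terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .constants import COULOMB
from .system import ModelTopology, SOLVENT_CHAIN


@dataclass
class FlatBottomRestraint:
    """Zero potential within ``radius`` of ``center``, harmonic wall outside."""

    atom_index: int
    center: np.ndarray
    radius: float = 1.5
    k: float = 10.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("flat-bottom radius must be positive")


class ToySystem:
    """Precomputed pair tables and energy/force evaluation for one topology."""

    def __init__(self, topology: ModelTopology,
                 cutoff: float | None = None,
                 dielectric: float | None = None,
                 restraints: Sequence[FlatBottomRestraint] = (),
                 wall_k: float = 10.0,
                 wall_margin: float = 2.0) -> None:
        self.topology = topology
        self.box = np.asarray(topology.box, dtype=float)
        self.dielectric = topology.dielectric if dielectric is None else dielectric
        self.cutoff = cutoff if cutoff is not None else min(self.box[0], self.box[1]) / 2.0
        self.restraints = list(restraints)
        for r in self.restraints:
            if not 0 <= r.atom_index < topology.n_atoms:
                raise IndexError(f"restraint references missing atom {r.atom_index}")
        self.wall_k = wall_k
        self.wall_z = self.box[2] / 2.0 - wall_margin

        n = topology.n_atoms
        self._q = topology.charges()
        self._sig = topology.sigmas()
        self._eps = topology.epsilons()
        self.fixed = topology.fixed_mask()
        # tether arrays
        anchors = np.zeros((n, 3))
        has_anchor = np.zeros(n, dtype=bool)
        tk = np.zeros(n)
        tl = np.zeros(n)
        for i, a in enumerate(topology.atoms):
            if a.anchor is not None and a.tether_k > 0 and not a.fixed:
                anchors[i] = a.anchor
                has_anchor[i] = True
                tk[i] = a.tether_k
                tl[i] = a.tether_length
        self._anchors = anchors
        self._tether_mask = has_anchor
        self._tether_k = tk
        self._tether_len = tl
        # walls act on every mobile bead
        self._wall_mask = ~self.fixed

        # pair lists: i<j, same-residue pairs excluded
        ii, jj = np.triu_indices(n, k=1)
        resid = np.array([(a.chain, a.resnum) for a in topology.atoms])
        same_res = (resid[ii, 0] == resid[jj, 0]) & (resid[ii, 1] == resid[jj, 1])
        keep = ~same_res
        self._ii = ii[keep]
        self._jj = jj[keep]
        self._rebuild_pair_params()

    # -- alchemical support -------------------------------------------------

    def set_lj(self, index: int, sigma: float, epsilon: float) -> None:
        """Override one atom's LJ parameters (alchemical ion mutation)."""
        self._sig = self._sig.copy()
        self._eps = self._eps.copy()
        self._sig[index] = sigma
        self._eps[index] = epsilon
        self._rebuild_pair_params()

    def _rebuild_pair_params(self) -> None:
        ii, jj = self._ii, self._jj
        self._qq = COULOMB * self._q[ii] * self._q[jj] / self.dielectric
        self._sij = 0.5 * (self._sig[ii] + self._sig[jj])
        self._eij = np.sqrt(self._eps[ii] * self._eps[jj])

    # -- geometry helpers ---------------------------------------------------

    def _pair_vectors(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = coords[self._jj] - coords[self._ii]
        for ax in (0, 1):  # periodic in x, y only
            L = self.box[ax]
            d[:, ax] -= L * np.round(d[:, ax] / L)
        r2 = np.einsum("ij,ij->i", d, d)
        return d, r2

    # -- energy -------------------------------------------------------------

    def energy(self, coords: np.ndarray, parts: bool = False):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinates shape {coords.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)")
        d, r2 = self._pair_vectors(coords)
        within = r2 < self.cutoff**2
        r = np.sqrt(r2[within])
        qq = self._qq[within]
        e_coul = float(np.sum(qq / r))
        s2 = (self._sij[within] / r) ** 2
        s6 = s2**3
        e_lj = float(np.sum(4.0 * self._eij[within] * (s6 * s6 - s6)))

        e_teth = 0.0
        if self._tether_mask.any():
            m = self._tether_mask
            dr = coords[m] - self._anchors[m]
            dist = np.linalg.norm(dr, axis=1)
            e_teth = float(np.sum(0.5 * self._tether_k[m]
                                  * (dist - self._tether_len[m]) ** 2))

        z = coords[self._wall_mask, 2]
        over = np.maximum(np.abs(z) - self.wall_z, 0.0)
        e_wall = float(np.sum(0.5 * self.wall_k * over**2))

        e_rest = 0.0
        for rs in self.restraints:
            dvec = coords[rs.atom_index] - rs.center
            dist = np.linalg.norm(dvec)
            if dist > rs.radius:
                e_rest += 0.5 * rs.k * (dist - rs.radius) ** 2

        total = e_coul + e_lj + e_teth + e_wall + e_rest
        if parts:
            return {"coulomb": e_coul, "lj": e_lj, "tether": e_teth,
                    "wall": e_wall, "restraint": e_rest, "total": total}
        return total

    # -- forces -------------------------------------------------------------

    def forces(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        n = self.topology.n_atoms
        F = np.zeros((n, 3))
        d, r2 = self._pair_vectors(coords)
        within = np.flatnonzero(r2 < self.cutoff**2)
        dv = d[within]
        r2w = r2[within]
        r = np.sqrt(r2w)
        qq = self._qq[within]
        eij = self._eij[within]
        s2 = (self._sij[within] ** 2) / r2w
        s6 = s2**3
        # force on j along +d (d = x_j - x_i)
        mag = qq / (r2w * r) + 24.0 * eij * (2.0 * s6 * s6 - s6) / r2w
        fpair = mag[:, None] * dv
        np.add.at(F, self._jj[within], fpair)
        np.add.at(F, self._ii[within], -fpair)

        if self._tether_mask.any():
            m = self._tether_mask
            dr = coords[m] - self._anchors[m]
            dist = np.linalg.norm(dr, axis=1)
            safe = np.maximum(dist, 1e-12)
            coef = -self._tether_k[m] * (dist - self._tether_len[m]) / safe
            F[m] += coef[:, None] * dr

        z = coords[:, 2]
        over = np.abs(z) - self.wall_z
        active = self._wall_mask & (over > 0)
        F[active, 2] -= self.wall_k * over[active] * np.sign(z[active])

        for rs in self.restraints:
            dvec = coords[rs.atom_index] - rs.center
            dist = np.linalg.norm(dvec)
            if dist > rs.radius:
                F[rs.atom_index] -= rs.k * (dist - rs.radius) * dvec / dist
        return F


def potential_energy(topology: ModelTopology, coordinates: np.ndarray,
                     restraints: Sequence[FlatBottomRestraint] = (),
                     cutoff: float | None = None,
                     dielectric: float | None = None) -> float:
    """Total toy-Hamiltonian energy of one configuration, kcal/mol."""
    return ToySystem(topology, cutoff=cutoff, dielectric=dielectric,
                     restraints=restraints).energy(coordinates)
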
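"""Overdamped (position-)Langevin dynamics of the toy pore model.

The Euler-Maruyama update for a unit-mass bead with friction ``gamma``
(1/ps) is ``dx = F dt / gamma + sqrt(2 kT dt / gamma) * xi`` with standard
normal ``xi``.  No momenta are propagated; the stationary distribution of
the scheme is the Boltzmann weight of the toy Hamiltonian up to the usual
O(dt) discretisation bias.  Per-atom forces are capped in magnitude to
keep rare steep Lennard-Jones contacts from destabilising the integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .hamiltonian import FlatBottomRestraint, ToySystem
from .system import ModelTopology
from .trajio import Trajectory


class InstabilityError(RuntimeError):
    pass


@dataclass
class BDProtocol:
    """Brownian-dynamics run parameters."""

    temperature: float = DEFAULT_TEMPERATURE  # K
    friction: float = 2.0                     # 1/ps
    timestep: float = 0.01                    # ps (10 fs)
    n_steps: int = 10000
    save_interval: int = 10
    seed: int = 0
    force_cap: float = 500.0                  # kcal/mol/A, per atom

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def bd_steps(force_fn: Callable[[np.ndarray], np.ndarray],
             coords: np.ndarray,
             n_steps: int,
             dt: float,
             kT: float,
             friction: float,
             rng: np.random.Generator,
             mobile: np.ndarray | None = None,
             wrap_box: np.ndarray | None = None,
             wrap_mask: np.ndarray | None = None,
             force_cap: float = 500.0,
             save_interval: int = 0) -> np.ndarray | list[np.ndarray]:
    """Advance coordinates by ``n_steps``; optionally collect frames.

    Returns the final coordinates, or the list of saved frames when
    ``save_interval`` > 0 (frame saved every ``save_interval`` steps,
    starting at step ``save_interval``).
    """
    x = np.array(coords, dtype=float)
    n = x.shape[0]
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    mob_dt = dt / friction
    noise_sd = np.sqrt(2.0 * kT * dt / friction)
    frames: list[np.ndarray] = []
    for step in range(1, n_steps + 1):
        F = force_fn(x)
        fmag = np.linalg.norm(F, axis=1)
        hot = fmag > force_cap
        if hot.any():
            F[hot] *= (force_cap / fmag[hot])[:, None]
        disp = mob_dt * F
        if kT > 0:
            disp = disp + noise_sd * rng.standard_normal((n, 3))
        x[mobile] += disp[mobile]
        if wrap_box is not None and wrap_mask is not None and wrap_mask.any():
            for ax in (0, 1):
                L = wrap_box[ax]
                x[wrap_mask, ax] -= L * np.round(x[wrap_mask, ax] / L)
        if save_interval and step % save_interval == 0:
            frames.append(x.copy())
    return frames if save_interval else x


def simulate_trajectory(topology: ModelTopology,
                        protocol: BDProtocol,
                        restraints: Sequence[FlatBottomRestraint] = (),
                        start_coordinates: np.ndarray | None = None,
                        external=None,
                        cutoff: float | None = None,
                        dielectric: float | None = None) -> Trajectory:
    """Run seeded Brownian dynamics on a topology and return the frames.

    ``external`` may provide additional ``energy(coords)`` and
    ``forces(coords)`` terms (used e.g. for planted test potentials).
    Identical (topology, protocol, seed) inputs give bit-identical output.
    """
    system = ToySystem(topology, cutoff=cutoff, dielectric=dielectric,
                       restraints=restraints)
    x = (np.array(start_coordinates, dtype=float)
         if start_coordinates is not None
         else topology.initial_coordinates())
    if x.shape != (topology.n_atoms, 3):
        raise ValueError("start coordinates do not match topology atom count")
    rng = np.random.default_rng(protocol.seed)
    kT = thermal_energy(protocol.temperature)
    mobile = ~system.fixed

    if external is not None:
        def force_fn(c):
            return system.forces(c) + external.forces(c)
    else:
        force_fn = system.forces

    free = mobile & ~system._tether_mask  # untethered beads wrap in x/y
    frames = bd_steps(force_fn, x, protocol.n_steps, protocol.timestep, kT,
                      protocol.friction, rng, mobile=mobile,
                      wrap_box=topology.box, wrap_mask=free,
                      force_cap=protocol.force_cap,
                      save_interval=max(1, protocol.save_interval))
    coords = np.array(frames)
    limit = 2.0 * float(np.max(topology.box))
    if not np.all(np.isfinite(coords)) or np.any(np.abs(coords) > limit):
        raise InstabilityError(
            "particle escaped the box (beyond twice the box length); "
            "use a smaller timestep or larger friction")
    times = (np.arange(1, len(frames) + 1)
             * protocol.save_interval * protocol.timestep)
    return Trajectory(coords, topology.box, times)


# ---------------------------------------------------------------------------
# planted-state fixture generator
# ---------------------------------------------------------------------------


@dataclass
class StatePopulation:
    """2-D Gaussian population of a reporter atom in (R, Z) space."""

    mean: tuple[float, float]      # (R, Z), A
    cov: Sequence[Sequence[float]]
    weight: float = 0.5

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            raise ValueError("covariance must be positive definite") from None
        self.cov = c


def plant_labeled_states(open_params: StatePopulation,
                         closed_params: StatePopulation,
                         n_frames: int,
                         seed: int = 0,
                         box_size: float = 200.0):
    """Two-atom fixture trajectory with known open/closed frame labels.

    Atom 0 is the reporter, placed at (x=R, y=0, z=Z) with (R, Z) drawn
    from the population of the frame's ground-truth state; atom 1 is a
    stationary reference marking the filter center at the origin, so the
    radial/axial descriptors computed against it recover the planted
    distributions.  The open fraction equals ``open_params.weight /
    (open_params.weight + closed_params.weight)`` in expectation.

    Returns ``(trajectory, labels)`` with labels 'open'/'closed'.
    """
    rng = np.random.default_rng(seed)
    p_open = open_params.weight / (open_params.weight + closed_params.weight)
    is_open = rng.random(n_frames) < p_open
    rz = np.empty((n_frames, 2))
    n_open = int(is_open.sum())
    if n_open:
        rz[is_open] = rng.multivariate_normal(
            open_params.mean, open_params.cov, size=n_open)
    if n_frames - n_open:
        rz[~is_open] = rng.multivariate_normal(
            closed_params.mean, closed_params.cov, size=n_frames - n_open)
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 0, 0] = rz[:, 0]
    coords[:, 0, 2] = rz[:, 1]
    labels = np.where(is_open, "open", "closed").tolist()
    traj = Trajectory(coords, np.full(3, box_size))
    return traj, labels


def planted_state_topology(box_size: float = 200.0) -> "ModelTopology":
    """Topology matching plant_labeled_states: reporter + center marker."""
    from .system import Atom, ModelTopology, ROLE_SIDECHAIN_N, ROLE_BACKBONE
    atoms = [Atom(0, "NZ", "LYS", 180, "C", ROLE_SIDECHAIN_N, 1.0, 3.3,
                  0.17),
             Atom(1, "REF", "REF", 1, "A", ROLE_BACKBONE, 0.0, 3.5, 0.1,
                  fixed=True)]
    return ModelTopology(atoms, np.full(3, box_size), "planted-states")
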
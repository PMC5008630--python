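"""Alchemical free-energy estimation for the toy pore model.

The Na+ -> K+ transformation interpolates only the ion's Lennard-Jones
parameters, sigma(lambda) = (1-lambda) sigma_Na + lambda sigma_K and
likewise for epsilon; the charge stays +1 throughout, so no soft-core
treatment is needed.  A leg samples each lambda window with Brownian
dynamics under a flat-bottom positional restraint (applied identically in
the bound and bulk legs, so restraint contributions cancel in the
thermodynamic cycle) and estimates per-interval free energies with BAR
(Bennett acceptance ratio, solved self-consistently) or exponential
averaging.

Sign convention: ddG(Na+ -> K+) = dG_bound - dG_bulk; positive values
mean the site prefers Na+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .dynamics import bd_steps
from .hamiltonian import FlatBottomRestraint, ToySystem
from .system import ModelTopology, ion_spec

ESTIMATORS = ("BAR", "EXP-forward", "EXP-backward")


@dataclass
class FEPProtocol:
    """Stratified lambda schedule and per-window sampling parameters."""

    lambdas: Sequence[float] = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 21))
    equil_steps: int = 1000
    prod_steps: int = 4000
    sample_interval: int = 10
    estimator: str = "BAR"
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 2.0
    timestep: float = 0.01
    restraint_radius: float = 1.5
    restraint_k: float = 10.0
    ess_floor: float = 10.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) < 2 or lam[0] != 0.0 or lam[-1] != 1.0 \
                or np.any(np.diff(lam) <= 0):
            raise ValueError(
                "lambda schedule must increase strictly from 0 to 1 with "
                "at least two values")
        if self.restraint_radius <= 0:
            raise ValueError("flat-bottom radius must be positive")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        self.lambdas = lam

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    def compatible_with(self, other: "FEPProtocol") -> bool:
        return (np.array_equal(self.lambdas, other.lambdas)
                and self.temperature == other.temperature
                and self.estimator == other.estimator)


@dataclass
class FEPResult:
    """Per-window and aggregate free energies of one leg (or a cycle)."""

    leg: str                              # 'bound' | 'bulk' | 'cycle'
    dG: float                             # kcal/mol
    window_dG: np.ndarray
    lambdas: np.ndarray
    protocol: FEPProtocol
    window_stats: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    ddG: float | None = None
    repeat_values: list[float] | None = None
    mean: float | None = None
    sd: float | None = None


# ---------------------------------------------------------------------------
# alchemical systems
# ---------------------------------------------------------------------------


class IonAlchemy:
    """Na+ <-> K+ Lennard-Jones interpolation of one ion in a topology."""

    def __init__(self, topology: ModelTopology, ion_index: int,
                 species0: str = "NA", species1: str = "K",
                 restraints: Sequence[FlatBottomRestraint] = (),
                 cutoff: float | None = None,
                 dielectric: float | None = None) -> None:
        self.topology = topology
        self.ion_index = ion_index
        s0, s1 = ion_spec(species0), ion_spec(species1)
        self.end0 = (s0.sigma, s0.epsilon)
        self.end1 = (s1.sigma, s1.epsilon)
        self.system = ToySystem(topology, cutoff=cutoff,
                                dielectric=dielectric, restraints=restraints)
        self._lam = None
        self.set_lambda(0.0)

    def lj_at(self, lam: float) -> tuple[float, float]:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        sigma = (1 - lam) * self.end0[0] + lam * self.end1[0]
        eps = (1 - lam) * self.end0[1] + lam * self.end1[1]
        return sigma, eps

    def set_lambda(self, lam: float) -> None:
        if lam == self._lam:
            return
        sigma, eps = self.lj_at(lam)
        self.system.set_lj(self.ion_index, sigma, eps)
        self._lam = lam

    # -- generic alchemical interface --------------------------------------

    def initial_coordinates(self) -> np.ndarray:
        return self.topology.initial_coordinates()

    @property
    def mobile(self) -> np.ndarray:
        return ~self.system.fixed

    @property
    def wrap_info(self):
        free = self.mobile & ~self.system._tether_mask
        return self.topology.box, free

    def energy(self, coords: np.ndarray, lam: float) -> float:
        self.set_lambda(lam)
        return self.system.energy(coords)

    def forces(self, coords: np.ndarray, lam: float) -> np.ndarray:
        self.set_lambda(lam)
        return self.system.forces(coords)


class HarmonicAlchemy:
    """Analytic test system: one particle, spring constant k0 -> k1.

    The exact free-energy change is (ndim * kT / 2) * ln(k1 / k0),
    independent of the interpolation path.
    """

    def __init__(self, k0: float, k1: float, ndim: int = 1) -> None:
        if k0 <= 0 or k1 <= 0:
            raise ValueError("spring constants must be positive")
        self.k0, self.k1, self.ndim = k0, k1, ndim

    def k_at(self, lam: float) -> float:
        return (1 - lam) * self.k0 + lam * self.k1

    def initial_coordinates(self) -> np.ndarray:
        return np.zeros((1, 3))

    @property
    def mobile(self) -> np.ndarray:
        return np.ones(1, dtype=bool)

    @property
    def wrap_info(self):
        return None, None

    def exact_dG(self, kT: float) -> float:
        return 0.5 * self.ndim * kT * math.log(self.k1 / self.k0)

    def energy(self, coords: np.ndarray, lam: float) -> float:
        x = np.asarray(coords, float)[0, :self.ndim]
        return 0.5 * self.k_at(lam) * float(np.sum(x * x))

    def forces(self, coords: np.ndarray, lam: float) -> np.ndarray:
        F = np.zeros((1, 3))
        x = np.asarray(coords, float)[0]
        F[0, :self.ndim] = -self.k_at(lam) * x[:self.ndim]
        return F


def alchemical_hamiltonian(topology: ModelTopology, ion_index: int,
                           lam: float,
                           restraints: Sequence[FlatBottomRestraint] = (),
                           **kwargs) -> Callable[[np.ndarray], float]:
    """Energy function of the ion-mutation Hamiltonian at a fixed lambda."""
    alch = IonAlchemy(topology, ion_index, restraints=restraints, **kwargs)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lambda coords: alch.energy(coords, lam)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def exp_estimator(dU: np.ndarray, kT: float) -> float:
    """Zwanzig exponential average: dG = -kT ln <exp(-dU/kT)>."""
    dU = np.asarray(dU, dtype=float)
    return float(-kT * (logsumexp(-dU / kT) - math.log(len(dU))))


def bar_estimator(dU_f: np.ndarray, dU_b: np.ndarray, kT: float,
                  tol: float = 1e-10) -> float:
    """Bennett acceptance ratio for one interval.

    ``dU_f`` = U1 - U0 sampled in state 0; ``dU_b`` = U0 - U1 sampled in
    state 1.  Solves the self-consistent equation with bisection, falling
    back to the exponential average if one sample set is missing.
    """
    dU_f = np.asarray(dU_f, dtype=float)
    dU_b = np.asarray(dU_b, dtype=float)
    if len(dU_b) == 0:
        return exp_estimator(dU_f, kT)
    if len(dU_f) == 0:
        return -exp_estimator(dU_b, kT)
    nf, nb = len(dU_f), len(dU_b)
    M = kT * math.log(nf / nb)

    def fermi_log_sum(x: np.ndarray) -> float:
        # log sum_i 1/(1+exp(x_i)) computed stably
        return float(logsumexp(-np.logaddexp(0.0, x)))

    def objective(C: float) -> float:
        # C plays the role of dG; with M = kT ln(nf/nb) the equation is
        # sum f((dU_f - C - M)/kT) = sum f((dU_b + C + M)/kT), f = Fermi
        lf = fermi_log_sum((dU_f - C - M) / kT)
        lb = fermi_log_sum((dU_b + C + M) / kT)
        return lf - lb

    lo = min(float(np.min(dU_f)), float(-np.max(dU_b))) - 50 * kT
    hi = max(float(np.max(dU_f)), float(-np.min(dU_b))) + 50 * kT
    flo, fhi = objective(lo), objective(hi)
    if flo * fhi > 0:
        # no bracket (extreme non-overlap); fall back to EXP
        return exp_estimator(dU_f, kT)
    C = brentq(objective, lo, hi, xtol=tol)
    return float(C)


def effective_sample_size(dU: np.ndarray, kT: float) -> float:
    if len(dU) == 0:
        return 0.0
    w = np.exp(-(dU - np.min(dU)) / kT)
    return float(np.sum(w) ** 2 / np.sum(w * w))


# ---------------------------------------------------------------------------
# leg runner
# ---------------------------------------------------------------------------


def run_fep_leg(alchemy, protocol: FEPProtocol, seed: int,
                leg: str = "bound",
                start_coordinates: np.ndarray | None = None,
                reverse: bool = False) -> FEPResult:
    """Sample all lambda windows of one leg and estimate its dG.

    Windows are visited in order, coordinates carrying over between
    neighbouring states.  In every state, forward (to the next lambda) and
    backward (to the previous lambda) energy differences are collected;
    per-interval free energies use the protocol's estimator.  With
    ``reverse=True`` the schedule is traversed 1 -> 0 and the reported dG
    refers to the reversed transformation.
    """
    lambdas = np.array(protocol.lambdas, dtype=float)
    if reverse:
        lambdas = lambdas[::-1]
    kT = protocol.kT
    rng = np.random.default_rng(seed)
    x = (np.array(start_coordinates, float) if start_coordinates is not None
         else alchemy.initial_coordinates())
    wrap_box, wrap_mask = alchemy.wrap_info
    n_states = len(lambdas)
    fwd: list[list[float]] = [[] for _ in range(n_states)]
    bwd: list[list[float]] = [[] for _ in range(n_states)]

    for i, lam in enumerate(lambdas):
        def force_fn(c, _lam=lam):
            return alchemy.forces(c, _lam)

        x = bd_steps(force_fn, x, protocol.equil_steps, protocol.timestep,
                     kT, protocol.friction, rng, mobile=alchemy.mobile,
                     wrap_box=wrap_box, wrap_mask=wrap_mask)
        n_samples = max(1, protocol.prod_steps // protocol.sample_interval)
        for _ in range(n_samples):
            x = bd_steps(force_fn, x, protocol.sample_interval,
                         protocol.timestep, kT, protocol.friction, rng,
                         mobile=alchemy.mobile, wrap_box=wrap_box,
                         wrap_mask=wrap_mask)
            u_here = alchemy.energy(x, lam)
            if i + 1 < n_states:
                fwd[i].append(alchemy.energy(x, lambdas[i + 1]) - u_here)
            if i > 0:
                bwd[i].append(alchemy.energy(x, lambdas[i - 1]) - u_here)

    window_dG = []
    stats_rows = []
    warnings_list: list[str] = []
    for i in range(n_states - 1):
        dU_f = np.array(fwd[i])
        dU_b = np.array(bwd[i + 1])
        if protocol.estimator == "BAR":
            dg = bar_estimator(dU_f, dU_b, kT)
        elif protocol.estimator == "EXP-forward":
            dg = exp_estimator(dU_f, kT)
        else:
            dg = -exp_estimator(dU_b, kT)
        ess_f = effective_sample_size(dU_f, kT)
        ess_b = effective_sample_size(dU_b, kT)
        if min(ess_f, ess_b) < protocol.ess_floor:
            warnings_list.append(
                f"window {i} ({lambdas[i]:.3f}->{lambdas[i + 1]:.3f}): "
                f"effective sample size {min(ess_f, ess_b):.1f} below "
                f"floor {protocol.ess_floor}")
        window_dG.append(dg)
        stats_rows.append({
            "lambda_from": lambdas[i], "lambda_to": lambdas[i + 1],
            "dG_kcal_mol": dg, "n_forward": len(dU_f),
            "n_backward": len(dU_b), "ess_forward": ess_f,
            "ess_backward": ess_b,
            "mean_dU_forward": float(dU_f.mean()) if len(dU_f) else math.nan,
            "var_dU_forward": float(dU_f.var()) if len(dU_f) else math.nan,
        })
    window_dG = np.array(window_dG)
    return FEPResult(leg=leg, dG=float(window_dG.sum()),
                     window_dG=window_dG, lambdas=lambdas,
                     protocol=protocol,
                     window_stats=pd.DataFrame(stats_rows),
                     warnings=warnings_list)


def ddG(bound: FEPResult, bulk: FEPResult) -> float:
    """Relative binding free energy: dG_bound - dG_bulk (kcal/mol).

    Positive values indicate a Na+-preferred site.  Both legs must share
    one protocol (schedule, temperature, estimator).
    """
    if not bound.protocol.compatible_with(bulk.protocol):
        raise ValueError("bound and bulk legs use incompatible protocols")
    return float(bound.dG - bulk.dG)


def repeat_and_aggregate(run: Callable[[int], float],
                         seeds: Sequence[int]) -> dict:
    """Run a free-energy calculation once per seed; report mean and SD.

    ``run`` maps a seed to a scalar free energy (a leg dG or a ddG).
    Seeds must be distinct; the sample standard deviation (ddof=1) needs
    at least two repeats and is otherwise absent (None).
    """
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    values = [float(run(s)) for s in seeds]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return {"values": values, "mean": mean, "sd": sd, "n": len(values)}


# ---------------------------------------------------------------------------
# thermodynamic-integration oracle
# ---------------------------------------------------------------------------


def thermodynamic_integration(alchemy, n_lambdas: int = 64,
                              equil_steps: int = 300, prod_steps: int = 1200,
                              sample_interval: int = 10,
                              temperature: float = DEFAULT_TEMPERATURE,
                              friction: float = 2.0, timestep: float = 0.01,
                              seed: int = 0, h: float = 1e-4) -> float:
    """Dense-schedule TI estimate of dG (trapezoid over <dU/dlambda>).

    The lambda-derivative is taken by central finite differences of the
    alchemical energy, making the routine independent of the analytic
    window estimators it serves as an oracle for.
    """
    lambdas = np.linspace(0.0, 1.0, n_lambdas)
    kT = thermal_energy(temperature)
    rng = np.random.default_rng(seed)
    x = alchemy.initial_coordinates()
    wrap_box, wrap_mask = alchemy.wrap_info
    means = []
    for lam in lambdas:
        def force_fn(c, _lam=lam):
            return alchemy.forces(c, _lam)

        x = bd_steps(force_fn, x, equil_steps, timestep, kT, friction, rng,
                     mobile=alchemy.mobile, wrap_box=wrap_box,
                     wrap_mask=wrap_mask)
        lo, hi = max(0.0, lam - h), min(1.0, lam + h)
        vals = []
        n_samples = max(1, prod_steps // sample_interval)
        for _ in range(n_samples):
            x = bd_steps(force_fn, x, sample_interval, timestep, kT,
                         friction, rng, mobile=alchemy.mobile,
                         wrap_box=wrap_box, wrap_mask=wrap_mask)
            vals.append((alchemy.energy(x, hi) - alchemy.energy(x, lo))
                        / (hi - lo))
        means.append(float(np.mean(vals)))
    return float(np.trapezoid(means, lambdas))
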
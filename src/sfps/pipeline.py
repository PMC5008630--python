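"""End-to-end orchestration: generate -> describe -> classify -> bind ->
interact -> FEP, as one seeded, configured, logged run.

A run is fully described by a RunConfig (serialisable to an INI file with
[run], [geometry], [protocol], [sites], [classifier], [clustering],
[hbond] and [fep] sections).  Every stage derives its seed from the
global seed through a counter-based scheme (stage index spawns an
independent stream), so adding a stage never perturbs earlier stages.
Identical config + seed reruns produce identical tables.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import logging
import os
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import (BindingSiteDefinition, analysis_window,
                      cluster_binding_modes, default_site_definitions,
                      free_energy_map, modes_table, site_occupancy)
from .constants import thermal_energy
from .descriptors import SFCenterDefinition, rz_series
from .dynamics import BDProtocol, StatePopulation, plant_labeled_states, \
    simulate_trajectory
from .fep import FEPProtocol, FlatBottomRestraint, IonAlchemy, ddG, \
    repeat_and_aggregate, run_fep_leg
from .hamiltonian import ToySystem
from .interactions import (HBondCriteria, classify_mode_coordination,
                           group_cation_distance, hbond_occupancy)
from .states import classify_frames, confidence_regions, fit_separator
from .system import (GeometryConfig, ModelTopology, build_model_topology,
                     build_solvent_box, ion_spec, ROLE_SIDECHAIN_N)
from .trajio import select_atoms, write_table, write_topology_pdb, \
    write_topology_table, write_trajectory

log = logging.getLogger("sfps")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are kept on disk."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: int) -> int:
    """Counter-based seed derivation: independent stream per stage index."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


def derive_coordination_cutoffs(ranges: dict[str, tuple[float, float]]
                                ) -> dict[str, float]:
    """Cutoff = mean of the coordinating-range limits, at two decimals.

    Rounding is half-to-even at the second decimal, e.g. the K+ range
    (2.80, 3.65) gives 3.225 -> 3.22.
    """
    out = {}
    for species, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(
                f"{species}: inverted or degenerate range ({lo}, {hi})")
        mid = (Decimal(str(lo)) + Decimal(str(hi))) / 2
        out[species] = float(mid.quantize(Decimal("0.01"),
                                          rounding=ROUND_HALF_EVEN))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    variant: str = "DEKA"
    ion_species: str = "NA"
    out_dir: str = "sfps_out"
    seed: int = 1
    # geometry
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    dielectric: float = 10.0
    # BD protocol
    temperature: float = 310.0
    friction: float = 2.0
    timestep: float = 0.01
    n_steps: int = 20000
    save_interval: int = 20
    # descriptors / classifier
    center_expression: str = "role backbone and resnum 180"
    svm_C: float = 10.0
    confidence_level: float = 0.95
    # planted training populations for the state classifier (R, Z) means
    train_open_mean: tuple[float, float] = (6.0, 3.0)
    train_closed_mean: tuple[float, float] = (2.0, -1.0)
    train_sigma: float = 0.6
    train_frames: int = 2000
    # binding analysis
    map_bin_width: float = 0.5
    map_cap: float = 6.0
    cluster_cutoff: float = 1.5
    occupancy_floor: float = 0.05
    window_fraction: float = 0.75
    # H-bond criterion
    hbond_cutoff: float = 3.5
    # FEP
    fep_enabled: bool = False
    fep_n_windows: int = 21
    fep_equil_steps: int = 1000
    fep_prod_steps: int = 4000
    fep_sample_interval: int = 10
    fep_estimator: str = "BAR"
    fep_restraint_radius: float = 1.5
    fep_restraint_k: float = 10.0
    fep_repeats: int = 3
    fep_bulk_waters: int = 26

    # -- serialization ------------------------------------------------------

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp["run"] = {"variant": self.variant, "ion_species": self.ion_species,
                     "out_dir": self.out_dir, "seed": str(self.seed),
                     "dielectric": repr(self.dielectric)}
        g = self.geometry
        cp["geometry"] = {
            "pore_radius": repr(g.pore_radius),
            "backbone_radius": repr(g.backbone_radius),
            "outer_ring_radius": repr(g.outer_ring_radius),
            "outer_ring_z": repr(g.outer_ring_z),
            "box": " ".join(repr(v) for v in g.box),
            "n_waters": str(g.n_waters),
            "n_ions": str(g.n_ions),
        }
        cp["protocol"] = {
            "temperature": repr(self.temperature),
            "friction": repr(self.friction),
            "timestep": repr(self.timestep),
            "n_steps": str(self.n_steps),
            "save_interval": str(self.save_interval),
        }
        cp["classifier"] = {
            "center_expression": self.center_expression,
            "svm_c": repr(self.svm_C),
            "confidence_level": repr(self.confidence_level),
            "train_open_mean": " ".join(map(repr, self.train_open_mean)),
            "train_closed_mean": " ".join(map(repr, self.train_closed_mean)),
            "train_sigma": repr(self.train_sigma),
            "train_frames": str(self.train_frames),
        }
        cp["clustering"] = {
            "map_bin_width": repr(self.map_bin_width),
            "map_cap": repr(self.map_cap),
            "cluster_cutoff": repr(self.cluster_cutoff),
            "occupancy_floor": repr(self.occupancy_floor),
            "window_fraction": repr(self.window_fraction),
        }
        cp["hbond"] = {"cutoff": repr(self.hbond_cutoff)}
        cp["fep"] = {
            "enabled": str(self.fep_enabled),
            "n_windows": str(self.fep_n_windows),
            "equil_steps": str(self.fep_equil_steps),
            "prod_steps": str(self.fep_prod_steps),
            "sample_interval": str(self.fep_sample_interval),
            "estimator": self.fep_estimator,
            "restraint_radius": repr(self.fep_restraint_radius),
            "restraint_k": repr(self.fep_restraint_k),
            "repeats": str(self.fep_repeats),
            "bulk_waters": str(self.fep_bulk_waters),
        }
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        cfg = cls()
        r = cp["run"]
        cfg.variant = r.get("variant", cfg.variant)
        cfg.ion_species = r.get("ion_species", cfg.ion_species)
        cfg.out_dir = r.get("out_dir", cfg.out_dir)
        cfg.seed = r.getint("seed", cfg.seed)
        cfg.dielectric = r.getfloat("dielectric", cfg.dielectric)
        if cp.has_section("geometry"):
            g = cp["geometry"]
            cfg.geometry = GeometryConfig(
                pore_radius=g.getfloat("pore_radius", 3.5),
                backbone_radius=g.getfloat("backbone_radius", 6.0),
                outer_ring_radius=g.getfloat("outer_ring_radius", 5.0),
                outer_ring_z=g.getfloat("outer_ring_z", 4.0),
                box=tuple(float(v) for v in
                          g.get("box", "24.0 24.0 28.0").split()),
                n_waters=g.getint("n_waters", 40),
                n_ions=g.getint("n_ions", 1),
                ion_species=cfg.ion_species,
            )
        cfg.geometry.ion_species = cfg.ion_species
        if cp.has_section("protocol"):
            p = cp["protocol"]
            cfg.temperature = p.getfloat("temperature", cfg.temperature)
            cfg.friction = p.getfloat("friction", cfg.friction)
            cfg.timestep = p.getfloat("timestep", cfg.timestep)
            cfg.n_steps = p.getint("n_steps", cfg.n_steps)
            cfg.save_interval = p.getint("save_interval", cfg.save_interval)
        if cp.has_section("classifier"):
            c = cp["classifier"]
            cfg.center_expression = c.get("center_expression",
                                          cfg.center_expression)
            cfg.svm_C = c.getfloat("svm_c", cfg.svm_C)
            cfg.confidence_level = c.getfloat("confidence_level",
                                              cfg.confidence_level)
            cfg.train_open_mean = tuple(
                float(v) for v in c.get("train_open_mean", "6.0 3.0").split())
            cfg.train_closed_mean = tuple(
                float(v) for v in
                c.get("train_closed_mean", "2.0 -1.0").split())
            cfg.train_sigma = c.getfloat("train_sigma", cfg.train_sigma)
            cfg.train_frames = c.getint("train_frames", cfg.train_frames)
        if cp.has_section("clustering"):
            c = cp["clustering"]
            cfg.map_bin_width = c.getfloat("map_bin_width", cfg.map_bin_width)
            cfg.map_cap = c.getfloat("map_cap", cfg.map_cap)
            cfg.cluster_cutoff = c.getfloat("cluster_cutoff",
                                            cfg.cluster_cutoff)
            cfg.occupancy_floor = c.getfloat("occupancy_floor",
                                             cfg.occupancy_floor)
            cfg.window_fraction = c.getfloat("window_fraction",
                                             cfg.window_fraction)
        if cp.has_section("hbond"):
            cfg.hbond_cutoff = cp["hbond"].getfloat("cutoff",
                                                    cfg.hbond_cutoff)
        if cp.has_section("fep"):
            f = cp["fep"]
            cfg.fep_enabled = f.getboolean("enabled", cfg.fep_enabled)
            cfg.fep_n_windows = f.getint("n_windows", cfg.fep_n_windows)
            cfg.fep_equil_steps = f.getint("equil_steps", cfg.fep_equil_steps)
            cfg.fep_prod_steps = f.getint("prod_steps", cfg.fep_prod_steps)
            cfg.fep_sample_interval = f.getint("sample_interval",
                                               cfg.fep_sample_interval)
            cfg.fep_estimator = f.get("estimator", cfg.fep_estimator)
            cfg.fep_restraint_radius = f.getfloat("restraint_radius",
                                                  cfg.fep_restraint_radius)
            cfg.fep_restraint_k = f.getfloat("restraint_k",
                                             cfg.fep_restraint_k)
            cfg.fep_repeats = f.getint("repeats", cfg.fep_repeats)
            cfg.fep_bulk_waters = f.getint("bulk_waters", cfg.fep_bulk_waters)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_ini().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# FEP convenience wrappers
# ---------------------------------------------------------------------------


def fep_protocol_from_config(cfg: RunConfig) -> FEPProtocol:
    return FEPProtocol(
        lambdas=np.linspace(0.0, 1.0, cfg.fep_n_windows),
        equil_steps=cfg.fep_equil_steps,
        prod_steps=cfg.fep_prod_steps,
        sample_interval=cfg.fep_sample_interval,
        estimator=cfg.fep_estimator,
        temperature=cfg.temperature,
        friction=cfg.friction,
        timestep=cfg.timestep,
        restraint_radius=cfg.fep_restraint_radius,
        restraint_k=cfg.fep_restraint_k,
    )


def run_bound_leg(topology: ModelTopology, ion_index: int,
                  restraint_center: np.ndarray, protocol: FEPProtocol,
                  seed: int, start_coordinates: np.ndarray | None = None,
                  dielectric: float | None = None):
    restraint = FlatBottomRestraint(ion_index, restraint_center,
                                    protocol.restraint_radius,
                                    protocol.restraint_k)
    alch = IonAlchemy(topology, ion_index, restraints=[restraint],
                      dielectric=dielectric)
    if start_coordinates is None:
        start_coordinates = topology.initial_coordinates()
        start_coordinates[ion_index] = restraint_center
    return run_fep_leg(alch, protocol, seed, leg="bound",
                       start_coordinates=start_coordinates)


def run_bulk_leg(protocol: FEPProtocol, seed: int, n_waters: int = 26,
                 ion_species: str = "NA",
                 dielectric: float | None = None):
    top = build_solvent_box(ion_species=ion_species, n_waters=n_waters,
                            seed=stage_seed(seed, 97))
    restraint = FlatBottomRestraint(0, np.zeros(3),
                                    protocol.restraint_radius,
                                    protocol.restraint_k)
    alch = IonAlchemy(top, 0, restraints=[restraint],
                      dielectric=dielectric)
    return run_fep_leg(alch, protocol, seed, leg="bulk")


# ---------------------------------------------------------------------------
# the experiment driver
# ---------------------------------------------------------------------------


def run_experiment(config: RunConfig) -> dict:
    """Execute the full analysis pipeline and write the report bundle.

    Returns a dict of the in-memory results keyed by stage.  On stage
    failure a StageError names the stage; outputs of completed stages
    remain in the output directory.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    results: dict = {"config": cfg}
    stage = "setup"

    def path(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    try:
        # -- stage 0: model ------------------------------------------------
        stage = "build_topology"
        log.info("building %s topology", cfg.variant)
        topology = build_model_topology(cfg.variant, cfg.geometry,
                                        seed=stage_seed(cfg.seed, 0))
        topology.dielectric = cfg.dielectric
        write_topology_table(topology, path("topology.tsv"))
        write_topology_pdb(topology, path("topology.pdb"))
        results["topology"] = topology
        ion_indices = topology.indices(role="ion")

        # -- stage 1: trajectory -------------------------------------------
        stage = "simulate"
        proto = BDProtocol(temperature=cfg.temperature,
                           friction=cfg.friction, timestep=cfg.timestep,
                           n_steps=cfg.n_steps,
                           save_interval=cfg.save_interval,
                           seed=stage_seed(cfg.seed, 1))
        log.info("simulating %d steps", cfg.n_steps)
        traj = simulate_trajectory(topology, proto)
        write_trajectory(traj, path("trajectory.dcd"), "DCD", topology)
        results["trajectory"] = traj

        # -- stage 2: descriptors ------------------------------------------
        stage = "descriptors"
        center = SFCenterDefinition(cfg.center_expression)
        reporters = topology.indices(role=ROLE_SIDECHAIN_N)
        if reporters:
            rep_series = rz_series(traj, topology, reporters[0], center)
            rep_series.to_tsv(path("reporter_rz.tsv"))
            results["reporter_rz"] = rep_series
        ion_series = rz_series(traj, topology, ion_indices[0], center)
        ion_series.to_tsv(path("ion_rz.tsv"))
        results["ion_rz"] = ion_series

        # -- stage 3: state model ------------------------------------------
        stage = "state_model"
        if reporters:
            s = cfg.train_sigma
            open_pop = StatePopulation(cfg.train_open_mean,
                                       [[s * s, 0], [0, s * s]], 0.5)
            closed_pop = StatePopulation(cfg.train_closed_mean,
                                         [[s * s, 0], [0, s * s]], 0.5)
            ttraj, tlabels = plant_labeled_states(
                open_pop, closed_pop, cfg.train_frames,
                seed=stage_seed(cfg.seed, 2))
            tpts = np.column_stack([ttraj.coordinates[:, 0, 0],
                                    ttraj.coordinates[:, 0, 2]])
            boundary = fit_separator(tpts, tlabels, C=cfg.svm_C)
            boundary = confidence_regions(boundary, tpts, tlabels,
                                          cfg.confidence_level)
            pts = np.column_stack([rep_series.R, rep_series.Z])
            labels, fractions = classify_frames(pts, boundary)
            with open(path("state_boundary.txt"), "w") as fh:
                fh.write(boundary.to_record() + "\n")
            write_table(pd.DataFrame([{
                "state": k, "fraction": v} for k, v in fractions.items()]),
                path("state_occupancy.tsv"))
            results["state_fractions"] = fractions
            results["state_boundary"] = boundary

        # -- stage 4: binding ----------------------------------------------
        stage = "binding"
        sites = default_site_definitions()
        fractions, site_labels = site_occupancy(
            traj, topology, ion_indices[0], sites, center)
        write_table(pd.DataFrame(
            [{"site": k, "occupancy": v} for k, v in fractions.items()]),
            path("site_occupancy.tsv"))
        results["site_occupancy"] = fractions
        fmap = free_energy_map(ion_series, cfg.map_bin_width,
                               thermal_energy(cfg.temperature), cfg.map_cap)
        fmap.to_tsv(path("free_energy_map.tsv"))
        results["free_energy_map"] = fmap

        window = analysis_window(traj.n_frames, cfg.window_fraction)
        bound = [f for f in window if site_labels[f] == "Site_OC"]
        modes = []
        if bound:
            modes = cluster_binding_modes(
                traj, topology, ion_indices[0], bound,
                cutoff=cfg.cluster_cutoff,
                occupancy_floor=cfg.occupancy_floor,
                n_analyzed_frames=len(window))
        write_table(modes_table(modes) if modes else
                    pd.DataFrame(columns=["rank", "occupancy", "n_frames",
                                          "representative_frame", "main",
                                          "too_small_for_fep"]),
                    path("binding_modes.tsv"))
        results["modes"] = modes

        # -- stage 5: interactions -----------------------------------------
        stage = "interactions"
        spec = ion_spec(cfg.ion_species)
        hrows = []
        if reporters:
            donors = "role sidechain-N and resnum 180"
            for label, acceptors in (
                    ("outer_ring_183", "role carboxylate-O and resnum 183"),
                    ("inner_ring_180", "role carboxylate-O and resnum 180")):
                try:
                    rep = hbond_occupancy(traj, topology, donors, acceptors,
                                          HBondCriteria(cfg.hbond_cutoff))
                except ValueError:
                    continue
                hrows.append({"pair": label, "occupancy": rep.occupancy,
                              "bifurcate_fraction": rep.bifurcate_fraction})
        write_table(pd.DataFrame(
            hrows, columns=["pair", "occupancy", "bifurcate_fraction"]),
            path("hbond_occupancy.tsv"))
        results["hbonds"] = hrows

        crows = []
        for m in modes:
            summary = classify_mode_coordination(m, traj, topology,
                                                 ion_indices[0], spec)
            summary["rank"] = m.rank
            if reporters:
                dists, exceed = group_cation_distance(
                    traj, topology, "role sidechain-N and resnum 180",
                    ion_indices[0])
                mdist = float(np.mean(dists[m.member_frames]))
                summary["mean_group_ion_distance_A"] = mdist
            crows.append(summary)
        write_table(pd.DataFrame(crows) if crows else
                    pd.DataFrame(columns=["rank", "mean_carboxylate_O",
                                          "tight_coordination"]),
                    path("mode_coordination.tsv"))
        results["mode_coordination"] = crows

        # -- stage 6: FEP ---------------------------------------------------
        stage = "fep"
        if cfg.fep_enabled and modes:
            fp = fep_protocol_from_config(cfg)
            frows = []
            eligible = [m for m in modes if m.main and not
                        m.too_small_for_fep] or modes[:1]
            for m in eligible:
                def one_ddg(seed_i: int) -> float:
                    bound_res = run_bound_leg(
                        topology, ion_indices[0], m.restraint_center, fp,
                        seed=seed_i, dielectric=cfg.dielectric)
                    bulk_res = run_bulk_leg(
                        fp, seed=seed_i + 1, n_waters=cfg.fep_bulk_waters,
                        ion_species=cfg.ion_species,
                        dielectric=cfg.dielectric)
                    return ddG(bound_res, bulk_res)

                seeds = [stage_seed(cfg.seed, 10 + 10 * m.rank + r)
                         for r in range(cfg.fep_repeats)]
                agg = repeat_and_aggregate(one_ddg, seeds)
                frows.append({
                    "system": cfg.variant, "ion": cfg.ion_species,
                    "mode": m.rank, "ddG_kcal_mol": agg["mean"],
                    "sd_kcal_mol": (float("nan") if agg["sd"] is None
                                    else agg["sd"]),
                    "n_repeats": agg["n"]})
            write_table(pd.DataFrame(frows), path("ddG_summary.tsv"))
            results["ddG"] = frows

        # -- manifest -------------------------------------------------------
        stage = "manifest"
        with open(path("manifest.txt"), "w") as fh:
            fh.write(f"sfps_version\t{__version__}\n")
            fh.write(f"config_hash\t{cfg.config_hash()}\n")
            fh.write(f"global_seed\t{cfg.seed}\n")
            for k in range(3):
                fh.write(f"stage_seed_{k}\t{stage_seed(cfg.seed, k)}\n")
        with open(path("run.cfg"), "w") as fh:
            fh.write(cfg.to_ini())
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return results
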
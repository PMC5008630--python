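"""Ion-binding analyses: site occupancy, Boltzmann-inverted free-energy
maps, permeation events and structural clustering of binding modes.

Binding sites are axial slabs (z-interval relative to the SF center,
capped at a maximum radial distance).  The outer constriction site
(Site_OC) is where the cation contacts the residue-180 carboxylates; its
default extent on the bundled geometry is |Z| <= 2 A, R <= 4 A.

Free energies come from Boltzmann inversion of the sampled (R, Z)
probability density: G = -kT ln(count / count_max), with empty bins held
at a display cap.

Binding modes at Site_OC are found by average-linkage hierarchical
clustering of per-frame feature vectors (distances from the ion to each
residue-180 side-chain O/N atom, fixed atom order), cut at a merge
distance; clusters are ranked by size, the top two are the *main* modes,
and modes below an occupancy floor are flagged as too small for FEP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .constants import thermal_energy
from .descriptors import RZSeries, SFCenterDefinition, rz_series
from .system import (ModelTopology, ROLE_CARBOXYLATE_O, ROLE_SIDECHAIN_N)
from .trajio import Trajectory

UNBOUND = "unbound"


class SiteOverlapError(ValueError):
    pass


@dataclass(frozen=True)
class BindingSiteDefinition:
    """Axial slab site: z interval (relative to SF center) and max radius."""

    name: str
    z_interval: tuple[float, float]
    max_R: float

    def __post_init__(self) -> None:
        if self.z_interval[0] >= self.z_interval[1]:
            raise ValueError(f"site {self.name}: need z_lo < z_hi")
        if self.max_R <= 0:
            raise ValueError(f"site {self.name}: max_R must be positive")

    def contains(self, Z: np.ndarray, R: np.ndarray) -> np.ndarray:
        lo, hi = self.z_interval
        return (Z >= lo) & (Z < hi) & (np.asarray(R) <= self.max_R)


def default_site_definitions() -> list[BindingSiteDefinition]:
    """Site ladder on the bundled model geometry, extracellular to interior."""
    return [
        BindingSiteDefinition("Ion_EX", (6.0, 10.0), 6.0),
        BindingSiteDefinition("Site_HFS", (2.0, 6.0), 6.0),
        BindingSiteDefinition("Site_OC", (-2.0, 2.0), 4.0),
        BindingSiteDefinition("Site_CEN", (-4.0, -2.0), 4.0),
        BindingSiteDefinition("Site_INT", (-6.0, -4.0), 4.0),
        BindingSiteDefinition("Site_IN", (-9.0, -6.0), 6.0),
    ]


def _check_disjoint(sites: Sequence[BindingSiteDefinition]) -> None:
    names = [s.name for s in sites]
    if len(set(names)) != len(names):
        raise ValueError("site names must be unique")
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            lo = max(a.z_interval[0], b.z_interval[0])
            hi = min(a.z_interval[1], b.z_interval[1])
            if lo < hi:
                raise SiteOverlapError(
                    f"sites {a.name} and {b.name} overlap in z on "
                    f"[{lo}, {hi}]")


def site_occupancy(trajectory: Trajectory, topology: ModelTopology,
                   ion_indices: Sequence[int] | int,
                   sites: Sequence[BindingSiteDefinition] | None = None,
                   center: SFCenterDefinition | None = None):
    """Per-site occupancy fractions and per-frame site labels.

    Returns ``(fractions, labels)``; with several ions both are dicts
    keyed by ion index.  Fractions include an 'unbound' entry so that the
    values sum to 1 per ion.
    """
    sites = list(sites) if sites is not None else default_site_definitions()
    _check_disjoint(sites)
    if np.isscalar(ion_indices):
        ion_indices = [int(ion_indices)]
        scalar = True
    else:
        scalar = False
    frac_out, label_out = {}, {}
    for ion in ion_indices:
        series = rz_series(trajectory, topology, ion, center)
        labels = np.full(len(series), UNBOUND, dtype=object)
        for site in sites:
            inside = site.contains(series.Z, series.R)
            labels[inside] = site.name
        n = max(len(labels), 1)
        fractions = {s.name: float(np.sum(labels == s.name)) / n
                     for s in sites}
        fractions[UNBOUND] = float(np.sum(labels == UNBOUND)) / n
        frac_out[ion] = fractions
        label_out[ion] = labels.tolist()
    if scalar:
        ion = ion_indices[0]
        return frac_out[ion], label_out[ion]
    return frac_out, label_out


# ---------------------------------------------------------------------------
# free-energy map
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyMap:
    R_edges: np.ndarray
    Z_edges: np.ndarray
    counts: np.ndarray          # (nR, nZ)
    free_energy: np.ndarray     # kcal/mol, min over sampled bins = 0
    kT: float
    cap: float

    def to_frame(self) -> pd.DataFrame:
        rc = 0.5 * (self.R_edges[:-1] + self.R_edges[1:])
        zc = 0.5 * (self.Z_edges[:-1] + self.Z_edges[1:])
        rr, zz = np.meshgrid(rc, zc, indexing="ij")
        return pd.DataFrame({
            "R_A": rr.ravel(), "Z_A": zz.ravel(),
            "count": self.counts.ravel().astype(int),
            "G_kcal_mol": self.free_energy.ravel(),
        })

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")


def free_energy_map(series: RZSeries | np.ndarray,
                    bin_width: float = 0.5,
                    kT: float | None = None,
                    cap: float = 6.0) -> FreeEnergyMap:
    """Boltzmann inversion of the sampled (R, Z) density.

    ``series`` is an RZSeries or an (n, 2) array of (R, Z) samples.
    G = -kT ln(count / count_max) for sampled bins; empty bins carry the
    cap value.  Doubling every count leaves G unchanged.
    """
    if kT is None:
        kT = thermal_energy()
    if kT <= 0:
        raise ValueError("kT must be positive")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(series, RZSeries):
        R, Z = series.R, series.Z
    else:
        arr = np.asarray(series, dtype=float)
        R, Z = arr[:, 0], arr[:, 1]
    if len(R) == 0:
        raise ValueError("empty series")

    def edges(v):
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    R_edges, Z_edges = edges(R), edges(Z)
    counts, _, _ = np.histogram2d(R, Z, bins=(R_edges, Z_edges))
    G = np.full_like(counts, float(cap))
    sampled = counts > 0
    G[sampled] = -kT * np.log(counts[sampled] / counts.max())
    return FreeEnergyMap(R_edges, Z_edges, counts, G, kT, cap)


# ---------------------------------------------------------------------------
# permeation events
# ---------------------------------------------------------------------------


def detect_permeation_events(series: RZSeries | np.ndarray,
                             z_threshold: float,
                             dwell: int = 5) -> list[tuple[int, str]]:
    """Debounced signed crossings of a z threshold.

    A crossing at frame f counts when the ion stays on the far side for at
    least ``dwell`` consecutive frames starting at f.  Direction 'inward'
    means decreasing z (extracellular to intracellular).
    """
    z = series.Z if isinstance(series, RZSeries) else np.asarray(series, float)
    if len(z) == 0:
        return []
    events: list[tuple[int, str]] = []
    side = 1 if z[0] >= z_threshold else -1
    i = 1
    while i < len(z):
        new_side = 1 if z[i] >= z_threshold else -1
        if new_side != side:
            window = z[i:i + dwell]
            stays = (len(window) >= dwell and
                     np.all((window >= z_threshold) == (new_side == 1)))
            if stays:
                events.append((i, "inward" if new_side < side else "outward"))
                side = new_side
        i += 1
    return events


# ---------------------------------------------------------------------------
# binding-mode clustering
# ---------------------------------------------------------------------------


@dataclass
class BindingMode:
    rank: int
    member_frames: list[int]
    occupancy: float
    centroid: np.ndarray          # feature vector, A
    representative_frame: int
    restraint_center: np.ndarray  # ion position at the representative frame
    feature_atoms: list[int]
    main: bool = False
    too_small_for_fep: bool = False

    @property
    def size(self) -> int:
        return len(self.member_frames)


def mode_feature_atoms(topology: ModelTopology) -> list[int]:
    """Residue-180 side-chain O/N atoms, in topology order."""
    return [i for i, a in enumerate(topology.atoms)
            if a.resnum == 180 and a.role in (ROLE_CARBOXYLATE_O,
                                              ROLE_SIDECHAIN_N)]


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = np.array(d, dtype=float)
    for ax in (0, 1):
        L = box[ax]
        d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def mode_features(trajectory: Trajectory, topology: ModelTopology,
                  ion_index: int, frames: Sequence[int],
                  feature_atoms: Sequence[int] | None = None) -> np.ndarray:
    """Per-frame distances (A) from the ion to each feature atom."""
    atoms = list(feature_atoms) if feature_atoms is not None \
        else mode_feature_atoms(topology)
    frames = np.asarray(frames, dtype=int)
    ion = trajectory.coordinates[frames, ion_index, :][:, None, :]
    others = trajectory.coordinates[frames][:, atoms, :]
    d = _min_image_xy(others - ion, topology.box)
    return np.linalg.norm(d, axis=2)


def cluster_binding_modes(trajectory: Trajectory, topology: ModelTopology,
                          ion_index: int,
                          bound_frames: Sequence[int],
                          feature_atoms: Sequence[int] | None = None,
                          cutoff: float = 1.5,
                          n_report: int = 3,
                          n_main: int = 2,
                          occupancy_floor: float = 0.05,
                          n_analyzed_frames: int | None = None) -> list[BindingMode]:
    """Cluster Site_OC-bound frames into cation binding modes.

    ``bound_frames`` are the frame indices where the ion occupies the
    site; ``n_analyzed_frames`` is the denominator for occupancy (defaults
    to the trajectory length).  Clusters are ranked by descending size
    with ties broken by first occurrence; the top ``n_main`` are flagged
    as the main binding modes.
    """
    bound_frames = sorted(int(f) for f in bound_frames)
    if not bound_frames:
        raise ValueError("no binding detected: empty bound-frame set")
    atoms = list(feature_atoms) if feature_atoms is not None \
        else mode_feature_atoms(topology)
    if not atoms:
        raise ValueError("no feature atoms (residue-180 side-chain O/N)")
    X = mode_features(trajectory, topology, ion_index, bound_frames, atoms)
    n_total = n_analyzed_frames or trajectory.n_frames
    if len(bound_frames) == 1:
        assignments = np.array([1])
    else:
        Zl = linkage(pdist(X), method="average")
        assignments = fcluster(Zl, t=cutoff, criterion="distance")

    modes: list[BindingMode] = []
    order = []
    for cid in np.unique(assignments):
        members = np.flatnonzero(assignments == cid)
        order.append((-len(members), members[0], cid))
    order.sort()
    for rank, (_, _, cid) in enumerate(order[:n_report], start=1):
        members = np.flatnonzero(assignments == cid)
        feats = X[members]
        centroid = feats.mean(axis=0)
        rep_local = members[int(np.argmin(np.linalg.norm(feats - centroid,
                                                         axis=1)))]
        rep_frame = bound_frames[rep_local]
        modes.append(BindingMode(
            rank=rank,
            member_frames=[bound_frames[m] for m in members],
            occupancy=len(members) / n_total,
            centroid=centroid,
            representative_frame=rep_frame,
            restraint_center=np.array(
                trajectory.coordinates[rep_frame, ion_index, :]),
            feature_atoms=atoms,
            main=rank <= n_main,
            too_small_for_fep=(len(members) / n_total) < occupancy_floor,
        ))
    return modes


def modes_table(modes: Sequence[BindingMode]) -> pd.DataFrame:
    rows = []
    for m in modes:
        row = {"rank": m.rank, "occupancy": m.occupancy,
               "n_frames": m.size, "representative_frame":
               m.representative_frame, "main": m.main,
               "too_small_for_fep": m.too_small_for_fep}
        for k, v in enumerate(m.centroid):
            row[f"centroid_d{k}_A"] = v
        rows.append(row)
    cols = (["rank", "occupancy", "n_frames", "representative_frame",
             "main", "too_small_for_fep"]
            + [f"centroid_d{k}_A" for k in
               range(len(modes[0].centroid) if modes else 0)])
    return pd.DataFrame(rows, columns=cols)


def analysis_window(n_frames: int, fraction: float = 0.75) -> list[int]:
    """Frame indices of the trailing analysis window (default final 75%)."""
    start = int(np.floor(n_frames * (1.0 - fraction)))
    return list(range(start, n_frames))
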
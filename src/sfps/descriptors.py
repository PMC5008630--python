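"""Geometric reporters: selectivity-filter center, axial Z and radial R.

Z is the signed axial offset of a tracked atom from the SF geometric
center (+Z toward the extracellular side, the direction ions enter from);
R is the in-plane (xy) distance from the pore axis through that center.
Both honour the minimum-image convention in the periodic x/y directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .system import ModelTopology
from .trajio import AtomSelection, Trajectory, select_atoms

#: default SF-center definition: the four residue-180 backbone anchors
DEFAULT_CENTER_EXPRESSION = "role backbone and resnum 180"


@dataclass
class SFCenterDefinition:
    """Which atoms define the SF geometric center, and how often."""

    expression: str = DEFAULT_CENTER_EXPRESSION
    per_frame: bool = True


@dataclass
class RZSeries:
    """Per-frame (Z, R) track of one atom relative to the SF center."""

    times: np.ndarray
    Z: np.ndarray
    R: np.ndarray
    atom_id: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not (len(self.times) == len(self.Z) == len(self.R)):
            raise ValueError("times, Z and R must have equal length")
        if np.any(self.R < 0):
            raise ValueError("R must be non-negative")

    def __len__(self) -> int:
        return len(self.Z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "Z_A": self.Z,
                             "R_A": self.R})

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = np.array(d, dtype=float)
    for ax in (0, 1):
        L = box[ax]
        d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def sf_center(frame: np.ndarray, topology: ModelTopology,
              definition: SFCenterDefinition | None = None) -> np.ndarray:
    """Geometric center of the defining atoms in one frame.

    Atoms straddling a periodic boundary are unwrapped to the image
    nearest the first defining atom before averaging, so the center is
    minimum-image consistent for any compact defining set.
    """
    definition = definition or SFCenterDefinition()
    sel = select_atoms(topology, definition.expression)
    if not sel.indices:
        raise ValueError(
            f"SF-center selection {definition.expression!r} is empty")
    pts = np.asarray(frame, dtype=float)[sel.indices]
    ref = pts[0]
    unwrapped = ref + _min_image_xy(pts - ref, topology.box)
    center = unwrapped.mean(axis=0)
    # wrap the center back into the primary cell
    center[:2] -= topology.box[:2] * np.round(center[:2] / topology.box[:2])
    return center


def compute_Z(position: np.ndarray, center: np.ndarray) -> float:
    """Signed axial offset, A (+ toward the extracellular side)."""
    return float(np.asarray(position, float)[2] - np.asarray(center, float)[2])


def compute_R(position: np.ndarray, center: np.ndarray,
              box: np.ndarray | None = None) -> float:
    """In-plane radial distance from the pore axis, A (minimum image)."""
    d = np.asarray(position, float) - np.asarray(center, float)
    if box is not None:
        d = _min_image_xy(d, np.asarray(box, float))
    return float(np.hypot(d[0], d[1]))


def rz_series(trajectory: Trajectory, topology: ModelTopology,
              tracked_atom: int,
              definition: SFCenterDefinition | None = None) -> RZSeries:
    """(Z, R) of one atom across all frames (vectorised)."""
    if not 0 <= tracked_atom < trajectory.n_atoms:
        raise IndexError(f"atom id {tracked_atom} out of range")
    definition = definition or SFCenterDefinition()
    sel = select_atoms(topology, definition.expression)
    if not sel.indices:
        raise ValueError(
            f"SF-center selection {definition.expression!r} is empty")
    box = topology.box
    pts = trajectory.coordinates[:, sel.indices, :]          # (F, M, 3)
    ref = pts[:, :1, :]
    unwrapped = ref + _min_image_xy(pts - ref, box)
    centers = unwrapped.mean(axis=1)                         # (F, 3)
    if not definition.per_frame and len(centers):
        centers = np.repeat(centers[:1], len(centers), axis=0)
    pos = trajectory.coordinates[:, tracked_atom, :]
    d = _min_image_xy(pos - centers, box)
    Z = pos[:, 2] - centers[:, 2]
    R = np.hypot(d[:, 0], d[:, 1])
    return RZSeries(trajectory.times, Z, R, tracked_atom)
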
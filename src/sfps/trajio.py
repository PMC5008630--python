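"""Trajectory container, file I/O and atom selections.

Coordinates are stored in angstrom as float64.  Multi-frame PDB
(MODEL/ENDMDL), CHARMM-dialect DCD and plain XYZ are supported through
MDAnalysis; analysis tables are written as TSV.  Partial charges are
written into the PDB B-factor column, and the SOLVENT chain maps to PDB
chain ``W``.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .system import ModelTopology, SOLVENT_CHAIN


class TrajectoryFormatError(ValueError):
    pass


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered frames of coordinates with an orthorhombic box.

    coordinates : (n_frames, n_atoms, 3) array, A
    box         : (3,) array, A (shared by all frames)
    times       : (n_frames,) array, ps
    """

    coordinates: np.ndarray
    box: np.ndarray
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[-1] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (3,) or (self.n_frames and np.any(self.box <= 0)):
            raise ValueError("box must be a positive 3-vector")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# MDAnalysis bridge
# ---------------------------------------------------------------------------

_PDB_CHAIN = {SOLVENT_CHAIN: "W"}
_PDB_CHAIN_BACK = {"W": SOLVENT_CHAIN}


def _universe_from_topology(topology: ModelTopology, n_frames: int = 1) -> mda.Universe:
    n = topology.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           residue_segindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("resnames", [a.resname for a in topology.atoms])
    u.add_TopologyAttr("resids", [a.resnum for a in topology.atoms])
    u.add_TopologyAttr("chainIDs",
                       [_PDB_CHAIN.get(a.chain, a.chain) for a in topology.atoms])
    u.add_TopologyAttr("tempfactors", [a.charge for a in topology.atoms])
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("elements", [a.name for a in topology.atoms])
    return u


def _box_dimensions(box: np.ndarray) -> np.ndarray:
    return np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)


def write_trajectory(trajectory: Trajectory, path: str,
                     fmt: str | None = None,
                     topology: ModelTopology | None = None) -> None:
    """Write a trajectory as multi-frame PDB, DCD or XYZ (by extension)."""
    fmt = (fmt or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt not in ("PDB", "DCD", "XYZ"):
        raise TrajectoryFormatError(f"unsupported format {fmt!r}")
    if trajectory.n_frames == 0:
        open(path, "w").close()
        return
    if topology is not None and topology.n_atoms != trajectory.n_atoms:
        raise TrajectoryFormatError(
            f"topology has {topology.n_atoms} atoms but trajectory has "
            f"{trajectory.n_atoms}")
    if fmt == "PDB" and topology is None:
        raise TrajectoryFormatError("PDB output requires a topology")
    if topology is not None:
        u = _universe_from_topology(topology)
    else:
        u = mda.Universe.empty(trajectory.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", ["X"] * trajectory.n_atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=trajectory.n_atoms, format=fmt,
                        multiframe=True) as w:
            for i in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[i].astype(np.float32)
                u.trajectory.ts.dimensions = _box_dimensions(trajectory.box)
                u.trajectory.ts.time = float(trajectory.times[i])
                w.write(u.atoms)


def _check_pdb_frames(path: str) -> None:
    """Reject multi-frame PDBs whose MODEL blocks disagree in atom count."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
            elif rec in ("ATOM", "HETATM"):
                current += 1
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
    if in_model:
        raise TrajectoryFormatError(
            f"truncated PDB: frame {len(counts)} has no ENDMDL")
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"inconsistent atom count at frame {bad}: "
            f"{counts[bad]} vs {counts[0]}")


def read_trajectory(path: str, fmt: str | None = None,
                    topology: ModelTopology | None = None) -> Trajectory:
    """Read a trajectory from PDB, DCD or XYZ.

    DCD carries no atom metadata and therefore requires a topology; the
    atom count is validated against it.  An empty file yields an empty
    Trajectory.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (fmt or os.path.splitext(path)[1].lstrip(".")).upper()
    if fmt not in ("PDB", "DCD", "XYZ"):
        raise TrajectoryFormatError(f"unsupported format {fmt!r}")
    if os.path.getsize(path) == 0:
        return Trajectory(np.zeros((0, 0, 3)), np.ones(3))
    if fmt == "DCD":
        if topology is None:
            raise TrajectoryFormatError(
                "DCD carries no atom metadata: a topology is required")
        reader = mda.coordinates.DCD.DCDReader(path)
        if reader.n_atoms != topology.n_atoms:
            raise TrajectoryFormatError(
                f"DCD has {reader.n_atoms} atoms, topology has "
                f"{topology.n_atoms}")
        frames, times, box = [], [], None
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=np.float64))
            times.append(float(ts.time))
            box = np.array(ts.dimensions[:3], dtype=float)
        reader.close()
        return Trajectory(np.array(frames), box, np.array(times))
    if fmt == "PDB":
        _check_pdb_frames(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        if topology is not None and len(u.atoms) != topology.n_atoms:
            raise TrajectoryFormatError(
                f"file has {len(u.atoms)} atoms, topology has "
                f"{topology.n_atoms}")
        frames, times = [], []
        box = np.ones(3)
        for ts in u.trajectory:
            frames.append(np.array(ts.positions, dtype=np.float64))
            times.append(float(ts.time))
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
    return Trajectory(np.array(frames), box, np.array(times))


# ---------------------------------------------------------------------------
# topology tables
# ---------------------------------------------------------------------------

_TOP_COLUMNS = ["id", "name", "resname", "resnum", "chain", "charge_e",
                "sigma_A", "epsilon_kcal_mol", "role"]


def write_topology_table(topology: ModelTopology, path: str) -> None:
    rows = [(a.id, a.name, a.resname, a.resnum, a.chain, a.charge,
             a.sigma, a.epsilon, a.role) for a in topology.atoms]
    df = pd.DataFrame(rows, columns=_TOP_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_topology_pdb(topology: ModelTopology, path: str) -> None:
    """Single-frame PDB of the initial coordinates, charges in B-factors."""
    traj = Trajectory(topology.initial_coordinates()[None, :, :], topology.box)
    write_trajectory(traj, path, "PDB", topology)


# ---------------------------------------------------------------------------
# atom selections
# ---------------------------------------------------------------------------


@dataclass
class AtomSelection:
    expression: str
    indices: list[int]

    def __len__(self) -> int:
        return len(self.indices)


class _Tokenizer:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        i = 0
        while i < len(text):
            if text[i].isspace():
                i += 1
                continue
            if text[i] in "()":
                self.tokens.append((text[i], i))
                i += 1
                continue
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            self.tokens.append((text[i:j], i))
            i = j
        self.k = 0

    def peek(self):
        return self.tokens[self.k] if self.k < len(self.tokens) else (None, len(self.text))

    def next(self):
        tok = self.peek()
        self.k += 1
        return tok


def select_atoms(topology: ModelTopology, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    Grammar: ``expr := term (or term)*``, ``term := factor (and factor)*``,
    ``factor := not factor | ( expr ) | all | none | keyword value`` with
    keywords ``chain``, ``resnum``, ``resname``, ``name``, ``role``.
    ``resnum`` accepts a single integer or an inclusive ``lo:hi`` range.
    """
    tz = _Tokenizer(expression)

    n = topology.n_atoms

    def prim() -> np.ndarray:
        tok, pos = tz.next()
        if tok is None:
            raise SelectionError(
                f"unexpected end of expression at position {pos}")
        if tok == "(":
            m = expr()
            close, cpos = tz.next()
            if close != ")":
                raise SelectionError(f"expected ')' at position {cpos}")
            return m
        if tok == "not":
            return ~prim()
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok in ("chain", "resnum", "resname", "name", "role"):
            val, vpos = tz.next()
            if val is None or val in ("and", "or", ")", "("):
                raise SelectionError(
                    f"keyword {tok!r} needs a value at position {vpos}")
            if tok == "resnum":
                try:
                    if ":" in val:
                        lo, hi = (int(v) for v in val.split(":", 1))
                    else:
                        lo = hi = int(val)
                except ValueError:
                    raise SelectionError(
                        f"bad residue number {val!r} at position {vpos}") from None
                return np.array([lo <= a.resnum <= hi for a in topology.atoms])
            attr = {"chain": "chain", "resname": "resname",
                    "name": "name", "role": "role"}[tok]
            return np.array([getattr(a, attr) == val for a in topology.atoms])
        raise SelectionError(f"syntax error at position {pos}: {tok!r}")

    def term() -> np.ndarray:
        m = prim()
        while tz.peek()[0] == "and":
            tz.next()
            m = m & prim()
        return m

    def expr() -> np.ndarray:
        m = term()
        while tz.peek()[0] == "or":
            tz.next()
            m = m | term()
        return m

    mask = expr()
    tok, pos = tz.peek()
    if tok is not None:
        raise SelectionError(f"unexpected token {tok!r} at position {pos}")
    indices = sorted(np.flatnonzero(mask).tolist())
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms")
    return AtomSelection(expression, indices)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(results: pd.DataFrame | Sequence[dict] | dict, path: str,
                float_precision: int = 4) -> None:
    """Write an analysis-result table as TSV with deterministic columns.

    Column names are expected to carry units (e.g. ``ddG_kcal_mol``).
    A mapping or record sequence is converted to a DataFrame first; an
    empty record list produces a header-only file when columns are known.
    """
    if results is None:
        raise ValueError("results must not be None")
    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, dict):
        df = pd.DataFrame([results])
    else:
        df = pd.DataFrame(list(results))
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_precision}f")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
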
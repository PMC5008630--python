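"""Open/closed conformational-state model in (R, Z) space.

A soft-margin linear SVM gives the best linear separation between the
closed and open populations of the side-chain reporter atom.  Per-class
95% confidence regions are bounded by lines parallel to the separator:
each class's boundary line sits at the level-quantile of the class's
signed distances, i.e. as far toward the class's own side as possible
while keeping at least ``ceil(level * n_class)`` training points of that
class on the class side.  For separable data both offsets are positive
and the strip between the lines is *unassigned*; for overlapping classes
the lines may cross the separator, the regions then overlap, and frames
claimed by both regions are resolved by the separator sign.

The decision value of a point p is d(p) = w.p + b with ||w|| = 1, so
decision values are signed distances (A) from the separator; the open
state lies on the d > 0 side.  Points exactly on a boundary belong to the
open side (documented tie-break).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import svm

OPEN, CLOSED, UNASSIGNED = "open", "closed", "unassigned"


@dataclass
class StateBoundary:
    """Linear discriminant in (R, Z) plus per-class confidence offsets."""

    w: np.ndarray                 # unit normal, (w_R, w_Z)
    b: float
    offset_closed: float | None = None   # closed region: d <= -offset_closed
    offset_open: float | None = None     # open region:   d >= +offset_open
    level: float = 0.95

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        norm = float(np.linalg.norm(self.w))
        if norm == 0:
            raise ValueError("degenerate separator (zero weight vector)")
        self.w = self.w / norm
        self.b = float(self.b) / norm

    def decision(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.w + self.b

    def to_record(self) -> str:
        """Six-number text record: w_R w_Z b offset_closed offset_open level."""
        oc = math.nan if self.offset_closed is None else self.offset_closed
        oo = math.nan if self.offset_open is None else self.offset_open
        vals = [self.w[0], self.w[1], self.b, oc, oo, self.level]
        return " ".join(f"{v:.8g}" for v in vals)

    @classmethod
    def from_record(cls, text: str) -> "StateBoundary":
        v = [float(t) for t in text.split()]
        if len(v) != 6:
            raise ValueError("boundary record must contain six numbers")
        return cls(np.array(v[:2]), v[2],
                   None if math.isnan(v[3]) else v[3],
                   None if math.isnan(v[4]) else v[4], v[5])


def _split(points: np.ndarray, labels: Sequence[str]):
    points = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2) in (R, Z)")
    is_open = lab == OPEN
    is_closed = lab == CLOSED
    if not (is_open | is_closed).all():
        bad = sorted(set(lab) - {OPEN, CLOSED})
        raise ValueError(f"labels must be 'open' or 'closed', got {bad}")
    return points, is_open, is_closed


def fit_separator(points: np.ndarray, labels: Sequence[str],
                  C: float = 10.0) -> StateBoundary:
    """Maximum-margin (soft, penalty C) linear separation of the states.

    Features are used raw, in angstrom, so the boundary and its offsets
    stay in physical units.
    """
    points, is_open, is_closed = _split(points, labels)
    if not is_open.any() or not is_closed.any():
        raise ValueError("both classes must be non-empty")
    clf = svm.SVC(kernel="linear", C=C)
    clf.fit(points, np.where(is_open, OPEN, CLOSED))
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    boundary = StateBoundary(w, b)
    # orient so the open class sits on the positive side
    d = boundary.decision(points)
    if d[is_open].mean() < d[is_closed].mean():
        boundary = StateBoundary(-boundary.w, -boundary.b)
    return boundary


def confidence_regions(boundary: StateBoundary, points: np.ndarray,
                       labels: Sequence[str],
                       level: float = 0.95) -> StateBoundary:
    """Fill per-class confidence offsets on a fitted boundary."""
    if not 0 < level < 1 and level != 1.0:
        raise ValueError("confidence level must lie in (0, 1]")
    points, is_open, is_closed = _split(points, labels)
    d = boundary.decision(points)

    def offset(values: np.ndarray, side: int) -> float:
        # side=+1: open class, keep >= k points at d >= threshold
        n = len(values)
        k = math.ceil(level * n)
        ordered = np.sort(side * values)[::-1]   # own-side distance, desc
        return float(ordered[k - 1])

    return StateBoundary(boundary.w, boundary.b,
                         offset_closed=offset(d[is_closed], -1),
                         offset_open=offset(d[is_open], +1),
                         level=level)


def classify_frames(rz: np.ndarray | "pd.DataFrame",
                    boundary: StateBoundary):
    """Label frames open/closed/unassigned and report region occupancies.

    ``rz`` is an (n, 2) array of (R, Z) points (an RZSeries can be passed
    via ``np.column_stack([series.R, series.Z])``).
    """
    if boundary.offset_open is None or boundary.offset_closed is None:
        raise ValueError("boundary has no confidence offsets; "
                         "run confidence_regions first")
    pts = np.asarray(rz, dtype=float)
    d = boundary.decision(pts)
    in_open = d >= boundary.offset_open                # ties -> open
    in_closed = d <= -boundary.offset_closed
    labels = np.full(len(d), UNASSIGNED, dtype=object)
    labels[in_closed] = CLOSED
    labels[in_open] = OPEN
    both = in_open & in_closed                         # overlapping regions
    labels[both] = np.where(d[both] >= 0, OPEN, CLOSED)
    n = len(labels)
    fractions = {state: float(np.sum(labels == state)) / n if n else 0.0
                 for state in (CLOSED, OPEN, UNASSIGNED)}
    return labels.tolist(), fractions


def classified_series_frame(series, labels) -> pd.DataFrame:
    """TSV-ready table (time, Z, R, label) for a classified RZ series."""
    return pd.DataFrame({"time_ps": series.times, "Z_A": series.Z,
                         "R_A": series.R, "state": labels})
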
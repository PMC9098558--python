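"""Overlap degree, earth mover's distance and centroid distance between maps.

The *overlap degree* (OD) of two or three co-registered motor maps is the
size of their intersection as a percentage of the size of their union, where
"size" is either area (mm²) or volume (mm²·µV)::

    OD_2 = 100 * X12 / (X1 + X2 - X12)
    OD_3 = 100 * X123 / (X1 + X2 + X3 - (X12 + X13 + X23) + X123)

The intersection of two amplitude maps is their cellwise minimum — the
unique choice for which X12 <= min(X1, X2) and the inclusion–exclusion
denominators above are exact (union = cellwise maximum).  ODs are binned on
a five-step category scale: negligible (0–20 %), low (20–40 %], medium
(40–60 %], high (60–80 %], very high (80–100 %].

Topography is compared with the earth mover's distance (EMD) — the minimal
work to transform one suprathreshold amplitude distribution into the other,
both normalised to unit mass, with Euclidean mm ground distance, solved as
an exact transportation linear program — and with the Euclidean distance
between map centroids.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .mapping import MotorMap, map_area, map_centroid, map_volume

__all__ = [
    "OdCategory",
    "OverlapInputs",
    "OverlapResult",
    "intersection_map",
    "union_map",
    "overlap_degree_two",
    "overlap_degree_three",
    "categorize_od",
    "centroid_distance",
    "earth_movers_distance",
    "overlap_report",
]


class OdCategory(str, enum.Enum):
    negligible = "negligible"
    low = "low"
    medium = "medium"
    high = "high"
    very_high = "very_high"


@dataclass(frozen=True)
class OverlapInputs:
    """Singleton, pairwise and triple intersection sizes for the OD formulas.

    ``kind`` states whether the X's are areas (mm²) or volumes (mm²·µV).
    """

    x1: float
    x2: float
    x12: float
    x3: float | None = None
    x13: float | None = None
    x23: float | None = None
    x123: float | None = None
    kind: str = "area"

    def __post_init__(self) -> None:
        vals = [self.x1, self.x2, self.x12, self.x3, self.x13, self.x23, self.x123]
        if any(v is not None and v < 0 for v in vals):
            raise ValueError("intersection sizes must be >= 0")
        tol = 1e-9 * max(self.x1, self.x2, 1.0)
        if self.x12 > min(self.x1, self.x2) + tol:
            raise ValueError("X12 cannot exceed min(X1, X2)")
        if self.x123 is not None:
            pairs = [p for p in (self.x12, self.x13, self.x23) if p is not None]
            if pairs and self.x123 > min(pairs) + tol:
                raise ValueError("X123 cannot exceed any pairwise intersection")


@dataclass(frozen=True)
class OverlapResult:
    """OD with its category plus topography metrics for one muscle set."""

    muscles: tuple[str, ...]
    intensity: str
    kind: str  # "area" | "volume"
    od_pct: float
    category: OdCategory | None
    emd_mm: float
    centroid_distance_mm: float


# ---------------------------------------------------------------------------
# map algebra
# ---------------------------------------------------------------------------


def _require_same_geometry(a: MotorMap, b: MotorMap) -> None:
    if not a.same_geometry(b):
        raise ValueError(
            "maps have different grid geometry; resample explicitly first"
        )


def intersection_map(a: MotorMap, b: MotorMap) -> MotorMap:
    """Cellwise-minimum map: the overlap region and height of two maps."""
    _require_same_geometry(a, b)
    return MotorMap(
        origin=a.origin,
        resolution=a.resolution,
        grid=np.minimum(a.grid, b.grid),
        muscle=f"{a.muscle}&{b.muscle}",
        intensity=a.intensity,
    )


def union_map(a: MotorMap, b: MotorMap) -> MotorMap:
    """Cellwise-maximum map (the union in the min/max map algebra)."""
    _require_same_geometry(a, b)
    return MotorMap(
        origin=a.origin,
        resolution=a.resolution,
        grid=np.maximum(a.grid, b.grid),
        muscle=f"{a.muscle}|{b.muscle}",
        intensity=a.intensity,
    )


# ---------------------------------------------------------------------------
# overlap degree
# ---------------------------------------------------------------------------


def overlap_degree_two(inp: OverlapInputs) -> float:
    """Two-map overlap degree, % of the union occupied by the intersection.

    Returns NaN when both maps are empty (zero denominator).
    """
    denom = inp.x1 + inp.x2 - inp.x12
    if denom <= 0:
        return float("nan")
    return 100.0 * inp.x12 / denom


def overlap_degree_three(inp: OverlapInputs) -> float:
    """Three-map overlap degree (triple intersection over triple union)."""
    if inp.x3 is None or inp.x13 is None or inp.x23 is None or inp.x123 is None:
        raise ValueError("triple OD needs X3, X13, X23 and X123")
    denom = inp.x1 + inp.x2 + inp.x3 - (inp.x12 + inp.x13 + inp.x23) + inp.x123
    if denom <= 0:
        return float("nan")
    return 100.0 * inp.x123 / denom


def categorize_od(od_pct: float) -> OdCategory:
    """Five-step OD category; first band closed, the rest half-open above.

    [0, 20] negligible, (20, 40] low, (40, 60] medium, (60, 80] high,
    (80, 100] very high.
    """
    if not 0.0 <= od_pct <= 100.0 or math.isnan(od_pct):
        raise ValueError(f"OD must be in [0, 100], got {od_pct}")
    if od_pct <= 20.0:
        return OdCategory.negligible
    if od_pct <= 40.0:
        return OdCategory.low
    if od_pct <= 60.0:
        return OdCategory.medium
    if od_pct <= 80.0:
        return OdCategory.high
    return OdCategory.very_high


# ---------------------------------------------------------------------------
# topography metrics
# ---------------------------------------------------------------------------


def centroid_distance(a: MotorMap, b: MotorMap, threshold_uv: float = 50.0) -> float:
    """Euclidean mm distance between the two maps' centroids (NaN if undefined)."""
    ca = map_centroid(a, threshold_uv)
    cb = map_centroid(b, threshold_uv)
    if ca is None or cb is None:
        return float("nan")
    return float(math.hypot(ca[0] - cb[0], ca[1] - cb[1]))


def _distribution(m: MotorMap, threshold_uv: float, coarsen: int):
    """Suprathreshold mass distribution: (positions (n,2) mm, weights (n,))."""
    grid = np.where(m.grid > threshold_uv, m.grid, 0.0)
    res = m.resolution
    if coarsen > 1:
        ny, nx = grid.shape
        py, px = (-ny) % coarsen, (-nx) % coarsen
        grid = np.pad(grid, ((0, py), (0, px)))
        grid = grid.reshape(
            grid.shape[0] // coarsen, coarsen, grid.shape[1] // coarsen, coarsen
        ).sum(axis=(1, 3))
        res = m.resolution * coarsen
    yy, xx = np.nonzero(grid)
    if yy.size == 0:
        return None, None
    # block centre = mean of the centres of the constituent fine cells
    x = m.origin[0] + (xx + 0.5) * res - m.resolution / 2.0
    y = m.origin[1] + (yy + 0.5) * res - m.resolution / 2.0
    w = grid[yy, xx]
    return np.column_stack([x, y]), w / w.sum()


def earth_movers_distance(
    a: MotorMap,
    b: MotorMap,
    threshold_uv: float = 50.0,
    coarsen: int = 1,
) -> float:
    """Exact EMD (mm) between two maps' suprathreshold amplitude distributions.

    Each distribution is the suprathreshold grid normalised to unit mass;
    ground distance is the Euclidean distance between cell centres in mm.
    The transportation problem is solved exactly with the HiGHS LP solver.
    ``coarsen`` aggregates the grid into blocks of that many cells per side
    first, trading spatial resolution for solve time on large maps.

    Returns NaN when either map has no suprathreshold mass.
    """
    _require_same_geometry(a, b)
    pa, wa = _distribution(a, threshold_uv, coarsen)
    pb, wb = _distribution(b, threshold_uv, coarsen)
    if pa is None or pb is None:
        return float("nan")
    return emd_point_masses(pa, wa, pb, wb)


def emd_point_masses(pos_a, w_a, pos_b, w_b) -> float:
    """EMD between two weighted point sets (weights must each sum to 1)."""
    pos_a = np.atleast_2d(pos_a)
    pos_b = np.atleast_2d(pos_b)
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    n, m = len(w_a), len(w_b)
    cost = cdist(pos_a, pos_b)  # (n, m)
    # transportation LP: minimise sum c_ij f_ij, rows ship w_a, cols receive w_b
    row_idx = np.repeat(np.arange(n), m)
    col_idx = n + np.tile(np.arange(m), n)
    var_idx = np.arange(n * m)
    A_eq = sparse.csr_matrix(
        (
            np.ones(2 * n * m),
            (np.concatenate([row_idx, col_idx]), np.concatenate([var_idx, var_idx])),
        ),
        shape=(n + m, n * m),
    )
    b_eq = np.concatenate([w_a, w_b])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS solves feasible transport
        raise RuntimeError(f"EMD transportation LP failed: {res.message}")
    return float(res.fun)


# ---------------------------------------------------------------------------
# cohort-style report
# ---------------------------------------------------------------------------


def overlap_report(
    maps: dict[str, MotorMap],
    threshold_uv: float = 50.0,
    intensity: str = "",
    subject: str = "",
    emd_coarsen: int = 1,
    compute_emd: bool = True,
) -> pd.DataFrame:
    """All overlap records for 2 or 3 co-registered muscle maps.

    For each *target* muscle, records are produced against each single
    *adjacent* muscle and (with 3 maps) against both together ("ALL"), for
    the area and the volume kind — with 3 muscles that is 9 records per
    kind, 6 pairwise and 3 triple.  EMD and centroid distance accompany each
    pairwise record; triple records carry the centroid distance between the
    target map and the triple-overlap map, and no EMD.
    """
    names = list(maps)
    if len(names) not in (2, 3):
        raise ValueError("overlap_report needs 2 or 3 maps")
    for a, b in itertools.combinations(names, 2):
        _require_same_geometry(maps[a], maps[b])

    size = {"area": map_area, "volume": map_volume}
    singles = {k: {n: fn(maps[n], threshold_uv) for n in names} for k, fn in size.items()}
    inter2 = {}
    for a, b in itertools.combinations(names, 2):
        m12 = intersection_map(maps[a], maps[b])
        inter2[frozenset((a, b))] = {
            "map": m12,
            "area": map_area(m12, threshold_uv),
            "volume": map_volume(m12, threshold_uv),
        }
    inter3 = None
    if len(names) == 3:
        m123 = intersection_map(inter2[frozenset(names[:2])]["map"], maps[names[2]])
        inter3 = {
            "map": m123,
            "area": map_area(m123, threshold_uv),
            "volume": map_volume(m123, threshold_uv),
        }

    pair_emd = {}
    pair_cdist = {}
    for a, b in itertools.combinations(names, 2):
        pair_emd[frozenset((a, b))] = (
            earth_movers_distance(maps[a], maps[b], threshold_uv, emd_coarsen)
            if compute_emd
            else float("nan")
        )
        pair_cdist[frozenset((a, b))] = centroid_distance(
            maps[a], maps[b], threshold_uv
        )

    rows = []
    for kind in ("area", "volume"):
        for target in names:
            adjacents = [n for n in names if n != target]
            for adj in adjacents:
                key = frozenset((target, adj))
                od = overlap_degree_two(
                    OverlapInputs(
                        x1=singles[kind][target],
                        x2=singles[kind][adj],
                        x12=inter2[key][kind],
                        kind=kind,
                    )
                )
                rows.append(
                    _row(subject, target, adj, intensity, kind, od,
                         pair_emd[key], pair_cdist[key])
                )
            if len(names) == 3:
                a, b = adjacents
                od3 = overlap_degree_three(
                    OverlapInputs(
                        x1=singles[kind][target],
                        x2=singles[kind][a],
                        x3=singles[kind][b],
                        x12=inter2[frozenset((target, a))][kind],
                        x13=inter2[frozenset((target, b))][kind],
                        x23=inter2[frozenset((a, b))][kind],
                        x123=inter3[kind],
                        kind=kind,
                    )
                )
                cdist_all = centroid_distance(maps[target], inter3["map"], threshold_uv)
                rows.append(
                    _row(subject, target, "ALL", intensity, kind, od3,
                         float("nan"), cdist_all)
                )
    return pd.DataFrame(rows)


def _row(subject, target, adjacent, intensity, kind, od, emd, cd):
    return {
        "subject": subject,
        "target": target,
        "adjacent_set": adjacent,
        "intensity": intensity,
        "kind": kind,
        "od_pct": od,
        "category": categorize_od(od).value if not math.isnan(od) else "",
        "emd_mm": emd,
        "centroid_dist_mm": cd,
    }
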
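"""Motor-map construction and size/location metrics.

A motor map is a regular 2-D grid of interpolated MEP amplitude (µV) built
from the per-site median amplitudes of one muscle at one stimulation
intensity.  Construction steps:

1. closely spaced stimulation sites are merged (single-linkage clustering,
   default 3 mm radius) into their mean coordinate and median amplitude;
2. 3-D coil coordinates are orthogonally projected onto the least-squares
   plane of the site cloud (in-plane distances in mm are preserved);
3. amplitudes are interpolated on the Delaunay triangulation of the merged
   sites, piecewise-linearly in *log* amplitude (geometric-mean
   interpolation) — exact at the sites, no overshoot, and far more faithful
   than linear-amplitude chords to the roughly exponential fall-off of MEP
   amplitude away from a representation's core at realistic ~14 mm site
   spacings — then tapered linearly to zero within one median site spacing
   outside the convex hull.  Amplitudes at or below a 10 µV response floor
   are treated as no response (zero) throughout.

Map metrics follow the field's conventions: *area* is the extent of the
suprathreshold representation (mm²), *volume* is that extent weighted by
amplitude (mm²·µV), and the *centroid* is the amplitude-weighted centre.
The default 50 µV threshold is the usual absolute response criterion; a
relative threshold (fraction of the map maximum) is available through
``contour_fractions``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import ConvexHull, Delaunay
from scipy.spatial.distance import cdist

__all__ = [
    "MotorMap",
    "MapMetrics",
    "PlaneDefinition",
    "merge_sites",
    "project_to_plane",
    "interpolate_map",
    "interpolate_values",
    "map_area",
    "map_volume",
    "map_centroid",
    "map_metrics",
    "contour_fractions",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass
class MotorMap:
    """Regular 2-D grid of MEP amplitude with mm geometry.

    ``grid[i, j]`` is the amplitude at cell centre
    ``(origin[0] + j * resolution, origin[1] + i * resolution)``.
    """

    origin: tuple[float, float]  # cell-centre of grid[0, 0], mm
    resolution: float  # mm per cell
    grid: np.ndarray  # (ny, nx) µV, >= 0
    muscle: str = ""
    intensity: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ValueError("grid values must be finite and >= 0")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of cell-centre coordinates in mm."""
        ny, nx = self.grid.shape
        x = self.origin[0] + np.arange(nx) * self.resolution
        y = self.origin[1] + np.arange(ny) * self.resolution
        return np.meshgrid(x, y)

    def same_geometry(self, other: "MotorMap") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.isclose(self.resolution, other.resolution)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class MapMetrics:
    """Area (mm²), volume (mm²·µV) and centroid (mm) of one map."""

    area_mm2: float
    volume_mm2_uv: float
    centroid_mm: tuple[float, float] | None
    threshold_uv: float


@dataclass(frozen=True)
class PlaneDefinition:
    """Least-squares plane: origin point, two in-plane unit axes, normal."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (2, 3) orthonormal in-plane directions
    normal: np.ndarray  # (3,)


# ---------------------------------------------------------------------------
# site preparation
# ---------------------------------------------------------------------------


def merge_sites(coords, amplitudes, merge_radius_mm: float = 3.0):
    """Merge closely spaced stimulation sites.

    Single-linkage clusters at ``merge_radius_mm`` are each replaced by their
    mean coordinate and the median of their amplitudes.  Clusters are
    returned in order of first appearance, so the result is deterministic.

    Returns ``(merged_coords, merged_amplitudes)``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    amplitudes = np.asarray(amplitudes, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("no sites to merge")
    if coords.shape[0] != amplitudes.shape[0]:
        raise ValueError("coords and amplitudes must have equal length")
    if coords.shape[0] == 1:
        return coords.copy(), amplitudes.copy()
    labels = fcluster(
        linkage(coords, method="single"), t=merge_radius_mm, criterion="distance"
    )
    merged_c, merged_a = [], []
    seen: dict[int, None] = {}
    for lab in labels:  # preserve first-appearance order
        if lab not in seen:
            seen[lab] = None
            mask = labels == lab
            merged_c.append(coords[mask].mean(axis=0))
            merged_a.append(float(np.median(amplitudes[mask])))
    return np.asarray(merged_c), np.asarray(merged_a)


def project_to_plane(coords_3d) -> tuple[np.ndarray, PlaneDefinition]:
    """Orthogonal projection onto the least-squares plane of the site cloud.

    The 2-D axes are the principal directions of the cloud within the plane,
    so in-plane mm distances are preserved.  Raises ``ValueError`` for
    degenerate (collinear or < 3 distinct points) clouds.
    """
    coords_3d = np.atleast_2d(np.asarray(coords_3d, dtype=float))
    if coords_3d.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = coords_3d.mean(axis=0)
    centered = coords_3d - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= max(s[0] * 1e-9, 1e-12):
        raise ValueError("site cloud is collinear or degenerate; no unique plane")
    axes = vt[:2]
    # deterministic axis orientation: largest-magnitude component positive
    for k in range(2):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    normal = np.cross(axes[0], axes[1])
    coords_2d = centered @ axes.T
    return coords_2d, PlaneDefinition(origin=centroid, axes=axes, normal=normal)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


#: amplitudes at or below this are treated as "no response" when building
#: maps: they enter the interpolation at the floor and map to 0 on output.
RESPONSE_FLOOR_UV = 10.0


def _taper_length(sites: np.ndarray) -> float:
    d = cdist(sites, sites)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def _build_interpolant(sites: np.ndarray, amps: np.ndarray, floor_uv: float):
    """Geometric-mean (log-linear) interpolation inside the hull, taper outside.

    Inside the site hull, log amplitude is interpolated piecewise-linearly
    on the Delaunay triangulation (exact at sites, no overshoot; chords in
    log space track the exponential decay of MEP amplitude with distance,
    where amplitude-space chords badly overestimate the tails).  Outside
    the hull, the boundary amplitude is tapered linearly to 0 within one
    median site spacing.  Output values at or below ``floor_uv`` are 0.
    """
    log_amps = np.log(np.maximum(amps, floor_uv))
    tri = Delaunay(sites)
    inner = LinearNDInterpolator(tri, log_amps)
    hull = ConvexHull(sites)
    hv = sites[hull.vertices]  # hull vertices in counter-clockwise order
    hva = log_amps[hull.vertices]
    seg_a = hv
    seg_b = np.roll(hv, -1, axis=0)
    amp_a = hva
    amp_b = np.roll(hva, -1)
    taper = _taper_length(sites)

    def evaluate(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        logv = inner(points)
        outside = np.isnan(logv)
        vals = np.exp(np.where(outside, 0.0, logv))
        if np.any(outside):
            p = points[outside]  # (m, 2)
            ab = seg_b - seg_a  # (k, 2)
            ap = p[:, None, :] - seg_a[None, :, :]  # (m, k, 2)
            denom = np.einsum("kj,kj->k", ab, ab)
            t = np.clip(np.einsum("mkj,kj->mk", ap, ab) / denom, 0.0, 1.0)
            foot = seg_a[None, :, :] + t[..., None] * ab[None, :, :]
            dist = np.linalg.norm(p[:, None, :] - foot, axis=-1)  # (m, k)
            kmin = np.argmin(dist, axis=1)
            rows = np.arange(p.shape[0])
            d = dist[rows, kmin]
            tt = t[rows, kmin]
            boundary_val = np.exp(amp_a[kmin] * (1.0 - tt) + amp_b[kmin] * tt)
            vals[outside] = boundary_val * np.clip(1.0 - d / taper, 0.0, None)
        return np.where(vals > floor_uv, vals, 0.0)

    return evaluate


def interpolate_values(
    sites, amplitudes, points, floor_uv: float = RESPONSE_FLOOR_UV
) -> np.ndarray:
    """Evaluate the map interpolant at arbitrary map-plane points (mm)."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    amplitudes = np.asarray(amplitudes, dtype=float)
    if sites.shape[0] < 3:
        raise ValueError("interpolation needs at least 3 merged sites")
    return _build_interpolant(sites, amplitudes, floor_uv)(points)


def interpolate_map(
    sites,
    amplitudes,
    resolution_mm: float = 1.0,
    margin_mm: float = 10.0,
    muscle: str = "",
    intensity: str = "",
    extent: tuple[float, float, float, float] | None = None,
    floor_uv: float = RESPONSE_FLOOR_UV,
) -> MotorMap:
    """Interpolate merged-site amplitudes onto a regular grid.

    The grid covers the sites plus ``margin_mm`` on every side (or the
    explicit ``extent`` = (xmin, xmax, ymin, ymax), used to co-register maps
    of different muscles on identical geometry).
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    amplitudes = np.asarray(amplitudes, dtype=float)
    if sites.shape[0] < 3:
        raise ValueError("interpolation needs at least 3 merged sites")
    if resolution_mm <= 0:
        raise ValueError("resolution must be > 0")
    if extent is None:
        xmin, ymin = sites.min(axis=0) - margin_mm
        xmax, ymax = sites.max(axis=0) + margin_mm
    else:
        xmin, xmax, ymin, ymax = extent
    x = np.arange(xmin, xmax + resolution_mm / 2, resolution_mm)
    y = np.arange(ymin, ymax + resolution_mm / 2, resolution_mm)
    xx, yy = np.meshgrid(x, y)
    vals = interpolate_values(
        sites, amplitudes, np.column_stack([xx.ravel(), yy.ravel()]), floor_uv
    )
    grid = vals.reshape(xx.shape)
    return MotorMap(
        origin=(float(x[0]), float(y[0])),
        resolution=float(resolution_mm),
        grid=grid,
        muscle=muscle,
        intensity=intensity,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def map_area(m: MotorMap, threshold_uv: float = 50.0) -> float:
    """Suprathreshold area: (cells with amplitude > threshold) x resolution²."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be > 0")
    return float(np.count_nonzero(m.grid > threshold_uv)) * m.resolution**2


def map_volume(m: MotorMap, threshold_uv: float = 50.0) -> float:
    """Suprathreshold volume: sum of amplitude over cells x resolution² (mm²·µV)."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be > 0")
    mask = m.grid > threshold_uv
    return float(m.grid[mask].sum()) * m.resolution**2


def map_centroid(
    m: MotorMap, threshold_uv: float = 50.0, weighted: bool = True
) -> tuple[float, float] | None:
    """Amplitude-weighted mean coordinate of the suprathreshold cells.

    Returns ``None`` when no cell exceeds the threshold (undefined centroid).
    With ``weighted=False`` the plain mean of the suprathreshold cell
    coordinates is returned instead.
    """
    mask = m.grid > threshold_uv
    if not np.any(mask):
        return None
    xx, yy = m.cell_centers()
    w = m.grid[mask] if weighted else np.ones(np.count_nonzero(mask))
    return (
        float(np.average(xx[mask], weights=w)),
        float(np.average(yy[mask], weights=w)),
    )


def map_metrics(m: MotorMap, threshold_uv: float = 50.0) -> MapMetrics:
    return MapMetrics(
        area_mm2=map_area(m, threshold_uv),
        volume_mm2_uv=map_volume(m, threshold_uv),
        centroid_mm=map_centroid(m, threshold_uv),
        threshold_uv=threshold_uv,
    )


def contour_fractions(m: MotorMap, fractions=(0.05, 0.30, 0.70)) -> list[float]:
    """Iso-levels at the given fractions of the map maximum (for plotting)."""
    peak = float(m.grid.max())
    if peak <= 0:
        raise ValueError("all-zero map has no contour levels")
    return [float(f) * peak for f in fractions]


# ---------------------------------------------------------------------------
# gridded text I/O (ESRI ASCII grid + JSON sidecar)
# ---------------------------------------------------------------------------


def write_ascii_grid(m: MotorMap, path) -> Path:
    """Write a map as an ESRI-style ASCII grid plus a ``.json`` sidecar."""
    path = Path(path)
    ny, nx = m.grid.shape
    half = m.resolution / 2.0
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {m.origin[0] - half:.6f}\n"
        f"yllcorner {m.origin[1] - half:.6f}\n"
        f"cellsize {m.resolution:.6f}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in m.grid[::-1]:  # ASCII grids run north to south
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"muscle": m.muscle, "intensity": m.intensity}, fh)
    return path


def read_ascii_grid(path) -> MotorMap:
    path = Path(path)
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)[::-1]
    res = hdr["cellsize"]
    origin = (hdr["xllcorner"] + res / 2.0, hdr["yllcorner"] + res / 2.0)
    meta = {"muscle": "", "intensity": ""}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return MotorMap(
        origin=origin,
        resolution=res,
        grid=grid,
        muscle=meta["muscle"],
        intensity=str(meta["intensity"]),
    )
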
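"""Endothelial wall-shear indices on a triangulated surface.

Given the wall shear stress (WSS) vector per surface cell over one cardiac
cycle of period T, four standard endothelial indices are computed:

* TAWSS  = (1/T) * int_0^T |WSS| dt                 (Pa)
* OSI    = 1/2 * (1 - |int_0^T WSS dt| / int_0^T |WSS| dt)   in [0, 0.5]
* RRT    = 1 / ((1 - 2*OSI) * TAWSS)                (1/Pa)
* ECAP   = OSI / TAWSS                              (1/Pa)

Low TAWSS (< 0.4 Pa is a common proatherogenic threshold, 0.2-0.3 Pa in
diseased vessels) and high OSI mark regions prone to endothelial
dysfunction; RRT is a proxy for near-wall residence time, and ECAP flags
thrombosis-susceptible low-shear oscillatory zones.  RRT is singular at
OSI = 0.5 and ECAP at TAWSS = 0; singular cells carry a +inf sentinel and
are counted rather than silently dropped.

Time integrals use the trapezoidal rule with periodic closure (the segment
from the last sample back to the value at t = 0 across the period is
included).  Indices are cell-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurfaceMesh",
    "WSSFieldSeries",
    "WallIndexMap",
    "ThresholdResult",
    "tangential_project",
    "compute_tawss",
    "compute_osi",
    "compute_rrt",
    "compute_ecap",
    "compute_indices",
    "threshold_area",
    "TAWSS_HIGH_THRESHOLD_PA",
    "TAWSS_LOW_THRESHOLD_PA",
]

logger = logging.getLogger(__name__)

#: Demonstration threshold for "high TAWSS" area mapping, Pa.
TAWSS_HIGH_THRESHOLD_PA = 5.0
#: Proatherogenic low-TAWSS threshold for a healthy vessel, Pa.
TAWSS_LOW_THRESHOLD_PA = 0.4


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface with per-cell areas and unit normals.

    ``vertices`` is (n_vertices, 3) in metres, ``triangles`` (n_cells, 3)
    0-based vertex indices.  Areas and normals come from the triangle cross
    product; zero-area cells are rejected.  ``nominal_element_size`` is
    resolution metadata in millimetres.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    nominal_element_size: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3 or t.size == 0:
            raise ValueError("triangles must be a non-empty (m, 3) array")
        if t.min() < 0 or t.max() >= v.shape[0]:
            raise ValueError("triangle indices out of range")
        cross = self._cross()
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        if np.any(areas <= 0.0):
            raise ValueError("mesh contains zero-area cells")
        object.__setattr__(self, "_areas", areas)
        object.__setattr__(self, "_normals", cross / (2.0 * areas)[:, None])

    def _cross(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    @property
    def n_cells(self) -> int:
        return self.triangles.shape[0]

    @property
    def cell_areas(self) -> np.ndarray:
        return self._areas

    @property
    def cell_normals(self) -> np.ndarray:
        return self._normals

    @property
    def cell_centers(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self._areas.sum())


@dataclass(frozen=True)
class WSSFieldSeries:
    """Per-cell WSS 3-vectors sampled over one cardiac cycle.

    ``wss`` has shape (n_times, n_cells, 3) in Pa; ``times`` start at 0,
    strictly increase and do not exceed ``period_T``.
    """

    mesh: SurfaceMesh
    times: np.ndarray
    wss: np.ndarray
    period_T: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wss, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "wss", w)
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")
        if t.ndim != 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if t[-1] > self.period_T * (1 + 1e-12):
            raise ValueError("times must not exceed period_T")
        if w.shape != (t.size, self.mesh.n_cells, 3):
            raise ValueError(
                f"wss shape {w.shape} does not match "
                f"(n_times={t.size}, n_cells={self.mesh.n_cells}, 3)"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("WSS values must be finite")


@dataclass
class WallIndexMap:
    """Per-cell wall indices plus singular-cell bookkeeping."""

    mesh: SurfaceMesh
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    ecap: np.ndarray
    n_zero_wss_cells: int = 0
    n_rrt_singular: int = 0
    n_ecap_singular: int = 0


@dataclass(frozen=True)
class ThresholdResult:
    area_m2: float
    fraction: float
    cell_mask: np.ndarray


# --------------------------------------------------------------------------
# quadrature
# --------------------------------------------------------------------------

def _periodic_closure(times: np.ndarray, values: np.ndarray, T: float):
    """Append the wrap point (T, value at t=0) when the last sample is < T."""
    if T - times[-1] > 1e-12 * T:
        times = np.concatenate([times, [T]])
        values = np.concatenate([values, values[:1]], axis=0)
    return times, values


def _periodic_trapz(times: np.ndarray, values: np.ndarray, T: float) -> np.ndarray:
    """Trapezoidal integral over [0, T] with periodic closure.

    ``values`` may have extra trailing axes (cells, components); integration
    is along axis 0.
    """
    t, v = _periodic_closure(times, values, T)
    return np.trapezoid(v, t, axis=0)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def tangential_project(series: WSSFieldSeries) -> WSSFieldSeries:
    """Remove any spurious component along the cell normal.

    Exported WSS fields sometimes carry numerical noise normal to the wall;
    true wall shear is tangential by definition.  Magnitudes never increase.
    """
    n = series.mesh.cell_normals  # (cells, 3)
    w = series.wss
    proj = np.einsum("tcx,cx->tc", w, n)
    w_tan = w - proj[:, :, None] * n[None, :, :]
    return WSSFieldSeries(series.mesh, series.times, w_tan, series.period_T)


def compute_tawss(series: WSSFieldSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per cell, Pa."""
    if series.times.size < 3:
        raise ValueError("TAWSS needs at least 3 time samples")
    mag = np.linalg.norm(series.wss, axis=2)
    return _periodic_trapz(series.times, mag, series.period_T) / series.period_T


def compute_osi(series: WSSFieldSeries) -> np.ndarray:
    """Oscillatory shear index per cell, clipped to [0, 0.5].

    OSI = 1/2 (1 - |int WSS dt| / int |WSS| dt).  Cells whose WSS is
    identically zero are degenerate: they get OSI = 0 and are counted in a
    log message.
    """
    if series.times.size < 3:
        raise ValueError("OSI needs at least 3 time samples")
    vec_int = _periodic_trapz(series.times, series.wss, series.period_T)
    mag_int = _periodic_trapz(
        series.times, np.linalg.norm(series.wss, axis=2), series.period_T
    )
    osi = np.zeros(series.mesh.n_cells)
    ok = mag_int > 0.0
    n_zero = int(np.count_nonzero(~ok))
    if n_zero:
        logger.warning("%d cells have identically zero WSS; OSI set to 0", n_zero)
    osi[ok] = 0.5 * (1.0 - np.linalg.norm(vec_int[ok], axis=1) / mag_int[ok])
    return np.clip(osi, 0.0, 0.5)


def compute_rrt(tawss: np.ndarray, osi: np.ndarray) -> np.ndarray:
    """Relative residence time 1/((1-2*OSI)*TAWSS), +inf where singular."""
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    denom = (1.0 - 2.0 * osi) * tawss
    floor = np.finfo(float).eps * max(float(np.max(tawss, initial=0.0)), 0.0)
    rrt = np.full_like(denom, np.inf)
    ok = denom > floor
    rrt[ok] = 1.0 / denom[ok]
    return rrt


def compute_ecap(tawss: np.ndarray, osi: np.ndarray) -> np.ndarray:
    """Endothelial cell activation potential OSI/TAWSS.

    +inf sentinel where TAWSS = 0 and OSI > 0; exactly 0 where both vanish.
    """
    tawss = np.asarray(tawss, dtype=float)
    osi = np.asarray(osi, dtype=float)
    ecap = np.zeros_like(tawss)
    pos = tawss > 0.0
    ecap[pos] = osi[pos] / tawss[pos]
    ecap[(~pos) & (osi > 0.0)] = np.inf
    return ecap


def compute_indices(series: WSSFieldSeries, project_tangential: bool = False) -> WallIndexMap:
    """Full TAWSS/OSI/RRT/ECAP map from a WSS time series."""
    if project_tangential:
        series = tangential_project(series)
    tawss = compute_tawss(series)
    osi = compute_osi(series)
    rrt = compute_rrt(tawss, osi)
    ecap = compute_ecap(tawss, osi)
    mag_int = _periodic_trapz(
        series.times, np.linalg.norm(series.wss, axis=2), series.period_T
    )
    return WallIndexMap(
        mesh=series.mesh, tawss=tawss, osi=osi, rrt=rrt, ecap=ecap,
        n_zero_wss_cells=int(np.count_nonzero(mag_int == 0.0)),
        n_rrt_singular=int(np.count_nonzero(~np.isfinite(rrt))),
        n_ecap_singular=int(np.count_nonzero(~np.isfinite(ecap))),
    )


_FIELDS = ("tawss", "osi", "rrt", "ecap")


def threshold_area(index_map: WallIndexMap, field_name: str, threshold: float,
                   direction: str = "above") -> ThresholdResult:
    """Surface area where an index is strictly above/below a threshold.

    Returns the masked area (m^2), its fraction of the total surface and
    the boolean cell mask.  Singular (+inf) cells count as "above" any
    finite threshold.
    """
    if field_name not in _FIELDS:
        raise ValueError(f"unknown field {field_name!r}; expected one of {_FIELDS}")
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    values = getattr(index_map, field_name)
    if direction == "above":
        mask = values > threshold
    elif direction == "below":
        mask = values < threshold
    else:
        raise ValueError("direction must be 'above' or 'below'")
    areas = index_map.mesh.cell_areas
    area = float(areas[mask].sum())
    return ThresholdResult(area, area / index_map.mesh.total_area, mask)
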
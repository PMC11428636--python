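"""Synthetic inputs with known ground truth.

Patient imaging and commercial-CFD exports behind hemodynamic studies are
rarely deposited, so every input the pipeline consumes can be generated
here with machine-readable ground truth:

* clinical-like central aortic pressure waveforms exhibiting the seven
  morphological landmarks (upstroke, incident rise, systolic peak,
  late-systolic decline, dicrotic notch, diastolic runoff, end-diastolic
  pressure), with exact landmark locations returned alongside;
* a single-hump inlet velocity waveform peaking at t = 0.15 s with an
  exactly prescribed cycle-mean velocity (0.14 m/s by default, which at a
  35.88 mm diameter and mu = 0.004 Pa*s corresponds to Re ~ 1331);
* multi-resolution triangulated tube surfaces (straight or gently curved)
  emulating 0.2-1.0 mm element-size families;
* per-cell WSS vector time series with planted TAWSS/OSI/RRT/ECAP.  The
  analytic mode uses square-wave temporal bases whose duty cycle f fixes
  OSI = (1 - |2f - 1|)/2 in closed form, with sign transitions placed
  halfway between samples so that trapezoidal quadrature recovers the
  planted values exactly;
* mesh-study tables with a planted convergence law value(h) = v* + C h^p.

Every generator is a pure, bitwise-deterministic function of its
``SynthConfig`` (including the seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .mesh_sensitivity import MeshStudyRow, MeshStudyTable
from .pulse_solver import WaveformSeries
from .wall_indices import (
    SurfaceMesh,
    WSSFieldSeries,
    WallIndexMap,
    compute_rrt,
    compute_ecap,
)
from .waveform_analysis import PressureWaveform, WaveformFeatures, Landmark, extract_features

__all__ = [
    "SynthConfig",
    "synth_pressure_waveform",
    "synth_flow_waveform",
    "synth_tube_mesh",
    "synth_wss_series",
    "synth_mesh_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generators.

    Defaults mirror a resting adult protocol: a 1.0 s cardiac cycle (3000
    solver steps of 0.001 s over three cycles), inlet velocity peaking at
    t = 0.15 s with a 0.14 m/s cycle mean, 120/80 mmHg central pressures,
    an ascending-aorta radius of 17.94 mm, and surface resolutions of
    0.2-1.0 mm in 0.2 mm steps.
    """

    seed: int = 0
    period_T: float = 1.0
    sbp: float = 120.0            # systolic peak pressure, mmHg
    dbp: float = 80.0             # diastolic minimum pressure, mmHg
    t_peak: float = 0.15          # inlet velocity peak time, s
    radius: float = 0.01794       # tube radius, m
    length: float = 0.10          # tube length, m
    element_sizes_mm: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    mean_velocity: float = 0.14   # cycle-mean inlet velocity, m/s
    flow_amplitude: float = 0.85  # pulsatility scale of the inlet waveform, m/s
    backflow_velocity: float = 0.02  # early-diastolic reverse-flow bump, m/s
    n_pressure_samples: int = 1000
    n_flow_samples: int = 1000
    wss_samples_per_cycle: int = 200
    osi_targets: tuple = (0.0, 0.1, 0.25, 0.4, 0.5)  # per axial region
    wss_magnitudes: tuple | None = None  # Pa per region; None -> seeded draw
    notch_depth: float = 0.15     # relative depth of the dicrotic dip
    noise: float = 0.0            # relative noise for the mesh-study generator

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError("need sbp > dbp > 0")
        if not (0 < self.t_peak < self.period_T):
            raise ValueError("t_peak must lie inside the period")
        if any(s <= 0 for s in self.element_sizes_mm):
            raise ValueError("element sizes must be positive")
        if any(not (0.0 <= o <= 0.5) for o in self.osi_targets):
            raise ValueError("OSI targets must lie in [0, 0.5]")
        if self.wss_magnitudes is not None:
            if len(self.wss_magnitudes) != len(self.osi_targets):
                raise ValueError("wss_magnitudes must match osi_targets in length")
            if any(not (0 < m <= 50.0) for m in self.wss_magnitudes):
                raise ValueError("wss_magnitudes must lie in (0, 50] Pa")
        if self.notch_depth < 0:
            raise ValueError("notch_depth must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


# --------------------------------------------------------------------------
# waveforms
# --------------------------------------------------------------------------

def synth_pressure_waveform(cfg: SynthConfig) -> tuple[PressureWaveform, WaveformFeatures]:
    """Central aortic pressure waveform with planted landmarks.

    Construction: a main systolic Gaussian, a broader reflected hump, a
    narrow negative Gaussian (the incisura) and the implied diastolic
    runoff, affinely rescaled so the global maximum is exactly ``sbp`` and
    the global minimum (the end-diastolic sample) exactly ``dbp``.  The
    returned features are the landmarks evaluated on the emitted samples.
    """
    rng = _stream_rng(cfg.seed, 1)
    T = cfg.period_T
    n = cfg.n_pressure_samples
    t = np.linspace(0.0, T, n, endpoint=False)
    x = t / T

    c_main = 0.28 + rng.uniform(-0.01, 0.01)
    w_main = 0.11 * (1 + rng.uniform(-0.05, 0.05))
    c_refl = 0.52 + rng.uniform(-0.01, 0.01)
    w_refl = 0.18 * (1 + rng.uniform(-0.05, 0.05))
    c_notch = 0.43 + rng.uniform(-0.005, 0.005)
    w_notch = 0.025 * (1 + rng.uniform(-0.05, 0.05))
    depth = cfg.notch_depth * (1 + rng.uniform(-0.1, 0.1)) if cfg.notch_depth > 0 else 0.0

    raw = (
        np.exp(-(((x - c_main) / w_main) ** 2))
        + 0.35 * np.exp(-(((x - c_refl) / w_refl) ** 2))
        - depth * np.exp(-(((x - c_notch) / w_notch) ** 2))
    )
    p = cfg.dbp + (cfg.sbp - cfg.dbp) * (raw - raw.min()) / (raw.max() - raw.min())
    wave = PressureWaveform(t, p, T, label="synthetic central aorta")

    i_max = int(np.argmax(p))
    i_min = int(np.argmin(p))
    notch = None
    if depth > 0.0:
        # the incisura is the unique interior local minimum planted by the
        # negative Gaussian: locate the sign change of the slope nearest the
        # planted center (the post-systolic baseline is monotone, so this is
        # also the only local minimum after the peak)
        dp = np.diff(p)
        local_min = np.flatnonzero((dp[:-1] < 0) & (dp[1:] > 0)) + 1
        near = local_min[np.abs(x[local_min] - c_notch) <= 4 * w_notch]
        if near.size == 0:
            raise ValueError(
                "notch landmark infeasible: the dip did not produce a local "
                "minimum; increase notch_depth"
            )
        j = int(near[np.argmin(np.abs(x[near] - c_notch))])
        notch = Landmark(float(p[j]), float(t[j]))
    tt = np.concatenate([t, [T]])
    pp = np.concatenate([p, [p[0]]])
    mean_p = float(np.trapezoid(pp, tt) / T)
    slopes = np.diff(p[: i_max + 1]) / np.diff(t[: i_max + 1])
    truth = WaveformFeatures(
        systolic_peak=Landmark(float(p[i_max]), float(t[i_max])),
        diastolic_min=Landmark(float(p[i_min]), float(t[i_min])),
        dicrotic_notch=notch,
        end_diastolic_pressure=float(p[-1]),
        pulse_pressure=float(p[i_max] - p[i_min]),
        mean_pressure=mean_p,
        upstroke_slope=float(np.max(slopes)) if slopes.size else 0.0,
    )
    return wave, truth


def synth_flow_waveform(cfg: SynthConfig, as_flow_rate: bool = False) -> WaveformSeries:
    """Inlet velocity (or volumetric flow) waveform.

    A smooth sin^2 systolic hump over [0, 2*t_peak] (so the peak falls
    exactly at ``t_peak``) with an optional small early-diastolic backflow
    bump, shifted so the discrete periodic-trapezoid cycle mean equals
    ``mean_velocity`` exactly.  With ``flow_amplitude = 0`` the waveform is
    constant at the mean.  ``as_flow_rate`` multiplies by the lumen area
    pi R^2 to give m^3/s.
    """
    T = cfg.period_T
    n = cfg.n_flow_samples
    t = np.linspace(0.0, T, n, endpoint=False)
    t_sys = 2.0 * cfg.t_peak
    if t_sys >= T:
        raise ValueError("systolic interval 2*t_peak must be shorter than the period")
    shape = np.where(t < t_sys, np.sin(np.pi * t / t_sys) ** 2, 0.0)
    if cfg.backflow_velocity > 0 and cfg.flow_amplitude > 0:
        t_back0, t_back1 = t_sys, min(t_sys + 0.15 * T, T)
        in_back = (t >= t_back0) & (t < t_back1)
        rel = (t[in_back] - t_back0) / (t_back1 - t_back0)
        shape = shape.astype(float)
        shape[in_back] -= (cfg.backflow_velocity / max(cfg.flow_amplitude, 1e-30)) * np.sin(np.pi * rel) ** 2

    def cycle_mean(v: np.ndarray) -> float:
        tt = np.concatenate([t, [T]])
        vv = np.concatenate([v, [v[0]]])
        return float(np.trapezoid(vv, tt) / T)

    v = cfg.flow_amplitude * shape
    v = v + (cfg.mean_velocity - cycle_mean(v))
    values = v * (np.pi * cfg.radius**2) if as_flow_rate else v
    units = "m^3/s" if as_flow_rate else "m/s"
    return WaveformSeries(t, values, T, units=units)


# --------------------------------------------------------------------------
# surface meshes
# --------------------------------------------------------------------------

def synth_tube_mesh(R: float, length: float, element_size_mm: float,
                    curved: bool = False) -> SurfaceMesh:
    """Triangulated tube (straight cylinder or torus segment) surface.

    Structured rings of near-equilateral triangles with mean edge length
    within 10% of the requested element size and consistent outward
    normals.  The curved variant bends the axis along a circular arc of the
    same centerline length (lateral area 2*pi*R*L holds exactly by Pappus).
    """
    h = element_size_mm * 1e-3
    if R <= 0 or length <= 0:
        raise ValueError("R and length must be positive")
    if h >= R:
        raise ValueError("element size must be smaller than the tube radius")
    n_theta = max(8, int(round(2 * np.pi * R / h)))
    n_z = max(2, int(round(length / (h * np.sqrt(3) / 2))))
    theta = 2 * np.pi * np.arange(n_theta) / n_theta

    if not curved:
        z = np.linspace(0.0, length, n_z + 1)
        ring = np.stack([R * np.cos(theta), R * np.sin(theta)], axis=1)
        verts = np.empty(((n_z + 1) * n_theta, 3))
        for j, zj in enumerate(z):
            verts[j * n_theta:(j + 1) * n_theta, :2] = ring
            verts[j * n_theta:(j + 1) * n_theta, 2] = zj
    else:
        bend = np.pi / 3.0
        Rc = length / bend
        Theta = np.linspace(0.0, bend, n_z + 1)
        verts = np.empty(((n_z + 1) * n_theta, 3))
        for j, Tj in enumerate(Theta):
            rr = Rc + R * np.cos(theta)
            sl = slice(j * n_theta, (j + 1) * n_theta)
            verts[sl, 0] = rr * np.cos(Tj)
            verts[sl, 1] = rr * np.sin(Tj)
            verts[sl, 2] = R * np.sin(theta)

    tris = []
    for j in range(n_z):
        base0 = j * n_theta
        base1 = (j + 1) * n_theta
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            a, b = base0 + i, base0 + i2
            c, d = base1 + i, base1 + i2
            tris.append((a, b, d))
            tris.append((a, d, c))
    mesh = SurfaceMesh(verts, np.array(tris, dtype=np.int64),
                       nominal_element_size=element_size_mm)
    # enforce outward orientation (radially for the straight tube, away from
    # the local arc center for the curved one)
    centers = mesh.cell_centers
    if not curved:
        outward = centers - np.array([0.0, 0.0, 1.0]) * centers[:, 2:3]
    else:
        phi = np.arctan2(centers[:, 1], centers[:, 0])
        axis_pts = np.stack(
            [ (length / (np.pi / 3.0)) * np.cos(phi),
              (length / (np.pi / 3.0)) * np.sin(phi),
              np.zeros_like(phi) ], axis=1)
        outward = centers - axis_pts
    flip = np.einsum("ij,ij->i", mesh.cell_normals, outward) < 0
    if np.any(flip):
        t = mesh.triangles.copy()
        t[flip] = t[flip][:, [0, 2, 1]]
        mesh = SurfaceMesh(verts, t, nominal_element_size=element_size_mm)
    return mesh


# --------------------------------------------------------------------------
# WSS fields
# --------------------------------------------------------------------------

def _tangent_direction(mesh: SurfaceMesh, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Unit tangential direction per cell: the axis projected on the wall."""
    a = np.asarray(axis, dtype=float)
    n = mesh.cell_normals
    d = a[None, :] - (n @ a)[:, None] * n
    norm = np.linalg.norm(d, axis=1)
    bad = norm < 1e-12
    if np.any(bad):  # cell normal parallel to the axis; fall back to x
        alt = np.array([1.0, 0.0, 0.0])
        d[bad] = alt[None, :] - (n[bad] @ alt)[:, None] * n[bad]
        norm = np.linalg.norm(d, axis=1)
    return d / norm[:, None]


def synth_wss_series(mesh: SurfaceMesh, cfg: SynthConfig, mode: str = "analytic",
                     flow_solution=None) -> tuple[WSSFieldSeries, WallIndexMap]:
    """WSS vector series with a planted wall-index map.

    analytic mode
        Cells are partitioned into axial bands, one per entry of
        ``cfg.osi_targets``.  Each band oscillates along its tangential
        direction as a unit square wave of duty cycle f = 1 - OSI_target
        (quantized to the sample grid, transitions halfway between samples)
        scaled by a per-band magnitude drawn once from the seed; the
        planted TAWSS equals that magnitude exactly and the planted OSI is
        (1 - |2*f - 1|)/2 of the quantized duty cycle.

    solver mode
        The wall-shear history of an axisymmetric pulse solution (pass one
        as ``flow_solution``; by default a unidirectional pressure-driven
        Carreau solve on the config geometry) is mapped along the tube with
        a smooth axial modulation; the flow never reverses, so the planted
        OSI is 0 everywhere and the planted TAWSS is the cycle-mean wall
        shear times the modulation.
    """
    T = cfg.period_T
    N = cfg.wss_samples_per_cycle
    times = T * np.arange(N) / N
    z = mesh.cell_centers[:, 2] if mode == "analytic" else None
    d_hat = _tangent_direction(mesh)

    if mode == "analytic":
        rng = _stream_rng(cfg.seed, 2)
        targets = np.asarray(cfg.osi_targets, dtype=float)
        n_regions = targets.size
        zc = mesh.cell_centers[:, 2]
        # straight tubes band along z; curved ones along the arc angle
        coord = zc if np.ptp(zc) > 1e-9 else np.arctan2(mesh.cell_centers[:, 1], mesh.cell_centers[:, 0])
        edges = np.quantile(coord, np.linspace(0, 1, n_regions + 1))
        region = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_regions - 1)
        if cfg.wss_magnitudes is not None:
            mags = np.asarray(cfg.wss_magnitudes, dtype=float)
        else:
            mags = rng.uniform(0.5, 20.0, size=n_regions)  # Pa, physiological band

        wss = np.zeros((N, mesh.n_cells, 3))
        tawss = np.zeros(mesh.n_cells)
        osi = np.zeros(mesh.n_cells)
        for k in range(n_regions):
            f = 1.0 - targets[k]
            j = int(round(f * N))
            j = min(max(j, 0), N)
            f_hat = j / N
            s = np.where(np.arange(N) < j, 1.0, -1.0)
            cells = np.flatnonzero(region == k)
            wss[:, cells, :] = mags[k] * s[:, None, None] * d_hat[cells][None, :, :]
            tawss[cells] = mags[k]
            osi[cells] = 0.5 * (1.0 - abs(2.0 * f_hat - 1.0))
        series = WSSFieldSeries(mesh, times, wss, T)
    elif mode == "solver":
        if flow_solution is None:
            from .pulse_solver import build_radial_grid, solve_pressure_driven, WaveformSeries as WS
            from .rheology import BLOOD
            grid = build_radial_grid(cfg.radius, n_interior=24)
            tt = np.linspace(0.0, T, 64, endpoint=False)
            # unidirectional forcing: mean gradient exceeds the oscillation
            g = -(80.0 + 40.0 * np.sin(2 * np.pi * tt / T))
            flow_solution = solve_pressure_driven(
                BLOOD, grid, WS(tt, g, T, units="Pa/m"), dt=T / 200, n_cycles=2
            )
        tau = np.interp(np.mod(times, T), flow_solution.times,
                        flow_solution.tau_wall, period=T)
        zc = mesh.cell_centers[:, 2]
        span = np.ptp(zc) if np.ptp(zc) > 0 else 1.0
        modulation = 1.0 + 0.3 * np.sin(2 * np.pi * (zc - zc.min()) / span)
        wss = tau[:, None, None] * modulation[None, :, None] * d_hat[None, :, :]
        tt2 = np.concatenate([times, [T]])
        tau2 = np.concatenate([tau, [tau[0]]])
        tau_mean = float(np.trapezoid(tau2, tt2) / T)
        tawss = tau_mean * modulation
        osi = np.zeros(mesh.n_cells)
        series = WSSFieldSeries(mesh, times, wss, T)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    truth = WallIndexMap(
        mesh=mesh, tawss=tawss, osi=osi,
        rrt=compute_rrt(tawss, osi), ecap=compute_ecap(tawss, osi),
        n_rrt_singular=int(np.count_nonzero(osi >= 0.5)),
    )
    return series, truth


# --------------------------------------------------------------------------
# mesh-study tables
# --------------------------------------------------------------------------

def synth_mesh_study(cfg: SynthConfig, true_v: float = 0.75, true_wss: float = 20.0,
                     C_v: float = 0.05, C_wss: float = 5.0, p: float = 2.0,
                     family: str = "synthetic") -> MeshStudyTable:
    """Mesh-study table with a planted convergence law value(h) = v* + C*h^p.

    Element counts scale like h^-3 (volumetric refinement); ``cfg.noise``
    adds seeded relative perturbations.
    """
    if p <= 0:
        raise ValueError("convergence order p must be positive")
    rng = _stream_rng(cfg.seed, 3)
    sizes = np.asarray(sorted(cfg.element_sizes_mm), dtype=float)
    noise_v = cfg.noise * rng.standard_normal(sizes.size)
    noise_w = cfg.noise * rng.standard_normal(sizes.size)
    rows = []
    count0 = 7.0e6 * sizes.min() ** 3  # anchor: ~7M elements at the finest size
    for i, hmm in enumerate(sizes):
        v = true_v + C_v * hmm**p
        w = true_wss + C_wss * hmm**p
        v *= 1.0 + noise_v[i]
        w *= 1.0 + noise_w[i]
        rows.append(
            MeshStudyRow(
                element_size_mm=float(hmm),
                element_count=max(1, int(round(count0 / hmm**3))),
                v_max=float(v),
                wss_max=float(w),
            )
        )
    return MeshStudyTable(family=family, rows=tuple(rows))
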
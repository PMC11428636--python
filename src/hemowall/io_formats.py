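"""File formats, run configuration and the end-to-end pipeline.

Formats:

* waveforms — CSV with a metadata comment line and a mandatory
  ``t_s,value`` header;
* surfaces and per-cell fields — ASCII VTK-XML PolyData (.vtp), readable by
  standard visualization tools;
* WSS time series — either a directory of per-step .vtp files with a JSON
  manifest, or a single HDF5 container;
* solver output — HDF5 container with /times, /radii, /u, /tau_wall, /Q,
  /dpdx datasets and parameter attributes;
* reports and ground truth — JSON (sorted keys, no timestamps, so repeated
  runs with one seed are byte-identical).

Infinite RRT/ECAP sentinels are written to VTK as a large finite value
(1e30) with a companion ``*_finite`` mask array, because VTK-XML readers
handle IEEE infinities inconsistently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .mesh_sensitivity import MeshStudyTable, build_report, render_report
from .pulse_solver import (
    FlowSolution,
    RadialGrid,
    WaveformSeries,
    build_radial_grid,
    solve_flow_driven,
)
from .rheology import BLOOD, CarreauParameters
from .synthetic_data import (
    SynthConfig,
    synth_flow_waveform,
    synth_mesh_study,
    synth_pressure_waveform,
    synth_tube_mesh,
    synth_wss_series,
)
from .wall_indices import (
    SurfaceMesh,
    WallIndexMap,
    WSSFieldSeries,
    compute_indices,
    threshold_area,
    TAWSS_HIGH_THRESHOLD_PA,
    TAWSS_LOW_THRESHOLD_PA,
)
from .waveform_analysis import PressureWaveform, extract_features

__all__ = [
    "ParseError",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_polydata",
    "read_polydata",
    "write_wss_series",
    "read_wss_series",
    "write_index_map",
    "save_flow_solution",
    "load_flow_solution",
    "RunConfig",
    "run_pipeline",
    "VTK_INF_SENTINEL",
]

logger = logging.getLogger(__name__)

VTK_INF_SENTINEL = 1e30


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# --------------------------------------------------------------------------
# waveform CSV
# --------------------------------------------------------------------------

def write_waveform_csv(path, times, values, units: str, period_T: float,
                       label: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units={units} period_T={period_T!r} label={label}\n")
        fh.write("t_s,value\n")
        for t, v in zip(times, values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def _parse_meta(line: str) -> dict:
    meta = {"units": "", "period_T": None, "label": ""}
    if not line.startswith("#"):
        return meta
    body = line[1:].strip()
    if "label=" in body:
        head, label = body.split("label=", 1)
        meta["label"] = label.strip()
        body = head
    for tok in body.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            if k == "units":
                meta["units"] = v
            elif k == "period_T":
                meta["period_T"] = float(v)
    return meta


def read_waveform_csv(path, kind: str = "auto", period_T: float | None = None):
    """Read a waveform CSV into a PressureWaveform or WaveformSeries.

    ``kind`` is "pressure", "series" or "auto" (pressure when the units tag
    is mmHg).  The period defaults to the metadata value, then to the last
    sample time.  Errors name the first offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    meta = _parse_meta(lines[0])
    start = 1 if lines[0].startswith("#") else 0
    if start >= len(lines) or lines[start].strip().replace(" ", "") != "t_s,value":
        raise ParseError(
            f"{path}, line {start + 1}: missing mandatory header 't_s,value'"
        )
    times, values = [], []
    prev_t = -np.inf
    for ln_no, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            if ";" in line or line.count(",") > 2:
                raise ParseError(
                    f"{path}, line {ln_no}: expected two comma-separated fields; "
                    "if the file uses a comma decimal separator, rewrite it with "
                    "'.' decimals and ',' field separators"
                )
            raise ParseError(f"{path}, line {ln_no}: expected 't,value'")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise ParseError(
                f"{path}, line {ln_no}: could not parse numbers from {line!r}"
            ) from None
        if not (np.isfinite(t) and np.isfinite(v)):
            raise ParseError(f"{path}, line {ln_no}: non-finite value")
        if t <= prev_t:
            raise ParseError(
                f"{path}, line {ln_no}: times must be strictly increasing "
                f"({t} after {prev_t})"
            )
        prev_t = t
        times.append(t)
        values.append(v)
    times = np.asarray(times)
    values = np.asarray(values)
    T = period_T or meta["period_T"] or float(times[-1])
    units = meta["units"]
    if kind == "pressure" or (kind == "auto" and units.lower() == "mmhg"):
        return PressureWaveform(times, values, T, label=meta["label"])
    return WaveformSeries(times, values, T, units=units)


# --------------------------------------------------------------------------
# VTK-XML PolyData (ASCII)
# --------------------------------------------------------------------------

def _data_array(name: str | None, arr: np.ndarray, dtype: str) -> ET.Element:
    el = ET.Element("DataArray", type=dtype, format="ascii")
    if name:
        el.set("Name", name)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        el.set("NumberOfComponents", str(arr.shape[1]))
    if dtype.startswith("Float"):
        el.text = " ".join(repr(float(x)) for x in arr.ravel())
    else:
        el.text = " ".join(str(int(x)) for x in arr.ravel())
    return el


def write_polydata(path, mesh: SurfaceMesh, cell_data: dict | None = None) -> None:
    """Write a triangulated surface with per-cell arrays as ASCII .vtp."""
    if mesh.n_cells == 0:
        raise ValueError("refusing to write an empty mesh")
    root = ET.Element("VTKFile", type="PolyData", version="1.0",
                      byte_order="LittleEndian")
    pd = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        pd, "Piece",
        NumberOfPoints=str(mesh.vertices.shape[0]),
        NumberOfVerts="0", NumberOfLines="0", NumberOfStrips="0",
        NumberOfPolys=str(mesh.n_cells),
    )
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array(None, mesh.vertices, "Float64"))
    polys = ET.SubElement(piece, "Polys")
    polys.append(_data_array("connectivity", mesh.triangles.ravel(), "Int64"))
    polys.append(_data_array("offsets", 3 * (np.arange(mesh.n_cells) + 1), "Int64"))
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != mesh.n_cells:
                raise ValueError(f"cell array {name!r} length mismatch")
            cd.append(_data_array(name, arr, "Float64"))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_polydata(path) -> tuple[SurfaceMesh, dict]:
    """Read an ASCII .vtp written by :func:`write_polydata`."""
    tree = ET.parse(path)
    piece = tree.getroot().find("./PolyData/Piece")
    if piece is None:
        raise ParseError(f"{path}: not a VTK PolyData file")

    def _floats(el):
        return np.array((el.text or "").split(), dtype=float)

    pts_el = piece.find("./Points/DataArray")
    verts = _floats(pts_el).reshape(-1, 3)
    conn_el = piece.find("./Polys/DataArray[@Name='connectivity']")
    offs_el = piece.find("./Polys/DataArray[@Name='offsets']")
    conn = np.array((conn_el.text or "").split(), dtype=np.int64)
    offs = np.array((offs_el.text or "").split(), dtype=np.int64)
    if np.any(np.diff(np.concatenate([[0], offs])) != 3):
        raise ParseError(f"{path}: only all-triangle PolyData is supported")
    tris = conn.reshape(-1, 3)
    cell_data = {}
    for el in piece.findall("./CellData/DataArray"):
        arr = _floats(el)
        ncomp = int(el.get("NumberOfComponents", "1"))
        cell_data[el.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    return SurfaceMesh(verts, tris), cell_data


# --------------------------------------------------------------------------
# WSS field series
# --------------------------------------------------------------------------

def write_wss_series(series: WSSFieldSeries, out: Path, basename: str = "wss",
                     container: str = "vtp") -> Path:
    """Persist a WSS series as .vtp steps + JSON manifest, or one HDF5 file.

    Returns the path to the manifest (vtp) or the .h5 file.
    """
    out = Path(out)
    if container == "vtp":
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for k, t in enumerate(series.times):
            fname = f"{basename}_{k:04d}.vtp"
            write_polydata(out / fname, series.mesh, {"WSS": series.wss[k]})
            files.append(fname)
        manifest = {
            "period_T": series.period_T,
            "times": [float(t) for t in series.times],
            "files": files,
            "wss_array": "WSS",
        }
        mpath = out / f"{basename}_series.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return mpath
    if container == "h5":
        out.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(out, "w") as f:
            f.create_dataset("times", data=series.times)
            f.create_dataset("wss", data=series.wss)
            f.create_dataset("vertices", data=series.mesh.vertices)
            f.create_dataset("triangles", data=series.mesh.triangles)
            f.attrs["period_T"] = series.period_T
            if series.mesh.nominal_element_size is not None:
                f.attrs["nominal_element_size_mm"] = series.mesh.nominal_element_size
        return out
    raise ValueError(f"unknown container {container!r}")


def read_wss_series(path) -> WSSFieldSeries:
    """Load a WSS series from a JSON manifest of .vtp steps or an HDF5 file."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            mesh = SurfaceMesh(
                f["vertices"][...], f["triangles"][...],
                nominal_element_size=f.attrs.get("nominal_element_size_mm"),
            )
            return WSSFieldSeries(mesh, f["times"][...], f["wss"][...],
                                  float(f.attrs["period_T"]))
    manifest = json.loads(path.read_text())
    files = manifest["files"]
    times = np.asarray(manifest["times"], dtype=float)
    name = manifest.get("wss_array", "WSS")
    mesh = None
    wss = None
    for k, fname in enumerate(files):
        step_path = path.parent / fname
        try:
            m, cd = read_polydata(step_path)
        except (OSError, ParseError, ValueError, ET.ParseError) as exc:
            raise ParseError(f"step {k} ({fname}): {exc}") from exc
        if name not in cd:
            raise ParseError(f"step {k} ({fname}): missing cell array {name!r}")
        arr = cd[name]
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ParseError(f"step {k} ({fname}): array {name!r} is not 3-component")
        if mesh is None:
            mesh = m
            wss = np.empty((len(files), m.n_cells, 3))
        elif m.n_cells != mesh.n_cells:
            raise ParseError(
                f"step {k} ({fname}): cell count {m.n_cells} != {mesh.n_cells}"
            )
        wss[k] = arr
    return WSSFieldSeries(mesh, times, wss, float(manifest["period_T"]))


# --------------------------------------------------------------------------
# wall-index output
# --------------------------------------------------------------------------

def write_index_map(index_map: WallIndexMap, out_base,
                    thresholds: dict | None = None) -> dict:
    """Write a wall-index map as .vtp + .csv + .json report.

    ``out_base`` is a path without extension.  ``thresholds`` maps a field
    name to ``(threshold, direction)``; defaults cover the high- and
    low-TAWSS demonstrations (5 Pa above, 0.4 Pa below).  Returns the report
    dict.
    """
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    if index_map.mesh.n_cells == 0:
        raise ValueError("empty index map")
    if thresholds is None:
        thresholds = {
            "tawss_high": ("tawss", TAWSS_HIGH_THRESHOLD_PA, "above"),
            "tawss_low": ("tawss", TAWSS_LOW_THRESHOLD_PA, "below"),
        }
    cell_data = {}
    masks = {}
    for fname in ("tawss", "osi", "rrt", "ecap"):
        arr = getattr(index_map, fname).astype(float).copy()
        finite = np.isfinite(arr)
        arr[~finite] = VTK_INF_SENTINEL
        cell_data[fname.upper()] = arr
        if fname in ("rrt", "ecap"):
            cell_data[f"{fname.upper()}_finite"] = finite.astype(float)
    report = {
        "n_cells": index_map.mesh.n_cells,
        "total_area_m2": index_map.mesh.total_area,
        "sentinel_counts": {
            "zero_wss_cells": index_map.n_zero_wss_cells,
            "rrt_singular": index_map.n_rrt_singular,
            "ecap_singular": index_map.n_ecap_singular,
        },
        "area_fractions": {},
    }
    for key, (fname, thr, direction) in thresholds.items():
        res = threshold_area(index_map, fname, thr, direction)
        cell_data[f"mask_{key}"] = res.cell_mask.astype(float)
        report["area_fractions"][key] = {
            "field": fname, "threshold": thr, "direction": direction,
            "area_m2": res.area_m2, "fraction": res.fraction,
        }
    write_polydata(out_base.with_suffix(".vtp"), index_map.mesh, cell_data)
    import pandas as pd
    df = pd.DataFrame({
        "cell_id": np.arange(index_map.mesh.n_cells),
        "area_m2": index_map.mesh.cell_areas,
        "tawss_pa": index_map.tawss,
        "osi": index_map.osi,
        "rrt_per_pa": index_map.rrt,
        "ecap_per_pa": index_map.ecap,
    })
    df.to_csv(out_base.with_suffix(".csv"), index=False)
    out_base.with_suffix(".json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# --------------------------------------------------------------------------
# solver HDF5 container
# --------------------------------------------------------------------------

def save_flow_solution(sol: FlowSolution, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=sol.times)
        f.create_dataset("radii", data=sol.grid.radii)
        f.create_dataset("u", data=sol.u)
        f.create_dataset("tau_wall", data=sol.tau_wall)
        f.create_dataset("tau_wall_signed", data=sol.tau_wall_signed)
        f.create_dataset("Q", data=sol.Q)
        f.create_dataset("dpdx", data=sol.dpdx)
        f.attrs["R"] = sol.grid.R
        f.attrs["layer_spec"] = list(sol.grid.layer_spec)
        f.attrs["n_cycles_run"] = sol.n_cycles_run
        f.attrs["converged"] = sol.converged
        f.attrs["periodicity_error"] = sol.periodicity_error


def load_flow_solution(path) -> FlowSolution:
    with h5py.File(path, "r") as f:
        ls = f.attrs["layer_spec"]
        grid = RadialGrid(f["radii"][...], float(f.attrs["R"]),
                          (float(ls[0]), int(ls[1]), float(ls[2])))
        return FlowSolution(
            grid=grid,
            times=f["times"][...],
            u=f["u"][...],
            tau_wall=f["tau_wall"][...],
            tau_wall_signed=f["tau_wall_signed"][...],
            Q=f["Q"][...],
            dpdx=f["dpdx"][...],
            n_cycles_run=int(f.attrs["n_cycles_run"]),
            converged=bool(f.attrs["converged"]),
            periodicity_error=float(f.attrs["periodicity_error"]),
        )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "rheology": {"mu_zero": 0.056, "mu_inf": 0.0035, "lambda_s": 3.313,
                 "n_index": 0.568, "rho": 1060.0},
    "solver": {"dt": 0.001, "n_cycles": 3, "picard_tol": 1e-5,
               "max_picard": 30, "n_interior": 48,
               "first_layer": 1e-4, "n_layers": 5, "growth": 1.2},
    "indices": {"tawss_high_pa": 5.0, "tawss_low_pa": 0.4},
    "waveform": {"notch_window": 0.4, "resample_points": 1000},
    "sensitivity": {"threshold_pct": 3.0},
    "synth": {},        # SynthConfig overrides
    "paths": {},        # optional external inputs
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with reference defaults.

    Defaults reproduce the standard protocol: dt = 0.001 s, 3 cycles,
    1e-5 residual, 3% mesh threshold, 5 Pa / 0.4 Pa TAWSS thresholds.
    Unknown keys anywhere in the document are rejected.
    """

    seed: int = 0
    rheology: CarreauParameters = field(default_factory=lambda: BLOOD)
    solver: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["solver"]))
    indices: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["indices"]))
    waveform: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["waveform"]))
    sensitivity: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG["sensitivity"]))
    synth: SynthConfig = field(default_factory=SynthConfig)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        unknown = set(doc) - set(_DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for block, defaults in _DEFAULT_CONFIG.items():
            if isinstance(defaults, dict):
                given = doc.get(block, {}) or {}
                if block not in ("synth", "paths"):
                    bad = set(given) - set(defaults)
                    if bad:
                        raise ValueError(f"unknown keys in '{block}': {sorted(bad)}")
                merged[block] = {**defaults, **given}
            else:
                merged[block] = doc.get(block, defaults)
        paths = merged["paths"]
        for key, p in paths.items():
            if not Path(p).exists():
                raise ValueError(f"configured path '{key}' does not exist: {p}")
        seed = int(merged["seed"])
        synth_kwargs = merged["synth"]
        synth_kwargs.setdefault("seed", seed)
        return cls(
            seed=seed,
            rheology=CarreauParameters.from_dict(merged["rheology"]),
            solver=merged["solver"],
            indices=merged["indices"],
            waveform=merged["waveform"],
            sensitivity=merged["sensitivity"],
            synth=SynthConfig(**synth_kwargs),
            paths=paths,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc or {})

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "rheology": self.rheology.to_dict(),
            "solver": self.solver,
            "indices": self.indices,
            "waveform": self.waveform,
            "sensitivity": self.sensitivity,
            "synth": self.synth.to_dict(),
            "paths": {k: str(v) for k, v in self.paths.items()},
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Synthesize inputs, solve, post-process and write the report bundle.

    Stages: synthetic inputs -> flow-driven pulse solve -> wall indices ->
    waveform features -> mesh-sensitivity report.  All numeric content is a
    pure function of the config (seed included); reports embed the config
    digest so reruns are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.synth
    report: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}

    logger.info("stage synth: waveforms, surface mesh, WSS series (seed=%d)", config.seed)
    pressure, truth = synth_pressure_waveform(cfg)
    flow = synth_flow_waveform(cfg, as_flow_rate=True)
    write_waveform_csv(out / "pressure.csv", pressure.times, pressure.pressures,
                       "mmHg", pressure.period_T, pressure.label)
    write_waveform_csv(out / "inlet_flow.csv", flow.times, flow.values,
                       flow.units, flow.period_T, "synthetic inlet")
    (out / "pressure_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    mesh = synth_tube_mesh(cfg.radius, cfg.length, max(cfg.element_sizes_mm))
    wss_series, planted = synth_wss_series(mesh, cfg, mode="analytic")
    report["stages"]["synth"] = {
        "n_cells": mesh.n_cells,
        "pressure_truth": truth.to_dict(),
    }

    logger.info("stage solve: flow-driven pulse solve")
    sol_cfg = config.solver
    grid = build_radial_grid(cfg.radius, first_layer=sol_cfg["first_layer"],
                             n_layers=sol_cfg["n_layers"], growth=sol_cfg["growth"],
                             n_interior=sol_cfg["n_interior"])
    solution = solve_flow_driven(
        config.rheology, grid, flow, dt=sol_cfg["dt"],
        n_cycles=sol_cfg["n_cycles"], picard_tol=sol_cfg["picard_tol"],
        max_picard=sol_cfg["max_picard"],
    )
    save_flow_solution(solution, out / "solution.h5")
    report["stages"]["solve"] = {
        "converged": solution.converged,
        "periodicity_error": solution.periodicity_error,
        "tau_wall_peak_pa": float(solution.tau_wall.max()),
        "tau_wall_mean_pa": float(solution.tau_wall.mean()),
    }

    logger.info("stage indices: TAWSS/OSI/RRT/ECAP on %d cells", mesh.n_cells)
    index_map = compute_indices(wss_series)
    idx_report = write_index_map(
        index_map, out / "wall_indices",
        thresholds={
            "tawss_high": ("tawss", config.indices["tawss_high_pa"], "above"),
            "tawss_low": ("tawss", config.indices["tawss_low_pa"], "below"),
        },
    )
    recovery = float(np.max(np.abs(index_map.tawss - planted.tawss)
                            / np.maximum(planted.tawss, 1e-30)))
    report["stages"]["indices"] = {**idx_report, "tawss_recovery_max_rel_err": recovery}

    logger.info("stage waveform: landmark extraction")
    feats = extract_features(pressure, notch_window=config.waveform["notch_window"])
    report["stages"]["waveform"] = feats.to_dict()

    logger.info("stage sensitivity: planted mesh study")
    table = synth_mesh_study(cfg)
    rep = build_report(table, threshold_pct=config.sensitivity["threshold_pct"])
    (out / "mesh_study.json").write_text(render_report(rep, table, fmt="json"))
    table.to_csv(out / "mesh_study.csv")
    report["stages"]["sensitivity"] = {
        "selected": rep.selected, "joint_selected": rep.joint_selected,
        "threshold_pct": rep.threshold_pct,
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
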
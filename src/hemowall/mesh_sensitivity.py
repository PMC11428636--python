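"""Mesh-independence (grid convergence) analysis for CFD summary tables.

Given per-resolution summaries (element size, element count, and the
parameters of interest V_max and WSS_max at peak systole), the procedure
compares each mesh with its next-coarser neighbor and reports the
percentage difference

    100 * |v_fine - v_coarse| / max(v_fine, v_coarse),

rounded half away from zero to an integer percent.  A mesh is accepted when
its difference from the next-coarser mesh does not exceed a threshold
(3% by convention); scanning from coarse to fine, the first qualifying
element size is selected, i.e. the least expensive acceptable mesh.  When
several parameters matter jointly, the finest of the per-parameter
selections is required.

The normalization-by-the-larger-value and the rounding rule are regression
-locked against a published ten-mesh healthy-aorta study bundled in
:mod:`hemowall.datasets` (all 16 printed percentage cells reproduce).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeshStudyRow",
    "MeshStudyTable",
    "PercentDiffs",
    "SensitivityReport",
    "consecutive_percent_diff",
    "select_mesh",
    "joint_selection",
    "build_report",
    "render_report",
]

PARAMETERS = ("v_max", "wss_max")

_CSV_COLUMNS = {
    "element_size_mm": "element_size_mm",
    "element_count": "element_count",
    "v_max_mps": "v_max",
    "wss_max_pa": "wss_max",
    "runtime_min": "runtime_min",
}


@dataclass(frozen=True)
class MeshStudyRow:
    """One resolution of a mesh family: size, count and peak-systole values."""

    element_size_mm: float
    element_count: int
    v_max: float          # m/s, maximum outlet velocity
    wss_max: float        # Pa, maximum wall shear stress
    runtime_min: float | None = None  # pass-through metadata only

    def __post_init__(self) -> None:
        if self.element_size_mm <= 0:
            raise ValueError("element_size_mm must be positive")
        if self.element_count <= 0:
            raise ValueError("element_count must be positive")
        if self.v_max < 0 or self.wss_max < 0:
            raise ValueError("v_max and wss_max must be non-negative")


@dataclass(frozen=True)
class MeshStudyTable:
    """Rows of a mesh family sorted by strictly increasing element size."""

    family: str
    rows: tuple[MeshStudyRow, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) < 2:
            raise ValueError("a mesh study needs at least 2 rows")
        sizes = [r.element_size_mm for r in rows]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("element sizes must be strictly increasing and unique")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([r.element_size_mm for r in self.rows])

    def values(self, parameter: str) -> np.ndarray:
        _check_parameter(parameter)
        return np.array([getattr(r, parameter) for r in self.rows], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_size_mm": [r.element_size_mm for r in self.rows],
                "element_count": [r.element_count for r in self.rows],
                "v_max_mps": [r.v_max for r in self.rows],
                "wss_max_pa": [r.wss_max for r in self.rows],
                "runtime_min": [r.runtime_min for r in self.rows],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str = "") -> "MeshStudyTable":
        missing = {"element_size_mm", "element_count", "v_max_mps", "wss_max_pa"} - set(df.columns)
        if missing:
            raise ValueError(f"mesh study table is missing columns: {sorted(missing)}")
        df = df.sort_values("element_size_mm")
        rows = []
        for _, rec in df.iterrows():
            rt = rec.get("runtime_min")
            rows.append(
                MeshStudyRow(
                    element_size_mm=float(rec["element_size_mm"]),
                    element_count=int(rec["element_count"]),
                    v_max=float(rec["v_max_mps"]),
                    wss_max=float(rec["wss_max_pa"]),
                    runtime_min=None if rt is None or pd.isna(rt) else float(rt),
                )
            )
        return cls(family=family, rows=tuple(rows))

    @classmethod
    def from_csv(cls, path, family: str = "") -> "MeshStudyTable":
        return cls.from_dataframe(pd.read_csv(path), family=family)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class PercentDiffs:
    """Consecutive-mesh differences: raw percentages and printed integers.

    Entry i compares row i (finer) with row i+1 (next coarser); the coarsest
    row has no entry.
    """

    raw: np.ndarray
    rounded: np.ndarray


def _check_parameter(parameter: str) -> None:
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5).astype(int) * np.sign(x).astype(int)


def consecutive_percent_diff(table: MeshStudyTable, parameter: str) -> PercentDiffs:
    """Percent difference of each mesh against its next-coarser neighbor.

    Normalized by the larger of the two values and rounded half away from
    zero to the integer percent actually printed in study tables.
    """
    v = table.values(parameter)
    fine, coarse = v[:-1], v[1:]
    denom = np.maximum(fine, coarse)
    if np.any(denom <= 0):
        raise ValueError("percent differences need positive parameter values")
    raw = 100.0 * np.abs(fine - coarse) / denom
    return PercentDiffs(raw=raw, rounded=_round_half_away(raw))


def select_mesh(table: MeshStudyTable, parameter: str,
                threshold_pct: float = 3.0) -> float | None:
    """Coarsest-acceptable element size at the given threshold, or None.

    Scans from the coarsest comparable mesh toward the finest and returns
    the first element size whose (rounded) difference from its next-coarser
    neighbor is within the threshold.
    """
    diffs = consecutive_percent_diff(table, parameter)
    for i in range(len(table.rows) - 2, -1, -1):  # coarse -> fine
        if diffs.rounded[i] <= threshold_pct:
            return table.rows[i].element_size_mm
    return None


def joint_selection(table: MeshStudyTable, parameters,
                    threshold_pct: float = 3.0) -> float | None:
    """Finest of the per-parameter selections (acceptable for every one)."""
    parameters = list(parameters)
    if not parameters:
        raise ValueError("need at least one parameter")
    picks = [select_mesh(table, p, threshold_pct) for p in parameters]
    if any(p is None for p in picks):
        return None
    return min(picks)


@dataclass(frozen=True)
class SensitivityReport:
    family: str
    threshold_pct: float
    percent_diffs: dict      # parameter -> PercentDiffs
    selected: dict           # parameter -> element size (mm) or None
    joint_selected: float | None


def build_report(table: MeshStudyTable, parameters=PARAMETERS,
                 threshold_pct: float = 3.0) -> SensitivityReport:
    parameters = list(parameters)
    diffs = {p: consecutive_percent_diff(table, p) for p in parameters}
    selected = {p: select_mesh(table, p, threshold_pct) for p in parameters}
    return SensitivityReport(
        family=table.family,
        threshold_pct=threshold_pct,
        percent_diffs=diffs,
        selected=selected,
        joint_selected=joint_selection(table, parameters, threshold_pct),
    )


def render_report(report: SensitivityReport, table: MeshStudyTable,
                  fmt: str = "markdown") -> str:
    """Study-table-shaped rendering of a sensitivity report.

    ``fmt`` is one of "markdown", "csv" or "json".  The runtime column is
    omitted when no row carries it.  The JSON form round-trips through
    ``json.loads``.
    """
    params = list(report.percent_diffs)
    n = len(table.rows)
    data: dict = {
        "element_size_mm": [r.element_size_mm for r in table.rows],
        "element_count": [r.element_count for r in table.rows],
    }
    for p in params:
        data[p] = list(table.values(p))
        pct = [int(v) for v in report.percent_diffs[p].rounded] + [None]
        data[f"{p}_pct_diff"] = pd.array(pct, dtype="Int64")
    if any(r.runtime_min is not None for r in table.rows):
        data["runtime_min"] = [r.runtime_min for r in table.rows]
    df = pd.DataFrame(data)
    if fmt == "markdown":
        buf = io.StringIO()
        buf.write(f"Mesh family: {report.family or '(unnamed)'} | "
                  f"threshold {report.threshold_pct:g}%\n")
        buf.write(df.to_string(index=False, na_rep=""))
        buf.write("\nSelected element size per parameter: ")
        buf.write(", ".join(f"{p}={report.selected[p]}" for p in params))
        buf.write(f"; joint={report.joint_selected}\n")
        return buf.getvalue()
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "json":
        payload = {
            "family": report.family,
            "threshold_pct": report.threshold_pct,
            "rows": df.where(pd.notna(df), None).to_dict(orient="records"),
            "selected": report.selected,
            "joint_selected": report.joint_selected,
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    raise ValueError(f"unknown format {fmt!r}")
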
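"""Aortic pressure-waveform morphology and comparison metrics.

A normal central aortic pressure waveform shows seven landmarks: the
initial systolic upstroke, the steep incident rise, the systolic peak, a
late-systolic decline, the incisura (dicrotic notch) marking aortic valve
closure, the diastolic runoff and the end-diastolic pressure.  This module
extracts those landmarks from sampled waveforms and provides the metrics
used to compare waveforms across meshes and against clinical recordings:
mean/max absolute difference, mean absolute percent error, and the
location-to-location pressure difference (delta-P).

Pressure I/O is in mmHg (1 mmHg = 133.322 Pa); comparisons are made on a
common uniform grid (linear interpolation, 1000 points by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "MMHG_TO_PA",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "PressureWaveform",
    "Landmark",
    "WaveformFeatures",
    "extract_features",
    "waveform_difference",
    "percent_error",
    "delta_p",
    "DeltaPResult",
    "systolic_diastolic_table",
]

logger = logging.getLogger(__name__)

MMHG_TO_PA = 133.322


def mmhg_to_pa(p):
    return np.asarray(p, dtype=float) * MMHG_TO_PA


def pa_to_mmhg(p):
    return np.asarray(p, dtype=float) / MMHG_TO_PA


@dataclass(frozen=True)
class PressureWaveform:
    """Sampled pressure waveform over one cardiac cycle.

    ``times`` (s) start at 0 and strictly increase within the period;
    ``pressures`` are mmHg.  ``label`` names the anatomical location.
    """

    times: np.ndarray
    pressures: np.ndarray
    period_T: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")
        if t.size < 16:
            raise ValueError("a pressure waveform needs at least 16 samples")
        if t.size != p.size:
            raise ValueError("times and pressures must have equal length")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if t[-1] > self.period_T * (1 + 1e-12):
            raise ValueError("times must not exceed period_T")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressures must be finite")

    def resample(self, n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
        """Uniform periodic resampling on [0, T) with n points."""
        tg = np.linspace(0.0, self.period_T, n, endpoint=False)
        tp = np.concatenate([self.times, [self.period_T]])
        pp = np.concatenate([self.pressures, [self.pressures[0]]])
        return tg, np.interp(tg, tp, pp)


@dataclass(frozen=True)
class Landmark:
    value: float   # mmHg
    time: float    # s


@dataclass(frozen=True)
class WaveformFeatures:
    systolic_peak: Landmark
    diastolic_min: Landmark
    dicrotic_notch: Landmark | None
    end_diastolic_pressure: float
    pulse_pressure: float
    mean_pressure: float
    upstroke_slope: float  # mmHg/s

    def to_dict(self) -> dict:
        d = {
            "systolic_peak_mmHg": self.systolic_peak.value,
            "systolic_peak_t_s": self.systolic_peak.time,
            "diastolic_min_mmHg": self.diastolic_min.value,
            "diastolic_min_t_s": self.diastolic_min.time,
            "end_diastolic_pressure_mmHg": self.end_diastolic_pressure,
            "pulse_pressure_mmHg": self.pulse_pressure,
            "mean_pressure_mmHg": self.mean_pressure,
            "upstroke_slope_mmHg_per_s": self.upstroke_slope,
        }
        if self.dicrotic_notch is not None:
            d["dicrotic_notch_mmHg"] = self.dicrotic_notch.value
            d["dicrotic_notch_t_s"] = self.dicrotic_notch.time
        return d


def _mean_pressure(w: PressureWaveform) -> float:
    t = np.concatenate([w.times, [w.period_T]])
    p = np.concatenate([w.pressures, [w.pressures[:1]]], axis=None)
    return float(np.trapezoid(p, t) / w.period_T)


def extract_features(w: PressureWaveform, notch_window: float = 0.4,
                     notch_prominence: float = 0.0) -> WaveformFeatures:
    """Locate the morphological landmarks of a pressure waveform.

    The systolic peak is the global maximum, the diastolic minimum the
    global minimum, and the end-diastolic pressure the value at the end of
    the cycle (last sample).  The dicrotic notch is the most prominent local
    minimum within ``(t_peak, t_peak + notch_window * T]``; if no local
    minimum exceeding ``notch_prominence`` (mmHg) exists the notch is
    reported as absent.  A constant waveform yields zero pulse pressure, no
    notch and a logged warning.
    """
    t, p = w.times, w.pressures
    i_max = int(np.argmax(p))
    i_min = int(np.argmin(p))
    peak = Landmark(float(p[i_max]), float(t[i_max]))
    trough = Landmark(float(p[i_min]), float(t[i_min]))
    pulse = peak.value - trough.value
    if pulse == 0.0:
        logger.warning("constant pressure waveform: no landmarks to extract")

    notch = None
    hi = peak.time + notch_window * w.period_T
    sel = np.flatnonzero((t > peak.time) & (t <= hi))
    if pulse > 0.0 and sel.size >= 3:
        seg = p[sel]
        idx, props = find_peaks(-seg, prominence=notch_prominence)
        if idx.size:
            best = idx[int(np.argmax(props["prominences"]))]
            j = sel[best]
            notch = Landmark(float(p[j]), float(t[j]))

    # steepest rising slope ahead of the peak (initial systolic upstroke)
    slope = 0.0
    if i_max > 0:
        d = np.diff(p[: i_max + 1]) / np.diff(t[: i_max + 1])
        if d.size:
            slope = float(np.max(d))
    return WaveformFeatures(
        systolic_peak=peak,
        diastolic_min=trough,
        dicrotic_notch=notch,
        end_diastolic_pressure=float(p[-1]),
        pulse_pressure=float(pulse),
        mean_pressure=_mean_pressure(w),
        upstroke_slope=slope,
    )


def _common_grid(a: PressureWaveform, b: PressureWaveform, n: int):
    if abs(a.period_T - b.period_T) > 1e-3 * max(a.period_T, b.period_T):
        raise ValueError(
            f"waveform periods differ by more than 0.1%: {a.period_T} vs {b.period_T}"
        )
    tg, pa = a.resample(n)
    _, pb = b.resample(n)
    return tg, pa, pb


def waveform_difference(a: PressureWaveform, b: PressureWaveform,
                        n: int = 1000) -> tuple[float, float]:
    """(mean |a-b|, max |a-b|) in mmHg on a common uniform grid."""
    _, pa, pb = _common_grid(a, b, n)
    d = np.abs(pa - pb)
    return float(d.mean()), float(d.max())


def percent_error(sim: PressureWaveform, ref: PressureWaveform,
                  n: int = 1000) -> float:
    """Mean absolute percent error 100*|sim-ref|/ref on the common grid.

    The reference must be strictly positive everywhere (physiological
    pressures in mmHg are).
    """
    _, ps, pr = _common_grid(sim, ref, n)
    if np.any(pr <= 0):
        raise ValueError("reference waveform must be strictly positive")
    return float(np.mean(100.0 * np.abs(ps - pr) / pr))


@dataclass(frozen=True)
class DeltaPResult:
    times: np.ndarray
    dp: np.ndarray       # mmHg, upstream - downstream
    mean_dp: float
    peak_dp: float       # signed value of largest-magnitude difference


def delta_p(upstream: PressureWaveform, downstream: PressureWaveform,
            n: int = 1000) -> DeltaPResult:
    """Pointwise pressure difference upstream - downstream over the cycle."""
    tg, pu, pd_ = _common_grid(upstream, downstream, n)
    dp = pu - pd_
    k = int(np.argmax(np.abs(dp)))
    return DeltaPResult(tg, dp, float(dp.mean()), float(dp[k]))


def systolic_diastolic_table(waveforms: list[PressureWaveform]) -> pd.DataFrame:
    """Systolic (global max) and diastolic (global min) pressure per waveform."""
    if not waveforms:
        raise ValueError("need at least one waveform")
    rows = [
        {
            "label": w.label,
            "systolic_mmHg": float(np.max(w.pressures)),
            "diastolic_mmHg": float(np.min(w.pressures)),
        }
        for w in waveforms
    ]
    return pd.DataFrame(rows, columns=["label", "systolic_mmHg", "diastolic_mmHg"])
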
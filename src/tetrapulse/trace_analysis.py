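"""Pulse-feature extraction from single-cell fluorescence traces.

The trajectory analysis mirrors the standard single-cell p53 workflow:
troughs and peaks are located by a 1-D watershed on a lightly smoothed copy
of the trace, and three features summarize the first pulse of each channel:

* **rise time** — time between the first trough and the first peak;
* **slope** — the maximum signal increase over any 1-h window between that
  trough and peak, expressed per hour and computed on the raw values;
* **max level** — signal at the first peak (baseline-subtracted by default).

Watershed rule: candidate peaks are interior local maxima of the smoothed
trace; a candidate is kept when its prominence — its height above the
higher of the two flanking basins, i.e. the minima separating it from the
nearest strictly higher ground on each side — reaches a configurable
fraction of the trace's global range.  Each kept peak is paired with the
minimum of the trace between the previous kept peak (or the trace start)
and it.  Endpoints are never peaks; ties break toward the earlier
timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import CHANNELS, TraceSet, CellTrace

__all__ = [
    "AnalysisParams",
    "PulseFeatures",
    "smooth",
    "find_peaks_troughs",
    "extract_features",
    "features_table",
    "damping_summary",
    "yfp_rfp_background_ratio",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunables of the trace analysis.

    ``smooth_window`` (odd sample count) controls the moving average used
    for extremum detection only; ``prominence_frac`` is the watershed
    prominence threshold as a fraction of the trace's global range;
    ``slope_window`` is the slope window in minutes (1 h, matching the
    imaging analysis); ``baseline_subtract`` switches the max level between
    peak-minus-trough and the absolute peak value.
    """

    smooth_window: int = 3
    prominence_frac: float = 0.2
    slope_window: float = 60.0
    baseline_subtract: bool = True

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd count >= 1")
        if not 0.0 < self.prominence_frac < 1.0:
            raise ValueError("prominence_frac must be in (0, 1)")
        if self.slope_window <= 0:
            raise ValueError("slope_window must be > 0")


@dataclass
class PulseFeatures:
    """Features of the first pulse of one channel of one cell."""

    trough_time: float
    peak_time: float
    rise_time: float
    slope: float
    max_level: float
    valid: bool

    @classmethod
    def invalid(cls) -> "PulseFeatures":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, False)


def smooth(values, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink symmetrically.

    At distance ``d`` from an edge the window is truncated to the samples
    actually available, so the output has the same length as the input and
    a window of 1 is the identity.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    values = np.asarray(values, dtype=float)
    if window > len(values):
        raise ValueError("window exceeds trace length")
    if window == 1:
        return values.copy()
    half = window // 2
    cumsum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def _candidate_peaks(v: np.ndarray) -> list[int]:
    """Interior local maxima; a flat run counts once, at its first index.

    Runs touching either endpoint are excluded (endpoints are never peaks).
    """
    n = len(v)
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j < n - 1 and v[i] > v[i - 1] and v[i] > v[j + 1]:
            out.append(i)
        i = j + 1
    return out


def _prominence(v: np.ndarray, i: int) -> float:
    """Height of peak ``i`` above the higher of its two flanking basins.

    Each basin is the minimum of the trace between the peak and the nearest
    strictly higher point on that side (or the trace end if none exists).
    """
    h = v[i]
    left_min = h
    j = i - 1
    while j >= 0 and v[j] <= h:
        left_min = min(left_min, v[j])
        j -= 1
    right_min = h
    j = i + 1
    n = len(v)
    while j < n and v[j] <= h:
        right_min = min(right_min, v[j])
        j += 1
    return h - max(left_min, right_min)


def find_peaks_troughs(values, times, params: AnalysisParams | None = None
                       ) -> list[tuple[float, float]]:
    """Watershed trough/peak pairs of a trace, ordered in time.

    Returns ``[(trough_time, peak_time), ...]``; an empty list when no peak
    clears the prominence threshold (e.g. monotone traces, whose only
    maximum sits on an endpoint).
    """
    params = params or AnalysisParams()
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 samples")
    if len(values) != len(times):
        raise ValueError("values and times must have equal length")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ValueError("time grid must be strictly increasing and uniform")

    v = smooth(values, min(params.smooth_window, _odd_floor(len(values))))
    threshold = params.prominence_frac * (v.max() - v.min())
    kept = [i for i in _candidate_peaks(v)
            if _prominence(v, i) >= threshold and _prominence(v, i) > 0]

    pairs = []
    prev = 0
    for p in kept:
        trough = prev + int(np.argmin(v[prev:p]))  # argmin -> earliest tie
        pairs.append((float(times[trough]), float(times[p])))
        prev = p
    return pairs


def _odd_floor(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def extract_features(trace: CellTrace, channel: str,
                     params: AnalysisParams | None = None) -> PulseFeatures:
    """Features of the first pulse of one channel.

    Detection runs on the smoothed trace; rise time, slope and max level
    are evaluated on the raw values at the detected grid points.  When the
    rise is shorter than the slope window, the slope falls back to the
    average rate over the whole rise, expressed per hour.
    """
    params = params or AnalysisParams()
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    values = trace.channel(channel)
    pairs = find_peaks_troughs(values, trace.time, params)
    if not pairs:
        return PulseFeatures.invalid()

    trough_t, peak_t = pairs[0]
    dt = float(trace.time[1] - trace.time[0])
    i_trough = int(round((trough_t - trace.time[0]) / dt))
    i_peak = int(round((peak_t - trace.time[0]) / dt))
    rise = peak_t - trough_t

    w = int(round(params.slope_window / dt))
    if w >= 1 and i_peak - i_trough >= w:
        seg = values[i_trough:i_peak + 1]
        diffs = seg[w:] - seg[:-w]
        slope = float(diffs.max()) / (w * dt / 60.0)
    else:
        slope = (float(values[i_peak] - values[i_trough]) / rise) * 60.0

    max_level = float(values[i_peak])
    if params.baseline_subtract:
        max_level -= float(values[i_trough])
    return PulseFeatures(trough_time=trough_t, peak_time=peak_t,
                         rise_time=rise, slope=slope, max_level=max_level,
                         valid=True)


def features_table(traceset: TraceSet,
                   params: AnalysisParams | None = None) -> pd.DataFrame:
    """Per-cell, per-channel feature table.

    Cells whose channel shows no detectable pulse get ``valid = False`` and
    NaN features; downstream statistics drop them (the count of dropped
    cells is the attrition implied by the ``valid`` column).
    """
    params = params or AnalysisParams()
    rows = []
    for trace in traceset:
        for channel in CHANNELS:
            f = extract_features(trace, channel, params)
            rows.append({
                "cell_id": trace.cell_id,
                "uv_dose": trace.condition.uv_dose,
                "genotype": trace.condition.genotype,
                "arc_status": trace.condition.arc_status,
                "channel": channel,
                "trough_time": f.trough_time,
                "peak_time": f.peak_time,
                "rise_time_min": f.rise_time,
                "slope_per_h": f.slope,
                "max_level": f.max_level,
                "valid": f.valid,
            })
    return pd.DataFrame(rows)


def damping_summary(traceset: TraceSet, reference_dose: float,
                    params: AnalysisParams | None = None) -> pd.DataFrame:
    """Per-condition tetramer/total damping summary.

    For every cell valid in both channels the damping ratio is its max YFP
    feature over its max RFP feature; conditions are summarized by the
    median ratio and, within each (genotype, arc_status) group, normalized
    to the median at ``reference_dose``.
    """
    feats = features_table(traceset, params)
    wide = (feats[feats["valid"]]
            .pivot_table(index=["cell_id", "uv_dose", "genotype", "arc_status"],
                         columns="channel", values="max_level")
            .dropna()
            .reset_index())
    if wide.empty:
        raise ValueError("no cell is valid in both channels")
    wide["ratio"] = wide["YFP"] / wide["RFP"]

    rows = []
    for (dose, genotype, arc), g in wide.groupby(
            ["uv_dose", "genotype", "arc_status"]):
        rows.append({
            "uv_dose": dose, "genotype": genotype, "arc_status": arc,
            "n_cells": len(g),
            "median_max_yfp": float(g["YFP"].median()),
            "median_max_rfp": float(g["RFP"].median()),
            "median_ratio": float(g["ratio"].median()),
        })
    out = pd.DataFrame(rows).sort_values(
        ["genotype", "arc_status", "uv_dose"]).reset_index(drop=True)

    norm = []
    for (genotype, arc), g in out.groupby(["genotype", "arc_status"]):
        ref = g[g["uv_dose"] == reference_dose]
        if ref.empty:
            raise ValueError(
                f"reference dose {reference_dose} absent for "
                f"({genotype}, {arc})")
        norm.append(g["median_ratio"] / float(ref["median_ratio"].iloc[0]))
    out["normalized_ratio"] = pd.concat(norm).sort_index()
    return out


def yfp_rfp_background_ratio(traceset: TraceSet,
                             reference_genotype: str = "L344P"):
    """Per-genotype median YFP/RFP level, normalized to a dark reference.

    The per-cell statistic is the ratio of time-averaged YFP to
    time-averaged RFP; the monomeric L344P mutant (pure complementation
    background) maps to 1 by construction.  Returns ``(summary, per_cell)``
    where ``summary`` is a Series of normalized medians indexed by genotype
    and ``per_cell`` holds each cell's normalized ratio.
    """
    rows = [{"cell_id": t.cell_id, "genotype": t.condition.genotype,
             "ratio": float(np.mean(t.yfp) / np.mean(t.rfp))}
            for t in traceset]
    per_cell = pd.DataFrame(rows)
    if per_cell.empty or reference_genotype not in set(per_cell["genotype"]):
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    ref_median = float(
        per_cell.loc[per_cell["genotype"] == reference_genotype, "ratio"].median())
    per_cell["normalized_ratio"] = per_cell["ratio"] / ref_median
    summary = per_cell.groupby("genotype")["normalized_ratio"].median()
    return summary, per_cell
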
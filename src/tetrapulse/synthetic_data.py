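"""Noisy single-cell trace populations and the long-format trace table.

Cell-to-cell variability is multiplicative and lognormal (positive,
right-skewed, as fluorescence amplitudes are): each cell draws a production
multiplier ``f_beta`` (scales ``beta1``) and a tetramerization multiplier
``f_kt`` (scales ``k_t``), both with mean 1 and configurable coefficient of
variation.  Detection adds independent Gaussian noise per channel and
timepoint; negative noisy values are clipped at zero.

Each cell owns an RNG keyed by ``(seed, condition index, cell index)``, so
enlarging ``n_cells`` or appending conditions never reshuffles the draws of
earlier cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import Condition, KineticParams, simulate_population_grid

__all__ = [
    "PopulationConfig",
    "CellTrace",
    "TraceSet",
    "generate_population",
    "write_traces",
    "read_traces",
]

CSV_COLUMNS = ["cell_id", "uv_dose", "genotype", "arc_status",
               "time_min", "channel", "value"]
CHANNELS = ("RFP", "YFP")


@dataclass(frozen=True)
class PopulationConfig:
    """Study design of one synthetic imaging experiment."""

    conditions: tuple[Condition, ...]
    n_cells: int = 200
    duration: float = 1440.0
    cv_beta: float = 0.3
    cv_kt: float = 0.3
    sigma_add: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cv_beta < 0 or self.cv_kt < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.sigma_add < 0:
            raise ValueError("sigma_add must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class CellTrace:
    """One cell's sampled two-channel trajectory with condition metadata."""

    cell_id: str
    condition: Condition
    time: np.ndarray
    rfp: np.ndarray
    yfp: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        if len(self.rfp) != len(self.time) or len(self.yfp) != len(self.time):
            raise ValueError("channel arrays must match the time grid length")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0)
                        or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9)):
            raise ValueError("time grid must be strictly increasing and uniform")
        if not (np.all(np.isfinite(self.rfp)) and np.all(np.isfinite(self.yfp))):
            raise ValueError("trace values must be finite")

    def channel(self, name: str) -> np.ndarray:
        if name == "RFP":
            return self.rfp
        if name == "YFP":
            return self.yfp
        raise ValueError(f"channel must be one of {CHANNELS}")


@dataclass
class TraceSet:
    """A collection of cell traces plus the provenance of their generation."""

    traces: list[CellTrace]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def conditions(self) -> list[Condition]:
        seen: list[Condition] = []
        for t in self.traces:
            if t.condition not in seen:
                seen.append(t.condition)
        return seen

    def subset(self, **fields) -> "TraceSet":
        """Traces whose condition matches all given fields
        (e.g. ``subset(uv_dose=6, arc_status="present")``)."""
        keep = [t for t in self.traces
                if all(getattr(t.condition, k) == v for k, v in fields.items())]
        return TraceSet(traces=keep, provenance=dict(self.provenance))


def _lognormal_mean_one(rng: np.random.Generator, cv: float) -> float:
    """Lognormal draw with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    s2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))


def generate_population(pop_config: PopulationConfig,
                        params: KineticParams | None = None) -> TraceSet:
    """Generate a seeded population of noisy traces across conditions."""
    params = params or KineticParams()
    traces: list[CellTrace] = []
    for ci, condition in enumerate(pop_config.conditions):
        f_beta = np.empty(pop_config.n_cells)
        f_kt = np.empty(pop_config.n_cells)
        rngs = [np.random.default_rng([pop_config.seed, ci, k])
                for k in range(pop_config.n_cells)]
        for k, rng in enumerate(rngs):
            f_beta[k] = _lognormal_mean_one(rng, pop_config.cv_beta)
            f_kt[k] = _lognormal_mean_one(rng, pop_config.cv_kt)
        t, rfp, yfp = simulate_population_grid(
            params, condition, pop_config.duration, f_beta, f_kt)
        for k, rng in enumerate(rngs):
            noise = rng.normal(0.0, pop_config.sigma_add, size=(2, len(t))) \
                if pop_config.sigma_add > 0 else np.zeros((2, len(t)))
            traces.append(CellTrace(
                cell_id=f"c{ci:02d}_{k:04d}",
                condition=condition,
                time=t.copy(),
                rfp=np.clip(rfp[:, k] + noise[0], 0.0, None),
                yfp=np.clip(yfp[:, k] + noise[1], 0.0, None),
            ))
    provenance = {
        "seed": pop_config.seed,
        "population": {
            "n_cells": pop_config.n_cells,
            "duration": pop_config.duration,
            "cv_beta": pop_config.cv_beta,
            "cv_kt": pop_config.cv_kt,
            "sigma_add": pop_config.sigma_add,
            "conditions": [asdict(c) for c in pop_config.conditions],
        },
        "kinetics": asdict(params),
    }
    return TraceSet(traces=traces, provenance=provenance)


def to_frame(traceset: TraceSet) -> pd.DataFrame:
    """Long-format table of a trace set (one row per cell/time/channel)."""
    frames = []
    for t in traceset:
        n = len(t.time)
        for channel in CHANNELS:
            frames.append(pd.DataFrame({
                "cell_id": t.cell_id,
                "uv_dose": t.condition.uv_dose,
                "genotype": t.condition.genotype,
                "arc_status": t.condition.arc_status,
                "time_min": t.time,
                "channel": channel,
                "value": t.channel(channel),
            }))
    if not frames:
        return pd.DataFrame(columns=CSV_COLUMNS)
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["cell_id", "time_min", "channel"],
                          kind="mergesort").reset_index(drop=True)


def write_traces(traceset: TraceSet, path) -> None:
    """Write a trace set as the long-format CSV table."""
    to_frame(traceset).to_csv(path, index=False, float_format="%.10g")


def read_traces(path) -> TraceSet:
    """Read a long-format trace CSV back into a :class:`TraceSet`.

    Validates the header, numeric values, channel completeness and the
    uniformity of each cell's time grid; errors name the offending row
    (0-based data row, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str})
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(
            f"malformed header: expected {CSV_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        return TraceSet(traces=[], provenance={"source": str(path)})
    for col in ("uv_dose", "time_min", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"non-numeric or missing {col!r} at row {row}")
        df[col] = numeric
    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = int(bad_channel.idxmax())
        raise ValueError(f"unknown channel {df['channel'][row]!r} at row {row}")

    traces = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        for col in ("uv_dose", "genotype", "arc_status"):
            if g[col].nunique() != 1:
                row = int(g.index[0])
                raise ValueError(
                    f"inconsistent {col!r} for cell {cell_id!r} near row {row}")
        condition = Condition(uv_dose=float(g["uv_dose"].iloc[0]),
                              genotype=str(g["genotype"].iloc[0]),
                              arc_status=str(g["arc_status"].iloc[0]))
        wide = g.pivot_table(index="time_min", columns="channel",
                             values="value", aggfunc="first")
        counts = g.groupby(["time_min", "channel"]).size()
        if (counts > 1).any():
            row = int(g.index[0])
            raise ValueError(
                f"duplicate (time, channel) rows for cell {cell_id!r} near row {row}")
        for channel in CHANNELS:
            if channel not in wide.columns or wide[channel].isna().any():
                row = int(g.index[0])
                raise ValueError(
                    f"missing {channel} rows for cell {cell_id!r} near row {row}")
        times = wide.index.to_numpy(dtype=float)
        dt = np.diff(times)
        if len(dt) and (np.any(dt <= 0)
                        or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9)):
            row = int(g.index[0])
            raise ValueError(
                f"non-uniform time grid for cell {cell_id!r} near row {row}")
        traces.append(CellTrace(cell_id=str(cell_id), condition=condition,
                                time=times,
                                rfp=wide["RFP"].to_numpy(dtype=float),
                                yfp=wide["YFP"].to_numpy(dtype=float)))
    return TraceSet(traces=traces, provenance={"source": str(path)})
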
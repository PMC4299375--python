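"""Canned in-silico experiments reproducing the study's qualitative results.

Each function sets up a seeded synthetic experiment with the default study
conditions (doses 3/6/12 J/m^2, n = 200 cells per condition, default noise),
runs the relevant part of the pipeline and returns the summary quantities:
background equivalence of the dark mutants, the constant-slope dissociation
between total and tetrameric p53, dose damping of the tetramer/total ratio,
the ARC-knockdown contrast, mechanism discrimination, and the numerical
validation of the feature extractor, rank-sum test and ODE solver.

Also hosts the independent brute-force reference implementations (exhaustive
extrema scan, bitmask rank-sum enumeration) used to validate the package's
own algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .kinetics import Condition, KineticParams, simulate_cell, tetramer_flux
from .model_fit import (DEFAULT_BOUNDS, condition_mean_traces, fit_model,
                        select_mechanism)
from .stats import mann_whitney_u, slope_conservation_test
from .synthetic_data import PopulationConfig, TraceSet, generate_population
from .trace_analysis import (AnalysisParams, features_table, damping_summary,
                             find_peaks_troughs, smooth,
                             yfp_rfp_background_ratio)

DOSES = (3.0, 6.0, 12.0)
N_CELLS = 200
DURATION = 1440.0


def _child_seed(seed: int, tag: int) -> int:
    """Derive a sub-stream seed below 2**31."""
    return int(np.random.default_rng([seed, tag]).integers(0, 2 ** 31 - 1))


# ---------------------------------------------------------------------------
# reporter background (dark-mutant) equivalence
# ---------------------------------------------------------------------------

def background_equivalence(seed: int, dose: float = 6.0,
                           n_cells: int = N_CELLS) -> dict:
    """Normalized YFP/RFP level of WT vs oligomerization mutants post-UV.

    Dimeric (L344A) and monomeric (L344P) mutants both leave the split
    fluorophore dark, so their normalized ratios should be statistically
    indistinguishable, while WT forms tetramers and separates sharply.
    """
    conditions = [Condition(dose, genotype=g) for g in ("WT", "L344A", "L344P")]
    cfg = PopulationConfig(conditions=tuple(conditions), n_cells=n_cells,
                           duration=DURATION, seed=_child_seed(seed, 1))
    ts = generate_population(cfg)
    summary, per_cell = yfp_rfp_background_ratio(ts, reference_genotype="L344P")

    def ratios(genotype):
        return per_cell.loc[per_cell["genotype"] == genotype,
                            "normalized_ratio"].to_numpy()

    p_mutants = mann_whitney_u(ratios("L344A"), ratios("L344P")).p_two_sided
    p_wt = mann_whitney_u(ratios("WT"), ratios("L344P")).p_two_sided
    return {
        "p_l344a_vs_l344p": p_mutants,
        "p_wt_vs_l344p": p_wt,
        "median_ratio_l344a": float(summary["L344A"]),
        "median_ratio_wt": float(summary["WT"]),
        "n_per_genotype": n_cells,
    }


# ---------------------------------------------------------------------------
# dose sweeps: slopes, rise times, damping
# ---------------------------------------------------------------------------

def dose_sweep(seed: int, arc_status: str = "present",
               doses=DOSES, n_cells: int = N_CELLS) -> TraceSet:
    """Simulate the WT dose-response experiment for one ARC status."""
    conditions = tuple(Condition(d, arc_status=arc_status) for d in doses)
    cfg = PopulationConfig(conditions=conditions, n_cells=n_cells,
                           duration=DURATION,
                           seed=_child_seed(seed, 2 if arc_status == "present"
                                            else 3))
    return generate_population(cfg)


def slope_dissociation(seed: int, traceset: TraceSet | None = None) -> dict:
    """Dose dependence of slope and rise time per channel (ARC present).

    The expectation under the throttle: total p53 (RFP) accumulates faster
    at higher dose while the tetramer (YFP) slope stays put; rise times
    grow with dose in both channels.
    """
    ts = traceset if traceset is not None else dose_sweep(seed)
    feats = features_table(ts)
    out: dict = {"doses": DOSES}
    for channel in ("RFP", "YFP"):
        rep = slope_conservation_test(feats, channel, seed=_child_seed(seed, 4))
        med = np.array(rep.median_slopes)
        rise = [float(feats[(feats["channel"] == channel) & feats["valid"]
                            & (feats["uv_dose"] == d)]["rise_time_min"].median())
                for d in rep.doses]
        out[channel] = {
            "median_slopes": rep.median_slopes,
            "slope_sems": rep.sems,
            "p_low_vs_high": rep.p_value,
            "conserved": rep.conserved,
            "slope_variation_frac": float((med.max() - med.min()) / med.max()),
            "median_rise_times": tuple(rise),
        }
    return out


def damping(seed: int, throttle_ts: TraceSet | None = None,
            knockdown_ts: TraceSet | None = None,
            reference_dose: float = DOSES[0]) -> dict:
    """Normalized median max-YFP/max-RFP ratio across doses, both ARC states."""
    ts_on = throttle_ts if throttle_ts is not None else dose_sweep(seed)
    ts_kd = knockdown_ts if knockdown_ts is not None else \
        dose_sweep(seed, arc_status="knockdown")
    out = {}
    for name, ts in (("throttle", ts_on), ("knockdown", ts_kd)):
        summary = damping_summary(ts, reference_dose=reference_dose)
        summary = summary.sort_values("uv_dose")
        out[name] = {
            "doses": tuple(summary["uv_dose"]),
            "normalized_ratios": tuple(summary["normalized_ratio"]),
        }
    return out


def knockdown_contrast(seed: int, dose: float = 6.0,
                       knockdown_ts: TraceSet | None = None,
                       present_ts: TraceSet | None = None) -> dict:
    """ARC knockdown vs control at one dose, plus slope conservation loss.

    Total p53 (RFP) max level and slope should be unaffected by knockdown
    while tetramer (YFP) slope and max increase, and the across-dose
    tetramer slope conservation should break.
    """
    ts_kd = knockdown_ts if knockdown_ts is not None else \
        dose_sweep(seed, arc_status="knockdown")
    ts_on = present_ts if present_ts is not None else dose_sweep(seed)
    feats_kd = features_table(ts_kd.subset(uv_dose=dose))
    feats_on = features_table(ts_on.subset(uv_dose=dose))

    def col(feats, channel, column):
        sub = feats[(feats["channel"] == channel) & feats["valid"]]
        return sub[column].to_numpy()

    out = {"dose": dose}
    for channel, key in (("RFP", "rfp"), ("YFP", "yfp")):
        for column, tag in (("max_level", "max"), ("slope_per_h", "slope")):
            r = mann_whitney_u(col(feats_kd, channel, column),
                               col(feats_on, channel, column))
            out[f"p_{key}_{tag}"] = r.p_two_sided
            out[f"median_{key}_{tag}_knockdown"] = float(
                np.median(col(feats_kd, channel, column)))
            out[f"median_{key}_{tag}_present"] = float(
                np.median(col(feats_on, channel, column)))
    rep = slope_conservation_test(features_table(ts_kd), "YFP",
                                  seed=_child_seed(seed, 5))
    out["p_kd_slope_conservation"] = rep.p_value
    out["kd_yfp_slope_conserved"] = rep.conserved
    return out


# ---------------------------------------------------------------------------
# feature-extraction validation
# ---------------------------------------------------------------------------

def triangular_pulse_features(params: AnalysisParams | None = None) -> dict:
    """Analytic check: linear rise 0->12 a.u. over 240 min, symmetric fall."""
    from .synthetic_data import CellTrace
    dt = 15.0
    up = np.arange(0.0, 240.0 + dt, dt) * (12.0 / 240.0)
    down = up[-2::-1]
    values = np.concatenate([up, down])
    times = np.arange(len(values)) * dt
    trace = CellTrace(cell_id="triangle", condition=Condition(0.0),
                      time=times, rfp=values, yfp=values)
    from .trace_analysis import extract_features
    f = extract_features(trace, "RFP", params)
    return {"rise_time_min": f.rise_time, "slope_per_h": f.slope,
            "max_level": f.max_level, "valid": f.valid}


def reference_extrema_scan(values, times,
                           params: AnalysisParams | None = None):
    """Exhaustive reference extrema detector (validation oracle).

    Independently re-derives trough/peak pairs by scanning every interior
    index with numpy primitives: a peak is the first index of any flat run
    higher than both flanking values whose prominence (height above the
    higher flanking basin, basins delimited by the nearest strictly higher
    point) reaches the threshold; each peak pairs with the earliest minimum
    since the previous peak.
    """
    params = params or AnalysisParams()
    v = smooth(np.asarray(values, dtype=float),
               min(params.smooth_window,
                   len(values) if len(values) % 2 else len(values) - 1))
    times = np.asarray(times, dtype=float)
    n = len(v)
    threshold = params.prominence_frac * (v.max() - v.min())
    peaks = []
    for i in range(1, n - 1):
        if not v[i] > v[i - 1]:
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j >= n - 1 or v[j + 1] >= v[i]:
            continue
        higher_left = np.nonzero(v[:i] > v[i])[0]
        lo = higher_left[-1] + 1 if len(higher_left) else 0
        left_base = v[lo:i].min()
        higher_right = np.nonzero(v[i + 1:] > v[i])[0]
        hi = i + 1 + higher_right[0] if len(higher_right) else n
        right_base = v[i + 1:hi].min() if hi > i + 1 else v[i]
        prominence = v[i] - max(left_base, right_base)
        if prominence >= threshold and prominence > 0:
            peaks.append(i)
    pairs = []
    prev = 0
    for p in peaks:
        trough = prev + int(np.argmin(v[prev:p]))
        pairs.append((float(times[trough]), float(times[p])))
        prev = p
    return pairs


def watershed_agreement(seed: int, n_traces: int = 1000,
                        max_len: int = 200) -> dict:
    """Fraction of random traces where watershed matches the exhaustive scan."""
    rng = np.random.default_rng(_child_seed(seed, 6))
    params = AnalysisParams()
    agree = 0
    for _ in range(n_traces):
        n = int(rng.integers(3, max_len + 1))
        kind = rng.integers(0, 3)
        if kind == 0:
            v = rng.normal(0, 1, n).cumsum()
        elif kind == 1:
            t = np.linspace(0, 1, n)
            v = np.zeros(n)
            for _ in range(int(rng.integers(1, 4))):
                c, w, a = rng.uniform(0, 1), rng.uniform(0.02, 0.3), rng.uniform(0.5, 3)
                v += a * np.exp(-0.5 * ((t - c) / w) ** 2)
            v += rng.normal(0, 0.05, n)
        else:
            v = rng.integers(0, 4, n).astype(float)  # plateaus and ties
        times = np.arange(n) * 15.0
        if find_peaks_troughs(v, times, params) == \
                reference_extrema_scan(v, times, params):
            agree += 1
    return {"agreement_frac": agree / n_traces, "n_traces": n_traces}


# ---------------------------------------------------------------------------
# rank-sum validation
# ---------------------------------------------------------------------------

def reference_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by direct pairwise enumeration.

    Independently of the rank-based implementation: for every subset of the
    pooled values taken as group 1, U is counted as the number of (x, y)
    pairs won plus half the ties.
    """
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n, n1 = len(pooled), len(x)

    def u_of(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return float((a[:, None] > b[None, :]).sum()
                     + 0.5 * (a[:, None] == b[None, :]).sum())

    u_obs = u_of(range(n1))
    us = np.array([u_of(idx) for idx in combinations(range(n), n1)])
    lo = float((us <= u_obs + 1e-9).mean())
    hi = float((us >= u_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(lo, hi))


def rank_sum_validation(seed: int, n_null: int = 2000,
                        n_per_group: int = 20) -> dict:
    """Exact-vs-oracle agreement and null rejection rate of the U test."""
    rng = np.random.default_rng(_child_seed(seed, 7))
    max_diff = 0.0
    for n1 in range(1, 10):
        for n2 in range(1, 10 - n1 + 1):
            for _ in range(4):
                x = np.round(rng.normal(0, 1, n1), 1)  # rounding forces ties
                y = np.round(rng.normal(0, 1, n2), 1)
                p_impl = mann_whitney_u(x, y).p_two_sided
                p_ref = reference_rank_sum_p(x, y)
                max_diff = max(max_diff, abs(p_impl - p_ref))
    rejections = 0
    for _ in range(n_null):
        x = rng.normal(0, 1, n_per_group)
        y = rng.normal(0, 1, n_per_group)
        if mann_whitney_u(x, y).p_two_sided < 0.05:
            rejections += 1
    return {"max_exact_oracle_diff": max_diff,
            "null_rejection_rate": rejections / n_null,
            "n_null": n_null}


# ---------------------------------------------------------------------------
# mechanism discrimination
# ---------------------------------------------------------------------------

def mechanism_recovery(seed: int, n_replicates: int = 50,
                       n_cells: int = N_CELLS, fit_dt: float = 1.0) -> dict:
    """Replicate mechanism-selection experiment plus flux-ceiling recovery.

    For each generating mechanism (throttle / ARC knockdown mass action),
    ``n_replicates`` synthetic datasets are simulated at the default study
    conditions, condition means are fitted by both mechanisms, and the AIC
    choice is recorded.  The flux ceiling ``k_t*K_A`` is recovered from a
    separate noiseless throttle dataset.
    """
    params = KineticParams()
    correct = {"throttle": 0, "mass_action": 0}
    for truth, arc in (("throttle", "present"), ("mass_action", "knockdown")):
        for rep in range(n_replicates):
            cfg = PopulationConfig(
                conditions=tuple(Condition(d, arc_status=arc) for d in DOSES),
                n_cells=n_cells, duration=DURATION,
                seed=_child_seed(seed, 1000 + 2 * rep + (truth == "throttle")))
            ts = generate_population(cfg, params)
            sel = select_mechanism(condition_mean_traces(ts), params,
                                   DEFAULT_BOUNDS, seed=seed, fit_dt=fit_dt)
            if sel.selected_model == truth:
                correct[truth] += 1

    # noiseless means for parameter recovery in the saturation regime
    cfg = PopulationConfig(
        conditions=tuple(Condition(d) for d in DOSES), n_cells=1,
        duration=DURATION, cv_beta=0.0, cv_kt=0.0, sigma_add=0.0,
        seed=_child_seed(seed, 8))
    ts = generate_population(cfg, params)
    fit = fit_model(condition_mean_traces(ts), "throttle", params,
                    DEFAULT_BOUNDS, seed=seed, fit_dt=fit_dt)
    product_true = params.k_t * params.K_A
    product_fit = fit.estimates["k_t"] * fit.estimates["K_A"]
    return {
        "throttle_selected_frac": correct["throttle"] / n_replicates,
        "mass_action_selected_frac": correct["mass_action"] / n_replicates,
        "n_replicates": n_replicates,
        "flux_ceiling_true": product_true,
        "flux_ceiling_fit": product_fit,
        "flux_ceiling_rel_error": abs(product_fit - product_true) / product_true,
        "noiseless_rss": fit.rss,
    }


# ---------------------------------------------------------------------------
# solver fidelity
# ---------------------------------------------------------------------------

def solver_fidelity(dose: float = 6.0, duration: float = 720.0,
                    refine: int = 100) -> dict:
    """RK4 vs 100x-finer reference, and conservation with sources/sinks off."""
    params = KineticParams()
    cond = Condition(dose)
    coarse = simulate_cell(params, cond, duration)
    fine = simulate_cell(params, cond, duration,
                         dt_solver=params.dt_solver / refine)
    rel = 0.0
    for channel in ("rfp", "yfp"):
        a, b = getattr(coarse, channel), getattr(fine, channel)
        rel = max(rel, float(np.max(np.abs(a - b)) / np.max(np.abs(b))))

    cons_params = params.with_(beta0=0.0, beta1=0.0, delta_D=0.0, delta_Q=0.0)
    traj = simulate_cell(cons_params, cond, 300.0, initial_state=(10.0, 1.0))
    total = 2.0 * traj.dimers + 4.0 * traj.tetramers
    cons_dev = float(np.max(np.abs(total - total[0])) / total[0])
    return {"max_rel_deviation": rel, "conservation_rel_deviation": cons_dev,
            "dose": dose, "duration": duration}


# ---------------------------------------------------------------------------
# throttle-regime flux property (used by kinetics tests)
# ---------------------------------------------------------------------------

def mean_rising_flux(dose: float, arc_status: str = "present",
                     duration: float = DURATION) -> float:
    """Time-averaged tetramer flux from UV to the tetramer peak."""
    params = KineticParams()
    cond = Condition(dose, arc_status=arc_status)
    traj = simulate_cell(params, cond, duration)
    peak = int(np.argmax(traj.tetramers))
    flux = tetramer_flux(traj.dimers[:peak + 1], params, arc_status)
    return float(np.mean(flux))
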
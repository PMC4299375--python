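"""Kinetic model of p53 dimer/tetramer dynamics after UV damage.

The model tracks two species per cell: the pool of p53 homo-dimers ``D``
(formed co-translationally, so no monomer species is tracked) and the pool of
tetramers ``Q`` ("dimers of dimers").  UV damage transiently elevates dimer
production; dimers combine pairwise into tetramers through a flux that is
either saturable (an ARC-like "throttle" that caps the flux at ``k_t * K_A``
regardless of how large the dimer pool grows) or pure mass action
(``k_t * D**2``, the ARC-knockdown limit ``K_A -> inf``).

    dD/dt = beta(t; dose) - delta_D * D - 2 * J(D)
    dQ/dt = J(D) - delta_Q * Q
    J(D)  = k_t * D**2 / (1 + D**2 / K_A)

Two fluorescence observables are derived from the state.  The RFP channel
tags every monomer, so it reports total p53 (``2 D + 4 Q`` monomer
equivalents); the YFP channel is a split-fluorophore complementation signal
that lights up only on tetramers, plus a small unspecific-complementation
bleed proportional to total p53 and an autofluorescence offset:

    RFP = alpha * (2 D + 4 Q) + c_R
    YFP = gamma * Q + b * alpha * (2 D + 4 Q) + c

Oligomerization mutants (L344A dimeric, L344P monomeric, M340E/L344K) never
form tetramers: their tetramer flux is zero and YFP carries only bleed and
offset.  The reconstituted fluorophore is irreversible, so YFP decays only
through degradation of the tetramer pool (rate ``delta_Q``), never by
complex dissociation.

Integration is fixed-step classical RK4.  The production envelope is
piecewise constant in time; the integrator splits every step at the envelope
breakpoints so each RK4 step sees a smooth right-hand side and the scheme
retains its full order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np

__all__ = [
    "GENOTYPES",
    "ARC_STATUSES",
    "KineticParams",
    "Condition",
    "CellTrajectory",
    "production_rate",
    "tetramer_flux",
    "steady_state",
    "simulate_cell",
    "simulate_population_grid",
]

GENOTYPES = ("WT", "L344A", "L344P", "M340E_L344K")
#: genotypes whose tetramerization flux is forced to zero
NON_TETRAMERIZING = ("L344A", "L344P", "M340E_L344K")
ARC_STATUSES = ("present", "knockdown")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants, reporter gains and solver settings.

    All abundances are in arbitrary units (a.u.); time is in minutes.

    Parameters
    ----------
    beta0
        Basal dimer production (a.u./min).
    beta1
        Dose gain of dimer production (a.u./min per J/m^2).
    tau0, tau1
        Base duration of the damage signal (min) and its dose gain
        (min per J/m^2): production stays elevated for ``tau0 + tau1*dose``.
    delta_D, delta_Q
        First-order degradation rates of dimers and tetramers (1/min).
    k_t
        Tetramerization rate constant (1/(a.u. min)).
    K_A
        Throttle capacity (a.u.^2).  ``math.inf`` disables the throttle
        (ARC knockdown); finite values cap the flux at ``k_t * K_A``.
    alpha
        RFP gain per monomer equivalent.
    gamma
        YFP gain per tetramer.
    b
        Unspecific-complementation bleed fraction (YFP picks up
        ``b * alpha * total``).
    c, c_R
        Autofluorescence offsets of the YFP and RFP channels.
    dt_solver, dt_sample
        RK4 step and output sampling interval (min).
    """

    beta0: float = 0.002
    beta1: float = 1.0
    tau0: float = 180.0
    tau1: float = 20.0
    delta_D: float = 0.02
    delta_Q: float = 0.02
    k_t: float = 0.01
    K_A: float = 1.0
    alpha: float = 0.2
    gamma: float = 200.0
    b: float = 0.001
    c: float = 5.0
    c_R: float = 5.0
    dt_solver: float = 0.1
    dt_sample: float = 15.0

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "tau0", "tau1", "delta_D", "delta_Q",
                     "k_t", "alpha", "gamma", "b", "c", "c_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"KineticParams.{name} must be >= 0")
        if not self.K_A > 0:  # math.inf is allowed and means "no throttle"
            raise ValueError("KineticParams.K_A must be > 0 (or inf)")
        if self.dt_solver <= 0 or self.dt_sample <= 0:
            raise ValueError("solver and sampling steps must be > 0")
        if self.dt_solver > self.dt_sample:
            raise ValueError("dt_solver must not exceed dt_sample")

    def with_(self, **kwargs) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one simulated cell population."""

    uv_dose: float
    genotype: str = "WT"
    arc_status: str = "present"

    def __post_init__(self) -> None:
        if self.uv_dose < 0:
            raise ValueError("uv_dose must be >= 0")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.arc_status not in ARC_STATUSES:
            raise ValueError(f"arc_status must be one of {ARC_STATUSES}")

    @property
    def tetramerizes(self) -> bool:
        return self.genotype not in NON_TETRAMERIZING


@dataclass
class CellTrajectory:
    """Noiseless sampled trajectory of a single cell (or one column of a batch)."""

    time: np.ndarray
    rfp: np.ndarray
    yfp: np.ndarray
    dimers: np.ndarray
    tetramers: np.ndarray
    condition: Condition | None = None


def production_rate(t, dose: float, params: KineticParams):
    """Dimer production rate beta(t; dose) in a.u./min.

    Production is ``beta0 + beta1*dose`` while the damage signal lasts
    (``0 <= t <= tau0 + tau1*dose``) and ``beta0`` otherwise, so both the
    amplitude and the duration of the elevated phase grow with UV dose.
    Accepts scalar or array ``t``.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    tau_end = params.tau0 + params.tau1 * dose
    elevated = (t >= 0.0) & (t <= tau_end)
    rate = np.where(elevated, params.beta0 + params.beta1 * dose, params.beta0)
    return rate if rate.ndim else float(rate)


def tetramer_flux(D, params: KineticParams, arc_status: str = "present"):
    """Tetramer formation flux J(D) in a.u./min.

    With ARC present the flux saturates: ``J = k_t D^2 / (1 + D^2/K_A)``,
    approaching the cap ``k_t*K_A`` once the squared dimer pool dwarfs the
    throttle capacity.  Under knockdown (or ``K_A = inf``) it reverts to mass
    action ``J = k_t D^2``.  Accepts scalar or array ``D``.
    """
    if arc_status not in ARC_STATUSES:
        raise ValueError(f"arc_status must be one of {ARC_STATUSES}")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("D must be >= 0")
    D2 = D * D
    if arc_status == "knockdown" or math.isinf(params.K_A):
        J = params.k_t * D2
    else:
        J = params.k_t * D2 / (1.0 + D2 / params.K_A)
    return J if J.ndim else float(J)


def _flux_vec(D, kt_eff, inv_KA):
    """Vectorized flux with per-column rate constants; ``inv_KA = 1/K_A``
    (0 for the mass-action limit)."""
    D2 = D * D
    return kt_eff * D2 / (1.0 + D2 * inv_KA)


def steady_state(params: KineticParams, condition: Condition,
                 kt_scale=1.0):
    """Pre-damage steady state (D*, Q*) at dose 0.

    Solves ``beta0 = delta_D*D + 2*J(D)`` by bisection (the left side is
    constant, the right side strictly increasing, so the root is unique) and
    balances the tetramer pool at ``Q* = J(D*)/delta_Q``.
    """
    kt_scale = np.atleast_1d(np.asarray(kt_scale, dtype=float))
    kt_eff = params.k_t * kt_scale
    if not condition.tetramerizes:
        kt_eff = np.zeros_like(kt_eff)
    inv_KA = 0.0 if (condition.arc_status == "knockdown"
                     or math.isinf(params.K_A)) else 1.0 / params.K_A
    if params.beta0 == 0.0:
        D = np.zeros_like(kt_eff)
        Q = np.zeros_like(kt_eff)
        return D, Q
    if params.delta_D <= 0:
        raise ValueError("steady state requires delta_D > 0 when beta0 > 0")
    lo = np.zeros_like(kt_eff)
    hi = np.full_like(kt_eff, params.beta0 / params.delta_D)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        excess = params.beta0 - params.delta_D * mid - 2.0 * _flux_vec(mid, kt_eff, inv_KA)
        lo = np.where(excess > 0, mid, lo)
        hi = np.where(excess > 0, hi, mid)
    D = 0.5 * (lo + hi)
    J = _flux_vec(D, kt_eff, inv_KA)
    if np.any(J > 0) and params.delta_Q <= 0:
        raise ValueError("steady state requires delta_Q > 0 when tetramers form")
    Q = J / params.delta_Q if params.delta_Q > 0 else np.zeros_like(D)
    return D, Q


def _rk4_segment(D, Q, rate, kt_eff, inv_KA, delta_D, delta_Q, t0, t1, dt):
    """Advance (D, Q) from t0 to t1 with RK4; ``rate`` constant in time."""
    span = t1 - t0
    n_sub = max(1, int(math.ceil(span / dt - 1e-9)))
    h = span / n_sub

    def rhs(D, Q):
        J = _flux_vec(D, kt_eff, inv_KA)
        return rate - delta_D * D - 2.0 * J, J - delta_Q * Q

    for _ in range(n_sub):
        k1D, k1Q = rhs(D, Q)
        k2D, k2Q = rhs(D + 0.5 * h * k1D, Q + 0.5 * h * k1Q)
        k3D, k3Q = rhs(D + 0.5 * h * k2D, Q + 0.5 * h * k2Q)
        k4D, k4Q = rhs(D + h * k3D, Q + h * k3Q)
        D = D + (h / 6.0) * (k1D + 2.0 * k2D + 2.0 * k3D + k4D)
        Q = Q + (h / 6.0) * (k1Q + 2.0 * k2Q + 2.0 * k3Q + k4Q)
    return D, Q


def _rk4_segment_scalar(D, Q, rate, kt, inv_KA, dD, dQ, t0, t1, dt):
    """Scalar fast path of :func:`_rk4_segment` (plain floats, no arrays)."""
    span = t1 - t0
    n_sub = max(1, int(math.ceil(span / dt - 1e-9)))
    h = span / n_sub
    h6 = h / 6.0
    for _ in range(n_sub):
        D2 = D * D
        J = kt * D2 / (1.0 + D2 * inv_KA)
        k1D = rate - dD * D - 2.0 * J
        k1Q = J - dQ * Q
        x = D + 0.5 * h * k1D
        y = Q + 0.5 * h * k1Q
        D2 = x * x
        J = kt * D2 / (1.0 + D2 * inv_KA)
        k2D = rate - dD * x - 2.0 * J
        k2Q = J - dQ * y
        x = D + 0.5 * h * k2D
        y = Q + 0.5 * h * k2Q
        D2 = x * x
        J = kt * D2 / (1.0 + D2 * inv_KA)
        k3D = rate - dD * x - 2.0 * J
        k3Q = J - dQ * y
        x = D + h * k3D
        y = Q + h * k3Q
        D2 = x * x
        J = kt * D2 / (1.0 + D2 * inv_KA)
        k4D = rate - dD * x - 2.0 * J
        k4Q = J - dQ * y
        D = D + h6 * (k1D + 2.0 * k2D + 2.0 * k3D + k4D)
        Q = Q + h6 * (k1Q + 2.0 * k2Q + 2.0 * k3Q + k4Q)
    return D, Q


def _integrate(params: KineticParams, dose: float, duration: float,
               beta_hi, tau_end, kt_eff, inv_KA,
               D0, Q0, dt_solver: float, nonfinite: str = "raise"):
    """Integrate the ODE on the sampling grid.

    ``beta_hi``, ``tau_end``, ``kt_eff`` may be per-column arrays (all
    broadcast against each other); ``inv_KA`` is scalar or per-column.
    Returns (sample_times, D, Q) with state arrays of shape
    (n_samples, n_columns).  ``nonfinite="nan"`` marks diverging columns
    with NaN instead of raising (used by the batched fitter, where a stiff
    corner of the search box is a skippable candidate, not an error).
    """
    n_samp = int(round(duration / params.dt_sample))
    sample_times = np.arange(n_samp + 1) * params.dt_sample

    beta_hi = np.atleast_1d(np.asarray(beta_hi, dtype=float))
    tau_end = np.atleast_1d(np.asarray(tau_end, dtype=float))
    kt_eff = np.atleast_1d(np.asarray(kt_eff, dtype=float))
    inv_KA = np.asarray(inv_KA, dtype=float)
    m = int(np.broadcast_shapes(beta_hi.shape, tau_end.shape, kt_eff.shape,
                                np.atleast_1d(inv_KA).shape)[0])
    beta_hi = np.broadcast_to(beta_hi, (m,))
    tau_end = np.broadcast_to(tau_end, (m,))

    # split every inter-sample interval at the production-envelope breakpoints
    # so each RK4 step integrates a smooth right-hand side
    breaks = set(np.unique(tau_end[(tau_end > 0) & (tau_end < duration)]))
    grid = sorted(set(sample_times.tolist()) | breaks)

    scalar = (m == 1 and np.ndim(inv_KA) == 0)
    if scalar:
        D, Q = float(np.atleast_1d(D0)[0]), float(np.atleast_1d(Q0)[0])
        kt_s, inv_s = float(kt_eff[0]), float(inv_KA)
        bhi, tend = float(beta_hi[0]), float(tau_end[0])
    else:
        D = np.broadcast_to(np.atleast_1d(np.asarray(D0, dtype=float)), (m,)).copy()
        Q = np.broadcast_to(np.atleast_1d(np.asarray(Q0, dtype=float)), (m,)).copy()

    out_D = np.empty((n_samp + 1, m))
    out_Q = np.empty((n_samp + 1, m))
    out_D[0] = D
    out_Q[0] = Q

    next_sample = 1
    for t0, t1 in zip(grid[:-1], grid[1:]):
        mid = 0.5 * (t0 + t1)
        if scalar:
            rate = bhi if mid <= tend else params.beta0
            D, Q = _rk4_segment_scalar(D, Q, rate, kt_s, inv_s,
                                       params.delta_D, params.delta_Q,
                                       t0, t1, dt_solver)
            if not (math.isfinite(D) and math.isfinite(Q)):
                raise ArithmeticError(
                    f"ODE solver produced non-finite state at t={t1:g} min")
        else:
            rate = np.where(mid <= tau_end, beta_hi, params.beta0)
            with np.errstate(over="ignore", invalid="ignore"):
                D, Q = _rk4_segment(D, Q, rate, kt_eff, inv_KA,
                                    params.delta_D, params.delta_Q,
                                    t0, t1, dt_solver)
            bad = ~(np.isfinite(D) & np.isfinite(Q))
            if bad.any():
                if nonfinite == "raise":
                    raise ArithmeticError(
                        f"ODE solver produced non-finite state at t={t1:g} min")
                D = np.where(bad, np.nan, D)
                Q = np.where(bad, np.nan, Q)
        if next_sample <= n_samp and abs(t1 - sample_times[next_sample]) < 1e-9:
            out_D[next_sample] = D
            out_Q[next_sample] = Q
            next_sample += 1
    return sample_times, out_D, out_Q


def observables(D, Q, params: KineticParams):
    """Map state to (RFP, YFP) fluorescence."""
    total = 2.0 * D + 4.0 * Q
    rfp = params.alpha * total + params.c_R
    yfp = params.gamma * Q + params.b * params.alpha * total + params.c
    return rfp, yfp


def simulate_cell(params: KineticParams, condition: Condition,
                  duration: float, beta_scale: float = 1.0,
                  kt_scale: float = 1.0,
                  initial_state: tuple[float, float] | None = None,
                  dt_solver: float | None = None) -> CellTrajectory:
    """Simulate one cell's noiseless two-channel trajectory.

    ``beta_scale`` and ``kt_scale`` are per-cell multipliers on the
    dose-dependent production gain ``beta1`` and on ``k_t``.  The initial
    state defaults to the pre-damage steady state; pass ``initial_state``
    to start elsewhere (used e.g. for conservation checks).
    """
    _check_duration(duration, params)
    dt = params.dt_solver if dt_solver is None else dt_solver
    dose = condition.uv_dose
    if dose < 0:
        raise ValueError("dose must be >= 0")

    kt_eff = params.k_t * kt_scale if condition.tetramerizes else 0.0
    inv_KA = 0.0 if (condition.arc_status == "knockdown"
                     or math.isinf(params.K_A)) else 1.0 / params.K_A
    beta_hi = params.beta0 + params.beta1 * beta_scale * dose
    tau_end = params.tau0 + params.tau1 * dose

    if initial_state is None:
        D0, Q0 = steady_state(params, condition, kt_scale=kt_scale)
        D0, Q0 = float(D0[0]), float(Q0[0])
    else:
        D0, Q0 = float(initial_state[0]), float(initial_state[1])

    t, D, Q = _integrate(params, dose, duration, beta_hi, tau_end,
                         kt_eff, inv_KA, D0, Q0, dt)
    D, Q = D[:, 0], Q[:, 0]
    rfp, yfp = observables(D, Q, params)
    return CellTrajectory(time=t, rfp=rfp, yfp=yfp, dimers=D, tetramers=Q,
                          condition=condition)


def simulate_population_grid(params: KineticParams, condition: Condition,
                             duration: float, beta_scales: np.ndarray,
                             kt_scales: np.ndarray,
                             dt_solver: float | None = None):
    """Vectorized batch of noiseless trajectories for one condition.

    Returns (times, rfp, yfp) with channel arrays of shape
    (n_samples, n_cells).  Used by the population generator and the fitter.
    """
    _check_duration(duration, params)
    dt = params.dt_solver if dt_solver is None else dt_solver
    beta_scales = np.asarray(beta_scales, dtype=float)
    kt_scales = np.asarray(kt_scales, dtype=float)
    kt_eff = params.k_t * kt_scales
    if not condition.tetramerizes:
        kt_eff = np.zeros_like(kt_eff)
    inv_KA = 0.0 if (condition.arc_status == "knockdown"
                     or math.isinf(params.K_A)) else 1.0 / params.K_A
    beta_hi = params.beta0 + params.beta1 * beta_scales * condition.uv_dose
    tau_end = np.full_like(beta_hi, params.tau0 + params.tau1 * condition.uv_dose)
    D0, Q0 = steady_state(params, condition, kt_scale=kt_scales)
    t, D, Q = _integrate(params, condition.uv_dose, duration, beta_hi,
                         tau_end, kt_eff, np.asarray(inv_KA), D0, Q0, dt)
    rfp, yfp = observables(D, Q, params)
    return t, rfp, yfp


def _check_duration(duration: float, params: KineticParams) -> None:
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = duration / params.dt_sample
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration must be a multiple of dt_sample")
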
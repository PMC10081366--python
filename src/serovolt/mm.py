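"""Dual-uptake Michaelis-Menten model of evoked serotonin release.

The extracellular concentration C(t) obeys

    dC/dt = R(t) (1 - A(t))
            - alpha * Vmax1 * C / (Km1 + C)
            - beta  * Vmax2 * C / (Km2 + C)

where R(t) is the evoked release rate during/after the stimulation train,
A(t) an autoreceptor-occupancy factor in [0, 1) that throttles release as
extracellular serotonin rises, and the two saturable clearance terms are
Uptake 1 (serotonin transporters: high affinity, low capacity; Km1, Vmax1)
and Uptake 2 (DAT/NET/OCT/PMAT: low affinity, high capacity; Km2, Vmax2).
alpha and beta are dimensionless weights of the two routes, fixed to 1 by
default and excluded from fitting (they are non-identifiable multipliers of
the Vmax values).

The equation is integrated with the explicit Euler method on a fine grid and
resampled to the 10 Hz acquisition grid.  Fitting minimises the RMSE between
model and measured trace with a finite-difference gradient descent in
log-parameter space (positivity by construction) with backtracking line
search and seeded multi-start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .datatypes import (ConcentrationTrace, IntegrationError,
                        StimulationProtocol, ValidationError,
                        FSCV_SWEEP_RATE_HZ)

__all__ = [
    "MMParams", "MMFitResult", "CONTROL_PARAMS", "uptake_rate", "release_rate",
    "simulate", "steady_state", "fit", "scenario_traces", "param_ratios",
    "FITTABLE_PARAMS",
]

logger = logging.getLogger(__name__)

try:  # numba accelerates the Euler stepping kernel when present
    from numba import njit as _njit
except ImportError:  # pragma: no cover - exercised only without numba
    _njit = None


def _euler_core_py(R, C0, dt, v1, k1, v2, k2,
                   a_max, a_ec50_h, a_hill, delay_steps):
    """Sequential Euler stepping; returns (C, clamp_count, bad_step)."""
    n = R.shape[0]
    C = np.empty(n)
    C[0] = C0
    clamps = 0
    for i in range(n - 1):
        c = C[i]
        if not math.isfinite(c):
            return C, clamps, i
        a = 0.0
        if a_max > 0.0:
            j = i - delay_steps
            if j < 0:
                j = 0
            c_del = C[j]
            if c_del > 0.0:
                ch = c_del ** a_hill
                a = a_max * ch / (a_ec50_h + ch)
        upt = v1 * c / (k1 + c) + v2 * c / (k2 + c)
        c_next = c + dt * (R[i] * (1.0 - a) - upt)
        if c_next < 0.0:
            clamps += 1
            c_next = 0.0
        C[i + 1] = c_next
    return C, clamps, -1


_euler_core = _njit(cache=True)(_euler_core_py) if _njit else _euler_core_py

#: Parameter names the RMSE fitter may vary (alpha/beta deliberately absent).
FITTABLE_PARAMS = ("R_max", "tau_on", "tau_off",
                   "K_m1", "V_max1", "K_m2", "V_max2")


@dataclass(frozen=True)
class MMParams:
    """Parameters of the dual-uptake model.

    Release envelope: R(t) = R_max * (1 - exp(-(t - t_on)/tau_on)) while the
    stimulus is on, then exponential relaxation with time constant tau_off.
    Autoreceptor term: delayed Hill function of concentration,
    A(t) = A_max * C(t - A_delay)^h / (A_ec50^h + C(t - A_delay)^h),
    off by default (A_max = 0).

    Units: concentrations nM, rates nM/s, times s.
    """

    R_max: float = 250.0          # peak evoked release rate, nM/s
    tau_on: float = 0.3           # release rise time constant, s
    tau_off: float = 0.3          # release decay time constant, s
    A_max: float = 0.0            # maximal autoreceptor occupancy, [0, 1)
    A_ec50: float = 60.0          # half-occupancy concentration, nM
    A_hill: float = 2.0           # Hill coefficient
    A_delay: float = 0.5          # autoreceptor feedback delay, s
    alpha: float = 1.0            # Uptake 1 weight
    beta: float = 1.0             # Uptake 2 weight
    V_max1: float = 12.0          # SERT capacity, nM/s
    K_m1: float = 2.0             # SERT affinity, nM
    V_max2: float = 780.0         # Uptake 2 capacity, nM/s
    K_m2: float = 170.0           # Uptake 2 affinity, nM
    C0: float = 0.0               # initial concentration, nM

    def __post_init__(self) -> None:
        for name in ("R_max", "tau_on", "tau_off", "A_ec50", "A_delay",
                     "V_max1", "K_m1", "V_max2", "K_m2", "C0",
                     "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.A_max < 1.0:
            raise ValidationError("A_max must lie in [0, 1)")

    def with_updates(self, **kwargs: float) -> "MMParams":
        return replace(self, **kwargs)


#: Control-state parameterisation used throughout (evoked hippocampal
#: serotonin): Km1 = 2 nM, Vmax1 = 12 nM/s, Km2 = 170 nM, Vmax2 = 780 nM/s.
CONTROL_PARAMS = MMParams()


def uptake_rate(C: float | np.ndarray, params: MMParams) -> float | np.ndarray:
    """Total clearance rate at concentration ``C`` (nM/s).

    Sum of the two saturable terms; 0 at C = 0, strictly increasing in C and
    bounded above by alpha*Vmax1 + beta*Vmax2.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValidationError("concentration must be >= 0")
    rate = (params.alpha * params.V_max1 * C / (params.K_m1 + C)
            + params.beta * params.V_max2 * C / (params.K_m2 + C))
    return float(rate) if rate.ndim == 0 else rate


def release_rate(t: np.ndarray, params: MMParams,
                 stim_start: float, stim_end: float) -> np.ndarray:
    """Evoked release envelope R(t) (nM/s) for times ``t``.

    Smooth boxcar: saturating rise with time constant tau_on while the
    stimulus is on, then exponential decay with tau_off from the value
    reached at stimulus end.  Zero before the stimulus and for zero-duration
    trains.
    """
    t = np.asarray(t, dtype=float)
    R = np.zeros_like(t)
    if stim_end <= stim_start:
        return R
    on = (t >= stim_start) & (t <= stim_end)
    if params.tau_on > 0:
        R[on] = params.R_max * (1.0 - np.exp(-(t[on] - stim_start) / params.tau_on))
        R_end = params.R_max * (1.0 - math.exp(-(stim_end - stim_start) / params.tau_on))
    else:
        R[on] = params.R_max
        R_end = params.R_max
    after = t > stim_end
    if params.tau_off > 0:
        R[after] = R_end * np.exp(-(t[after] - stim_end) / params.tau_off)
    return R


def simulate(params: MMParams, protocol: StimulationProtocol,
             dt: float = 0.01, duration: float = 30.0,
             stim_start: float = 5.0) -> ConcentrationTrace:
    """Explicit-Euler forward solution, resampled to the 10 Hz grid.

    The stimulation train starts at ``stim_start`` (a pre-stimulation
    baseline segment is required downstream for amplitude detection).
    Concentration is clamped at 0 with a logged event if an Euler step
    undershoots; a non-finite state raises :class:`IntegrationError` naming
    the offending step.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if duration < protocol.duration_s:
        raise ValidationError("duration must cover the stimulation train")
    stim_end = stim_start + protocol.duration_s
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    R = release_rate(t, params, stim_start, stim_end)
    delay_steps = int(round(params.A_delay / dt)) if params.A_max > 0 else 0
    ec50_h = params.A_ec50 ** params.A_hill if params.A_max > 0 else 1.0
    C, clamp_events, bad_step = _euler_core(
        R, params.C0, dt,
        params.alpha * params.V_max1, params.K_m1,
        params.beta * params.V_max2, params.K_m2,
        params.A_max, ec50_h, params.A_hill, delay_steps)
    if bad_step >= 0:
        raise IntegrationError(
            f"non-finite concentration at step {bad_step} "
            f"(t = {t[bad_step]:.4f} s); reduce dt")
    if clamp_events:
        logger.debug("Euler solution clamped at 0 on %d step(s)", clamp_events)
    # nearest-step lookup onto the 10 Hz acquisition grid
    t10 = np.arange(0.0, duration + 1e-9, 1.0 / FSCV_SWEEP_RATE_HZ)
    idx = np.clip(np.round(t10 / dt).astype(int), 0, n - 1)
    return ConcentrationTrace(
        t10, C[idx], stim_start_s=stim_start, stim_end_s=stim_end,
        metadata={"params": params, "dt": dt, "clamp_events": clamp_events,
                  "protocol": protocol})


def steady_state(R_const: float, params: MMParams) -> float:
    """Concentration at which total clearance balances a constant release.

    Analytic root of ``uptake_rate(C) = R_const``: a quadratic when both
    uptake routes are active.  Requires ``R_const`` below the total clearance
    capacity alpha*Vmax1 + beta*Vmax2.
    """
    if R_const < 0:
        raise ValidationError("release rate must be >= 0")
    cap = params.alpha * params.V_max1 + params.beta * params.V_max2
    if R_const >= cap:
        raise ValidationError(
            f"no steady state: release {R_const} nM/s >= clearance capacity "
            f"{cap} nM/s")
    if R_const == 0:
        return 0.0
    v1 = params.alpha * params.V_max1
    v2 = params.beta * params.V_max2
    k1, k2 = params.K_m1, params.K_m2
    if v2 == 0:
        return R_const * k1 / (v1 - R_const)
    if v1 == 0:
        return R_const * k2 / (v2 - R_const)
    # (v1+v2-R) C^2 + (v1 k2 + v2 k1 - R(k1+k2)) C - R k1 k2 = 0
    a = v1 + v2 - R_const
    b = v1 * k2 + v2 * k1 - R_const * (k1 + k2)
    c = -R_const * k1 * k2
    disc = b * b - 4.0 * a * c
    return float((-b + math.sqrt(disc)) / (2.0 * a))


@dataclass
class MMFitResult:
    """Outcome of an RMSE fit of the dual-uptake model to a trace."""

    fitted: MMParams
    rmse: float
    iterations: int
    converged: bool
    frozen: frozenset[str] = field(default_factory=frozenset)
    ratios_vs_control: dict[str, float] | None = None

    @property
    def free(self) -> tuple[str, ...]:
        return tuple(p for p in FITTABLE_PARAMS if p not in self.frozen)


def _rmse(params: MMParams, trace: ConcentrationTrace,
          protocol: StimulationProtocol, dt: float) -> float:
    sim = simulate(params, protocol, dt=dt,
                   duration=float(trace.time_s[-1]),
                   stim_start=float(trace.stim_start_s))
    n = min(sim.concentration_nM.size, trace.concentration_nM.size)
    diff = sim.concentration_nM[:n] - trace.concentration_nM[:n]
    return float(np.sqrt(np.mean(diff * diff)))


def fit(trace: ConcentrationTrace, protocol: StimulationProtocol,
        init: MMParams, frozen: Iterable[str] = (),
        *, dt: float = 0.01, rel_tol: float = 1e-6, max_iter: int = 10_000,
        n_starts: int = 5, jitter_sd: float = 0.2, seed: int = 0,
        control: "MMFitResult | None" = None) -> MMFitResult:
    """Fit the free parameters by RMSE gradient descent with multi-start.

    Gradients are finite differences in log-parameter space (positivity by
    construction); steps use a backtracking (Armijo) line search.  Descent
    stops when the relative RMSE improvement falls below ``rel_tol`` or after
    ``max_iter`` iterations.  ``n_starts`` seeded log-normal jitters of the
    initial guess guard against the cost surface's local minima; the best
    final RMSE wins.

    If ``control`` is supplied the post/control parameter ratios are attached
    to the result.
    """
    frozen = frozenset(frozen)
    unknown = frozen - set(FITTABLE_PARAMS)
    if unknown:
        raise ValidationError(f"unknown frozen parameter(s): {sorted(unknown)}")
    free = [p for p in FITTABLE_PARAMS if p not in frozen]
    if not free:
        raise ValidationError("all parameters frozen: nothing to fit")
    if trace.stim_start_s is None:
        raise ValidationError("trace must carry a stimulation annotation")

    rng = np.random.default_rng(seed)

    def params_from_theta(theta: np.ndarray) -> MMParams:
        return init.with_updates(**{p: math.exp(v) for p, v in zip(free, theta)})

    def cost(theta: np.ndarray) -> float:
        return _rmse(params_from_theta(theta), trace, protocol, dt)

    theta0 = np.array([math.log(max(getattr(init, p), 1e-9)) for p in free])
    starts = [theta0] + [theta0 + rng.normal(0.0, jitter_sd, size=theta0.size)
                         for _ in range(max(0, n_starts - 1))]

    best_theta, best_cost, best_iters, best_conv = theta0, cost(theta0), 0, False
    h = 1e-5
    for start in starts:
        theta = start.copy()
        f = cost(theta)
        step = 0.1
        converged = False
        it = 0
        while it < max_iter:
            it += 1
            grad = np.empty_like(theta)
            for j in range(theta.size):
                tp = theta.copy()
                tp[j] += h
                grad[j] = (cost(tp) - f) / h
            gnorm = float(np.linalg.norm(grad))
            if gnorm < 1e-12:
                converged = True
                break
            d = -grad / gnorm
            t_step, f_new = step, None
            for _ in range(30):
                cand = cost(theta + t_step * d)
                if cand < f - 1e-4 * t_step * gnorm:
                    f_new = cand
                    break
                t_step *= 0.5
            if f_new is None:
                converged = True  # no descent direction at resolvable step
                break
            improvement = (f - f_new) / max(f_new, 1e-15)
            theta = theta + t_step * d
            f = f_new
            step = min(t_step * 2.0, 1.0)
            if improvement < rel_tol:
                converged = True
                break
        if f < best_cost or (f == best_cost and not best_conv):
            best_theta, best_cost, best_iters, best_conv = theta, f, it, converged
    fitted = params_from_theta(best_theta)
    result = MMFitResult(fitted=fitted, rmse=best_cost, iterations=best_iters,
                         converged=best_conv, frozen=frozen)
    if control is not None:
        result.ratios_vs_control = param_ratios(result, control)
    return result


def scenario_traces(control: MMParams, protocol: StimulationProtocol,
                    *, dt: float = 0.01, duration: float = 30.0,
                    stim_start: float = 5.0) -> dict[str, ConcentrationTrace]:
    """Forward simulations of the three canonical uptake-inhibition scenarios.

    - ``km2_x10``: competitive Uptake 2 inhibition, Km2 tenfold control;
    - ``km1_x10``: competitive Uptake 1 (SERT) inhibition, Km1 tenfold;
    - ``km1_x10_vmax1_x0.5``: Uptake 1 inhibition with Km1 tenfold and Vmax1
      halved (the escitalopram-like scenario).

    Each perturbation slows clearance, so every scenario trace has a longer
    half-life than the control simulation.
    """
    kw = dict(dt=dt, duration=duration, stim_start=stim_start)
    scenarios = {
        "km2_x10": control.with_updates(K_m2=10.0 * control.K_m2),
        "km1_x10": control.with_updates(K_m1=10.0 * control.K_m1),
        "km1_x10_vmax1_x0.5": control.with_updates(
            K_m1=10.0 * control.K_m1, V_max1=0.5 * control.V_max1),
    }
    return {name: simulate(p, protocol, **kw) for name, p in scenarios.items()}


def param_ratios(post: MMFitResult, control: MMFitResult) -> dict[str, float]:
    """Post-drug / control parameter ratios (ratio 1 for frozen parameters)."""
    if post.frozen != control.frozen:
        raise ValidationError("post and control fits must share a frozen set")
    ratios: dict[str, float] = {}
    for name in FITTABLE_PARAMS:
        if name in post.frozen:
            ratios[name] = 1.0
            continue
        denom = getattr(control.fitted, name)
        if denom == 0:
            raise ValidationError(f"control {name} is 0: ratio undefined")
        ratios[name] = getattr(post.fitted, name) / denom
    return ratios
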
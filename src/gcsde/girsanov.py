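"""Change of measure removing the drift of the GC-content process.

With the integrating-factor transform ``Y_t = e^{-(a-b) t} F_t`` the SDE
reduces to ``dY = b e^{-(a-b) t} dt + c(t) e^{-(a-b) t} dB_t``.  Choosing
the deterministic drift

    u(t) = b / c(t)

and the exponential martingale

    M_T = exp( -int_0^T u dB  -  1/2 int_0^T u^2 ds )

defines, by the Girsanov theorem, a measure ``Q`` (``dQ = M_T dP``) under
which ``B~_t = B_t + int_0^t u ds`` is a Brownian motion and
``dY = c(t) e^{-(a-b) t} dB~``: the reweighted GC process has no drift —
GC content is just as likely to increase as to decrease.  The Novikov
condition ``E[exp(1/2 int u^2 ds)] < oo`` holds automatically for
deterministic bounded ``u``, i.e. whenever ``c`` is bounded away from 0.

``u`` requires the reciprocal ``1/c(t)``, so the construction demands a
strictly positive schedule; monotonicity of ``c`` (the invertibility
framing) is advisory metadata and only produces a warning.  Weights are
kept in log space since ``int u^2 ds`` can be large for small ``c``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import (
    GridError,
    PerturbationSchedule,
    RateParameters,
    ScheduleDomainError,
    TimeGrid,
    TrajectoryEnsemble,
)
from .sde_sim import simulate_em

logger = logging.getLogger("gcsde")

__all__ = [
    "MeasureChange",
    "DriftlessReport",
    "girsanov_drift",
    "novikov_check",
    "radon_nikodym_weights",
    "validate_driftless",
]

#: log-scale overflow guard: exp(x) for x above this is reported as inf.
_EXP_OVERFLOW = 700.0


@dataclass
class MeasureChange:
    """Tabulated drift, per-path log weights and the Novikov diagnostic."""

    u_values: np.ndarray
    log_weights: np.ndarray
    novikov_value: float
    grid: TimeGrid

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_weights)):
            raise ScheduleDomainError("non-finite log Radon-Nikodym weights")

    @property
    def weights(self) -> np.ndarray:
        """Per-path weights ``M_T`` (stable shifted exponentiation)."""
        shift = self.log_weights.max()
        return np.exp(self.log_weights - shift) * math.exp(min(shift, _EXP_OVERFLOW))


@dataclass
class DriftlessReport:
    """Outcome of the drift-removal validation experiment.

    ``weighted_mean`` estimates ``E_Q[Y_T - Y_0]`` (zero if the change of
    measure removed the drift); ``unweighted_mean`` estimates the
    original drift ``E_P[Y_T - Y_0] = int_0^T b e^{-(a-b) s} ds``.
    Standard errors are Monte-Carlo; ``is_driftless`` applies the 4-SE
    rule to the weighted estimate.
    """

    weighted_mean: float
    weighted_se: float
    unweighted_mean: float
    unweighted_se: float
    expected_p_drift: float
    mean_weight: float
    mean_weight_se: float
    novikov_value: float
    n_paths: int

    @property
    def is_driftless(self) -> bool:
        return abs(self.weighted_mean) < 4.0 * self.weighted_se

    @property
    def p_drift_detected(self) -> bool:
        """True when the unweighted ensemble shows a significant drift."""
        return abs(self.unweighted_mean) > 4.0 * self.unweighted_se


def girsanov_drift(
    params: RateParameters, sched: PerturbationSchedule, grid: TimeGrid
) -> np.ndarray:
    """Deterministic drift ``u(t) = b / c(t)`` tabulated on the grid.

    Raises :class:`ScheduleDomainError` naming the first offending time
    if ``c`` vanishes (or is negative) anywhere on the grid.  Emits a
    warning when the schedule is not flagged monotonic — the classical
    invertibility framing — but proceeds, since only positivity is
    needed to form the reciprocal.
    """
    times = grid.times
    c_vals = sched.values(times)
    bad = np.flatnonzero(c_vals <= 0)
    if bad.size:
        t_bad = times[bad[0]]
        raise ScheduleDomainError(
            f"Girsanov drift u = b/c undefined: c({t_bad:g}) = "
            f"{c_vals[bad[0]]:g} (schedule must be strictly positive on the grid)"
        )
    if sched.is_monotonic == "none" and not sched.is_constant:
        warnings.warn(
            "schedule is not flagged monotonic; the drift removal only "
            "needs c(t) > 0, but the monotone-c interpretation does not apply",
            RuntimeWarning,
            stacklevel=2,
        )
    return params.b / c_vals


def novikov_check(u_values: np.ndarray, grid: TimeGrid) -> float:
    """Novikov diagnostic ``exp(1/2 int_0^T u(s)^2 ds)`` for deterministic u.

    The integral is a trapezoid over the tabulated values.  Returns
    ``math.inf`` when the exponent overflows (condition violated /
    integral divergent at the grid's resolution).
    """
    u = np.asarray(u_values, dtype=float)
    if u.shape != grid.times.shape:
        raise GridError(
            f"u_values shape {u.shape} does not match grid ({grid.times.shape})"
        )
    if not np.all(np.isfinite(u)):
        raise ScheduleDomainError("non-finite drift values")
    exponent = 0.5 * float(np.trapezoid(u * u, grid.times))
    if exponent > _EXP_OVERFLOW:
        logger.warning(
            "Novikov exponent %.3g overflows; reporting inf (condition fails "
            "at this resolution)", exponent,
        )
        return math.inf
    return math.exp(exponent)


def radon_nikodym_weights(
    ensemble: TrajectoryEnsemble | np.ndarray,
    u_values: np.ndarray,
    grid: TimeGrid,
) -> np.ndarray:
    """Per-path ``log M_T = -sum_i u(s_i) dB_i - 1/2 sum_i u(s_i)^2 ds``.

    ``ensemble`` is either an Euler-Maruyama :class:`TrajectoryEnsemble`
    (its stored driving Brownian increments are used) or a raw increment
    array of shape ``(n_paths, n_steps)``.  The sample mean of
    ``exp(log M_T)`` converges to 1 (martingale normalisation).
    """
    if isinstance(ensemble, TrajectoryEnsemble):
        if ensemble.method != "euler_maruyama":
            raise GridError(
                "Radon-Nikodym reweighting needs the driving Brownian "
                f"increments; the '{ensemble.method}' scheme does not store them"
            )
        if ensemble.increments is None:
            raise GridError("ensemble does not carry its driving increments")
        dB = ensemble.increments
    else:
        dB = np.asarray(ensemble, dtype=float)
    u = np.asarray(u_values, dtype=float)
    if u.shape != grid.times.shape:
        raise GridError(
            f"u_values shape {u.shape} does not match grid ({grid.times.shape})"
        )
    if dB.ndim != 2 or dB.shape[1] != grid.n_steps:
        raise GridError(
            f"increments shape {dB.shape} does not match grid "
            f"(expected (n_paths, {grid.n_steps}))"
        )
    u_left = u[:-1]  # Ito: left-endpoint evaluation
    log_w = -(dB @ u_left) - 0.5 * float(np.sum(u_left * u_left)) * grid.dt
    return log_w


def validate_driftless(
    params: RateParameters,
    sched: PerturbationSchedule,
    grid: TimeGrid,
    n_paths: int,
    seed: int,
) -> DriftlessReport:
    """Monte-Carlo check that the reweighted GC process has no drift.

    Simulates ``F`` under the physical measure by Euler-Maruyama, forms
    ``Y_t = e^{-(a-b) t} F_t``, reweights the terminal displacement
    ``Y_T - Y_0`` by the Radon-Nikodym weights and reports both weighted
    and unweighted drift estimates with Monte-Carlo standard errors.
    The closed-form original drift ``int_0^T b e^{-(a-b) s} ds`` is
    included for reference.
    """
    u = girsanov_drift(params, sched, grid)
    novikov = novikov_check(u, grid)
    ens = simulate_em(params, sched, grid, n_paths, seed)
    log_w = radon_nikodym_weights(ens, u, grid)
    mc = MeasureChange(u_values=u, log_weights=log_w, novikov_value=novikov, grid=grid)
    w = mc.weights

    lam = params.rate_gap
    y = np.exp(-lam * grid.times)[np.newaxis, :] * ens.values
    dy = y[:, -1] - y[:, 0]

    sqrt_n = math.sqrt(n_paths)
    weighted = w * dy
    if params.is_degenerate:
        expected_p_drift = params.b * grid.t_end
    else:
        expected_p_drift = params.b * (1.0 - math.exp(-lam * grid.t_end)) / lam
    return DriftlessReport(
        weighted_mean=float(weighted.mean()),
        weighted_se=float(weighted.std(ddof=1) / sqrt_n) if n_paths > 1 else 0.0,
        unweighted_mean=float(dy.mean()),
        unweighted_se=float(dy.std(ddof=1) / sqrt_n) if n_paths > 1 else 0.0,
        expected_p_drift=expected_p_drift,
        mean_weight=float(w.mean()),
        mean_weight_se=float(w.std(ddof=1) / sqrt_n) if n_paths > 1 else 0.0,
        novikov_value=novikov,
        n_paths=n_paths,
    )
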
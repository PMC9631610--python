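"""Stochastic path simulation of the GC-content SDE.

Two schemes are provided and serve as mutual oracles:

* :func:`simulate_em` — Euler-Maruyama time stepping of
  ``dF = (a F + b (1 - F)) dt + c(t) dB``.  The diffusion coefficient is
  state-independent, so EM already has strong order 1.0 here.
* :func:`simulate_exact` — samples the explicit solution

      F_t = -b/(a-b) + (F0 + b/(a-b)) e^{(a-b) t}
            + int_0^t c(s) e^{(a-b)(t-s)} dB_s

  step by step: deterministic propagation over each interval plus a
  Gaussian increment whose variance is the local Ito-isometry integral.
  Its marginals match the closed forms exactly in distribution at any
  step count.

:func:`stochastic_integral` discretises the Brownian-motion term alone,
``sum_i c(s_i) e^{(a-b)(t - s_i)} dB_i`` with left-endpoint (Ito,
non-anticipating) evaluation of the integrand and
``dB_i ~ Normal(0, ds)``.  A debug flag reproduces the literal
"white noise times ds" reading of the discretisation for comparison; it
does not recover the Ito-isometry variance and exists only to document
that fact.

Randomness: one master seed spawns an independent stream per path
(``numpy.random.SeedSequence.spawn``), so enlarging ``n_paths`` never
changes earlier paths.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .model_core import (
    GridError,
    ParameterError,
    PerturbationSchedule,
    RateParameters,
    TimeGrid,
    TrajectoryEnsemble,
)

__all__ = [
    "brownian_increments",
    "simulate_em",
    "simulate_exact",
    "stochastic_integral",
]

#: Half-width of the clamp applied when ``clamp=True``: paths are kept in
#: [eps, 1 - eps].
CLAMP_EPS = 1e-6

#: Gauss-Legendre order for the per-step local variance integrals of the
#: exact scheme (c is smooth on each small step in all supported cases).
_LOCAL_QUAD_ORDER = 20


def _validate(grid: TimeGrid, n_paths: int) -> None:
    if not isinstance(grid, TimeGrid):
        raise GridError(f"grid must be a TimeGrid, got {type(grid).__name__}")
    if grid.n_steps < 1:
        raise GridError("grid must contain at least one step")
    if n_paths < 1:
        raise ParameterError(f"n_paths must be >= 1, got {n_paths}")


def brownian_increments(grid: TimeGrid, n_paths: int, seed: int) -> np.ndarray:
    """Draw ``dB_i ~ Normal(0, ds)``, shape ``(n_paths, n_steps)``.

    Path ``i`` is generated from the ``i``-th child stream of
    ``SeedSequence(seed)``; the first ``m`` rows are identical for every
    ``n_paths >= m``.
    """
    _validate(grid, n_paths)
    children = np.random.SeedSequence(seed).spawn(n_paths)
    out = np.empty((n_paths, grid.n_steps))
    scale = np.sqrt(grid.dt)
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        out[i] = rng.standard_normal(grid.n_steps)
    out *= scale
    return out


def simulate_em(
    params: RateParameters,
    sched: PerturbationSchedule,
    grid: TimeGrid,
    n_paths: int,
    seed: int,
    clamp: bool = False,
    increments: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble of GC-fraction paths.

    Each path follows
    ``F_{i+1} = F_i + (a F_i + b (1 - F_i)) ds + c(s_i) dB_i`` with the
    schedule evaluated at the left endpoint.  By default paths may exit
    (0, 1); the ensemble records per-path first-exit flags.  With
    ``clamp=True`` the state is restricted to ``[1e-6, 1 - 1e-6]`` after
    every step (this biases comparisons against the closed forms and is
    off by default).  Pre-drawn Brownian increments of shape
    ``(n_paths, n_steps)`` may be supplied to couple ensembles across
    grids; otherwise they are drawn from ``seed``.
    """
    _validate(grid, n_paths)
    if increments is None:
        dB = brownian_increments(grid, n_paths, seed)
    else:
        dB = np.asarray(increments, dtype=float)
        if dB.shape != (n_paths, grid.n_steps):
            raise GridError(
                f"increments shape {dB.shape} does not match "
                f"({n_paths}, {grid.n_steps})"
            )
    times = grid.times
    dt = grid.dt
    c_left = sched.values(times[:-1])
    a, b = params.a, params.b
    values = np.empty((n_paths, grid.n_steps + 1))
    values[:, 0] = params.F0
    state = values[:, 0].copy()
    exited = np.zeros(n_paths, dtype=bool)
    for i in range(grid.n_steps):
        state = state + (a * state + b * (1.0 - state)) * dt + c_left[i] * dB[:, i]
        if clamp:
            np.clip(state, CLAMP_EPS, 1.0 - CLAMP_EPS, out=state)
        exited |= (state <= 0.0) | (state >= 1.0)
        values[:, i + 1] = state
    return TrajectoryEnsemble(
        grid=grid, values=values, seed=seed, method="euler_maruyama",
        quantity="gc_fraction", increments=dB, exit_flags=exited,
    )


def _local_noise_variances(
    params: RateParameters, sched: PerturbationSchedule, grid: TimeGrid
) -> np.ndarray:
    """Per-step variances int_{s_i}^{s_{i+1}} c(s)^2 e^{2(a-b)(s_{i+1}-s)} ds."""
    lam2 = 2.0 * params.rate_gap
    times = grid.times
    out = np.empty(grid.n_steps)
    for i in range(grid.n_steps):
        lo, hi = times[i], times[i + 1]
        val, _ = integrate.fixed_quad(
            lambda s: np.asarray(sched.c(s), dtype=float) ** 2
            * np.exp(lam2 * (hi - s)),
            lo, hi, n=_LOCAL_QUAD_ORDER,
        )
        out[i] = max(float(val), 0.0)
    return out


def simulate_exact(
    params: RateParameters,
    sched: PerturbationSchedule,
    grid: TimeGrid,
    n_paths: int,
    seed: int,
    clamp: bool = False,
) -> TrajectoryEnsemble:
    """Sample the explicit solution of the linear SDE on the grid.

    The recursion propagates the deterministic part exactly over each
    step and adds an independent centred Gaussian whose variance is the
    local Ito-isometry integral, so the marginal law at every grid time
    is exact regardless of step count.  The stored ``increments`` are
    these integrated noise terms (not raw Brownian increments).
    """
    _validate(grid, n_paths)
    lam = params.rate_gap
    dt = grid.dt
    decay = np.exp(lam * dt)
    if params.is_degenerate:
        drift_const = params.b * dt  # F grows linearly when a = b
    else:
        eq = params.equilibrium_gc
        drift_const = eq * (1.0 - decay)
    local_sd = np.sqrt(_local_noise_variances(params, sched, grid))

    children = np.random.SeedSequence(seed).spawn(n_paths)
    noise = np.empty((n_paths, grid.n_steps))
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        noise[i] = rng.standard_normal(grid.n_steps)
    noise *= local_sd[np.newaxis, :]

    values = np.empty((n_paths, grid.n_steps + 1))
    values[:, 0] = params.F0
    state = values[:, 0].copy()
    exited = np.zeros(n_paths, dtype=bool)
    for i in range(grid.n_steps):
        state = state * decay + drift_const + noise[:, i]
        if clamp:
            np.clip(state, CLAMP_EPS, 1.0 - CLAMP_EPS, out=state)
        exited |= (state <= 0.0) | (state >= 1.0)
        values[:, i + 1] = state
    return TrajectoryEnsemble(
        grid=grid, values=values, seed=seed, method="exact",
        quantity="gc_fraction", increments=noise, exit_flags=exited,
    )


def stochastic_integral(
    params: RateParameters,
    sched: PerturbationSchedule,
    grid: TimeGrid,
    n_paths: int,
    seed: int,
    increments: np.ndarray | None = None,
    literal_ds_factor: bool = False,
) -> np.ndarray:
    """Per-path discretisation of ``int_0^T c(s) e^{(a-b)(T-s)} dB_s``.

    Returns ``sum_i c(s_i) e^{(a-b)(T - s_i)} dB_i`` (one value per
    path).  Across paths the sample is Gaussian with mean 0 and variance
    converging to the Ito-isometry integral as the grid refines.

    Parameters
    ----------
    increments
        Optional pre-drawn Brownian increments of shape
        ``(n_paths, n_steps)``; drawn from ``seed`` when omitted.
    literal_ds_factor
        Debug-only: additionally multiply each term by ``ds``, the
        literal reading of the printed discretisation formula.  This
        double-counts the time step, collapses the variance by a factor
        ``ds`` and is provided purely for comparison.
    """
    _validate(grid, n_paths)
    if increments is None:
        increments = brownian_increments(grid, n_paths, seed)
    elif increments.shape != (n_paths, grid.n_steps):
        raise GridError(
            f"increments shape {increments.shape} does not match "
            f"({n_paths}, {grid.n_steps})"
        )
    times = grid.times
    weights = sched.values(times[:-1]) * np.exp(
        params.rate_gap * (grid.t_end - times[:-1])
    )
    if literal_ds_factor:
        weights = weights * grid.dt
    return increments @ weights
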
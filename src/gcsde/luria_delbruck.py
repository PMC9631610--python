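"""Stochastic Luria-Delbruck mutation model via geometric Brownian growth.

A population growing at stochastic rate ``k + p W_t`` follows geometric
Brownian motion; multiplying by the per-capita mutation rate ``mu`` gives
the instantaneous mutation count

    M_t = P_t mu = P_0 mu exp( (k - p^2/2) t + p B_t ) ,

the Ito-calculus analogue of the classical fluctuation-experiment model:
the ensemble mean grows like ``P_0 mu e^{k t}`` while individual
trajectories fluctuate lognormally, increasingly so as ``k`` approaches
``p^2 / 2``.  Mutation counts here are real-valued intensities, not
integers; :func:`poisson_counts` is an optional extension that draws
integer counts around the continuous intensities for fluctuation-style
analyses.

Splitting by Chargaff parity, the count decomposes into AT and GC parts,
``M = M_AT + M_GC`` with ``M_GC = |g alpha F|`` and
``M_AT = |g beta (1 - F)|`` for genome size ``g`` and GC fraction ``F``
(the moduli make the decomposition insensitive to rate signs).
Cumulative mutation load is the pathwise Lebesgue integral
``int_0^t M_s ds``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .model_core import (
    GridError,
    ParameterError,
    TimeGrid,
    TrajectoryEnsemble,
)

__all__ = [
    "GrowthParameters",
    "MutationCounts",
    "simulate_mutations",
    "decompose_mutations",
    "cumulative_mutations",
    "poisson_counts",
]


@dataclass(frozen=True)
class GrowthParameters:
    """Parameters of the stochastic population-growth / mutation model.

    Attributes
    ----------
    P0 : initial population size (> 0).
    k : growth-rate constant, per unit time.
    p : white-noise amplitude, per sqrt(time); a magnitude, so >= 0.
    mu : mutations per individual per unit time (>= 0).
    g : genome size in nucleotides, used by the AT/GC decomposition.
    """

    P0: float
    k: float
    p: float
    mu: float
    g: int = 1

    def __post_init__(self) -> None:
        for name in ("P0", "k", "p", "mu"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        if self.P0 <= 0:
            raise ParameterError(f"P0 must be positive, got {self.P0}")
        if self.p < 0:
            raise ParameterError(f"noise amplitude p is a magnitude, got {self.p}")
        if self.mu < 0:
            raise ParameterError(f"mu must be non-negative, got {self.mu}")
        if not (isinstance(self.g, (int, np.integer)) and self.g >= 1):
            raise ParameterError(f"genome size g must be an integer >= 1, got {self.g}")

    def mean_mutations(self, t) -> np.ndarray | float:
        """Ensemble mean ``E[M_t] = P0 mu e^{k t}`` (lognormal mean identity)."""
        return self.P0 * self.mu * np.exp(self.k * np.asarray(t, dtype=float))

    def variance_mutations(self, t) -> np.ndarray | float:
        """``Var[M_t] = (P0 mu)^2 e^{2 k t} (e^{p^2 t} - 1)``."""
        t = np.asarray(t, dtype=float)
        m = self.P0 * self.mu * np.exp(self.k * t)
        return m * m * np.expm1(self.p**2 * t)

    def median_mutations(self, t) -> np.ndarray | float:
        """Median path ``P0 mu e^{(k - p^2/2) t}``; flattens as k -> p^2/2."""
        return self.P0 * self.mu * np.exp(
            (self.k - 0.5 * self.p**2) * np.asarray(t, dtype=float)
        )


@dataclass(frozen=True)
class MutationCounts:
    """AT/GC decomposition of an instantaneous mutation count."""

    at_count: float
    gc_count: float

    def __post_init__(self) -> None:
        if self.at_count < 0 or self.gc_count < 0:
            raise ParameterError("mutation counts must be non-negative")

    @property
    def total(self) -> float:
        """``M = M_AT + M_GC`` — conservation is exact by construction."""
        return self.at_count + self.gc_count


def simulate_mutations(
    gp: GrowthParameters, grid: TimeGrid, n_paths: int, seed: int
) -> TrajectoryEnsemble:
    """Exact lognormal paths of the mutation count ``M_t``.

    Uses the pathwise-exact update
    ``M_{i+1} = M_i exp((k - p^2/2) ds + p dB_i)``; with ``p = 0`` every
    path equals the deterministic curve ``P0 mu e^{k t}``.  Stored
    increments are the Brownian increments ``dB_i``.
    """
    if not isinstance(grid, TimeGrid):
        raise GridError(f"grid must be a TimeGrid, got {type(grid).__name__}")
    if n_paths < 1:
        raise ParameterError(f"n_paths must be >= 1, got {n_paths}")
    dt = grid.dt
    children = np.random.SeedSequence(seed).spawn(n_paths)
    dB = np.empty((n_paths, grid.n_steps))
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        dB[i] = rng.standard_normal(grid.n_steps)
    dB *= math.sqrt(dt)

    log_m = np.empty((n_paths, grid.n_steps + 1))
    log_m[:, 0] = math.log(gp.P0 * gp.mu) if gp.mu > 0 else -np.inf
    if gp.mu == 0:
        values = np.zeros((n_paths, grid.n_steps + 1))
    else:
        drift = (gp.k - 0.5 * gp.p**2) * dt
        log_m[:, 1:] = log_m[:, [0]] + np.cumsum(drift + gp.p * dB, axis=1)
        values = np.exp(log_m)
    return TrajectoryEnsemble(
        grid=grid, values=values, seed=seed, method="exact",
        quantity="mutation_count", increments=dB,
    )


def decompose_mutations(
    g: int, alpha: float, beta: float, F: float
) -> MutationCounts:
    """Split a genome's mutation intensity into AT and GC components.

    ``gc_count = |g alpha F|`` and ``at_count = |g beta (1 - F)|``; the
    moduli make the result independent of the rates' signs.  ``alpha``
    and ``beta`` default-use is the unperturbed constants ``a`` and
    ``b``; callers tracking the white-noise-perturbed instantaneous
    rates may pass those instead.
    """
    if not 0.0 <= F <= 1.0:
        raise ParameterError(f"GC fraction F must lie in [0, 1], got {F}")
    if g < 1:
        raise ParameterError(f"genome size must be >= 1, got {g}")
    return MutationCounts(
        at_count=abs(g * beta * (1.0 - F)),
        gc_count=abs(g * alpha * F),
    )


def cumulative_mutations(
    paths: TrajectoryEnsemble | np.ndarray, grid: TimeGrid | None = None
) -> np.ndarray:
    """Pathwise cumulative mutation load ``int_0^t M_s ds``.

    Composite-trapezoid cumulative integral along each path; the result
    has the same shape as the input values, is 0 at ``t = 0``, and is
    non-decreasing in ``t`` for non-negative intensities.
    """
    if isinstance(paths, TrajectoryEnsemble):
        values, grid = paths.values, paths.grid
    else:
        if grid is None:
            raise GridError("a TimeGrid is required with a raw value array")
        values = np.atleast_2d(np.asarray(paths, dtype=float))
        if values.shape[1] != grid.n_steps + 1:
            raise GridError(
                f"values shape {values.shape} inconsistent with grid "
                f"(expected n_steps+1 = {grid.n_steps + 1} columns)"
            )
    if np.any(values < 0):
        raise ParameterError("mutation intensities must be non-negative")
    return integrate.cumulative_trapezoid(values, grid.times, axis=1, initial=0.0)


def poisson_counts(
    intensities: np.ndarray, seed: int
) -> np.ndarray:
    """Integer mutation counts drawn as Poisson around continuous intensities.

    Extension beyond the continuous model, for fluctuation-style integer
    analyses: each entry is an independent Poisson draw with mean equal
    to the corresponding intensity.
    """
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities < 0):
        raise ParameterError("Poisson intensities must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(intensities)
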
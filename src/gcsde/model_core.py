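"""Core domain types and closed-form quantities of the GC-content SDE.

The model describes the genomic GC fraction ``F_t`` of a non-recombining,
Chargaff-parity-compliant organism evolving under an AT->GC mutation rate
``a`` and a GC->AT mutation rate ``b``, each perturbed by Gaussian white
noise scaled by a deterministic schedule ``c(t)``:

    dF_t = (a F_t + b (1 - F_t)) dt + c(t) dB_t .

This module holds the parameter containers and everything that can be
written in closed form: the noise-free (deterministic) trajectory, the
expectation of ``F_t`` (the Brownian term vanishes under the expectation),
and the variance obtained from the Ito isometry,

    Var(F_t) = int_0^t c(s)^2 exp(2 (a - b) (t - s)) ds ,

which for general ``c`` has no antiderivative and is computed by adaptive
quadrature.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

import numpy as np
from scipy import integrate

logger = logging.getLogger("gcsde")

#: Below this |a - b| the closed forms switch to their (a - b) -> 0 limit
#: branch; naive evaluation is 0/0 there.
AB_DEGENERACY_TOL = 1e-10

#: Default absolute tolerance for adaptive quadrature of the variance
#: integral.
QUADRATURE_ABS_TOL = 1e-10

#: Node count of the composite-trapezoid fallback used when adaptive
#: quadrature reports trouble.
TRAPEZOID_FALLBACK_NODES = 10_000


class GCSDEError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(GCSDEError, ValueError):
    """A model parameter violates its constraints."""


class GridError(GCSDEError, ValueError):
    """A time grid is malformed or incompatible with other inputs."""


class ScheduleDomainError(GCSDEError, ValueError):
    """The perturbation schedule c(t) is invalid where it is needed."""


class QuadratureError(GCSDEError, ArithmeticError):
    """Numerical integration failed to converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParameters:
    """Mutation-rate constants and the initial GC fraction.

    Parameters
    ----------
    a
        AT->GC mutation-rate constant, per unit (dimensionless) time.
    b
        GC->AT mutation-rate constant, per unit time.
    F0
        Initial GC fraction, strictly inside (0, 1) unless
        ``allow_boundary_F0`` is set (the SNP model fixes ``F0 = 0``).
    allow_a_ge_b
        The model's standard regime assumes ``a - b < 0`` (GC content
        relaxes toward ``-b/(a-b)``).  Constructing parameters outside
        that regime requires this explicit override; every closed form
        still evaluates.
    allow_boundary_F0
        Permit ``F0`` equal to 0 or 1 (used internally by the SNP
        GC-content model, which starts from ``F0 = 0``).
    """

    a: float
    b: float
    F0: float
    allow_a_ge_b: bool = False
    allow_boundary_F0: bool = False

    def __post_init__(self) -> None:
        for name in ("a", "b", "F0"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        lo_ok = self.F0 >= 0 if self.allow_boundary_F0 else self.F0 > 0
        hi_ok = self.F0 <= 1 if self.allow_boundary_F0 else self.F0 < 1
        if not (lo_ok and hi_ok):
            raise ParameterError(
                f"F0 must lie in (0, 1), got {self.F0}; pass "
                "allow_boundary_F0=True to permit the endpoints"
            )
        if self.a - self.b >= 0 and not self.allow_a_ge_b:
            raise ParameterError(
                f"the default regime requires a - b < 0 (got a={self.a}, "
                f"b={self.b}); pass allow_a_ge_b=True to override"
            )

    @property
    def rate_gap(self) -> float:
        """The decay rate ``a - b`` of the deterministic dynamics."""
        return self.a - self.b

    @property
    def is_degenerate(self) -> bool:
        """True when ``|a - b|`` is below the limit-branch threshold."""
        return abs(self.a - self.b) < AB_DEGENERACY_TOL

    @property
    def equilibrium_gc(self) -> float:
        """The fixed point ``-b/(a-b)`` of the noise-free dynamics.

        Undefined (raises) in the degenerate ``a = b`` case, where the
        deterministic trajectory grows linearly instead of saturating.
        """
        if self.is_degenerate:
            raise ParameterError("no finite equilibrium when a = b")
        return -self.b / (self.a - self.b)


Monotonicity = Literal["increasing", "decreasing", "none"]


@dataclass(frozen=True)
class PerturbationSchedule:
    """Deterministic scale ``c(t)`` of the white-noise rate perturbation.

    ``c`` maps times in ``[0, domain_end]`` to non-negative values with
    the same units as the rates.  The metadata flags are advisory: the
    Girsanov construction warns when ``is_monotonic`` is ``"none"`` and
    requires ``lower_bound > 0``.

    Use the factory helpers :func:`constant_schedule`,
    :func:`sqrt_schedule`, :func:`linear_decay_schedule` and
    :func:`quadratic_decay_schedule` for the standard scenario families.
    """

    c: Callable[[float], float]
    domain_end: float
    is_constant: bool = False
    is_monotonic: Monotonicity = "none"
    lower_bound: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (self.domain_end > 0 and math.isfinite(self.domain_end)):
            raise ParameterError(
                f"domain_end must be positive and finite, got {self.domain_end}"
            )

    def __call__(self, t):
        return self.c(t)

    def values(self, times: np.ndarray) -> np.ndarray:
        """Evaluate ``c`` on an array of times (vectorised, always ndarray)."""
        times = np.asarray(times, dtype=float)
        out = self.c(times)
        return np.broadcast_to(np.asarray(out, dtype=float), times.shape).copy()

    def check_metadata(self, n_probe: int = 512, rtol: float = 1e-9) -> None:
        """Verify the advisory flags against a dense sample of ``c``.

        Raises :class:`ScheduleDomainError` if a flag contradicts the
        sampled values (negativity always raises regardless of flags).
        """
        ts = np.linspace(0.0, self.domain_end, n_probe)
        vals = self.values(ts)
        if np.any(vals < -rtol):
            t_bad = ts[np.argmin(vals)]
            raise ScheduleDomainError(
                f"c(t) must be non-negative on [0, {self.domain_end}]; "
                f"c({t_bad:g}) = {vals.min():g}"
            )
        if self.is_constant and np.ptp(vals) > rtol * (1 + abs(vals[0])):
            raise ScheduleDomainError("is_constant set but c varies on the domain")
        d = np.diff(vals)
        tol = rtol * (1 + np.abs(vals).max())
        if self.is_monotonic == "increasing" and np.any(d < -tol):
            raise ScheduleDomainError("is_monotonic='increasing' contradicted by samples")
        if self.is_monotonic == "decreasing" and np.any(d > tol):
            raise ScheduleDomainError("is_monotonic='decreasing' contradicted by samples")
        if vals.min() < self.lower_bound - tol:
            raise ScheduleDomainError(
                f"lower_bound={self.lower_bound} exceeds sampled minimum {vals.min():g}"
            )


def constant_schedule(c0: float, t_end: float = 1.0) -> PerturbationSchedule:
    """``c(t) = c0`` — the constant scaling of the microbial-symbiont model."""
    if c0 < 0:
        raise ParameterError(f"constant schedule requires c0 >= 0, got {c0}")
    return PerturbationSchedule(
        c=lambda t, _c0=c0: np.full_like(np.asarray(t, dtype=float), _c0)
        if np.ndim(t) else _c0,
        domain_end=t_end, is_constant=True, is_monotonic="increasing",
        lower_bound=c0, name=f"const({c0:g})",
    )


def sqrt_schedule(kappa: float = 0.5, t_end: float = 1.0) -> PerturbationSchedule:
    """``c(t) = kappa * sqrt(t)`` — perturbations growing without bound."""
    if kappa < 0:
        raise ParameterError(f"sqrt schedule requires kappa >= 0, got {kappa}")
    return PerturbationSchedule(
        c=lambda t, _k=kappa: _k * np.sqrt(t),
        domain_end=t_end, is_monotonic="increasing", lower_bound=0.0,
        name=f"sqrt({kappa:g})",
    )


def linear_decay_schedule(kappa: float = 0.5, t_end: float = 1.0) -> PerturbationSchedule:
    """``c(t) = kappa * (T - t)`` — perturbations shrinking linearly to zero."""
    if kappa < 0:
        raise ParameterError(f"linear decay requires kappa >= 0, got {kappa}")
    return PerturbationSchedule(
        c=lambda t, _k=kappa, _T=t_end: _k * (_T - np.asarray(t, dtype=float)),
        domain_end=t_end, is_monotonic="decreasing", lower_bound=0.0,
        name=f"linear_decay({kappa:g})",
    )


def quadratic_decay_schedule(kappa: float = 0.5, t_end: float = 1.0) -> PerturbationSchedule:
    """``c(t) = kappa * (T - t)^2`` — perturbations shrinking quadratically."""
    if kappa < 0:
        raise ParameterError(f"quadratic decay requires kappa >= 0, got {kappa}")
    return PerturbationSchedule(
        c=lambda t, _k=kappa, _T=t_end: _k * (_T - np.asarray(t, dtype=float)) ** 2,
        domain_end=t_end, is_monotonic="decreasing", lower_bound=0.0,
        name=f"quad_decay({kappa:g})",
    )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid ``0 = s_0 < s_1 < ... < s_N = T``."""

    t_end: float
    n_steps: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_end) and self.t_end > 0):
            raise GridError(f"t_end must be positive and finite, got {self.t_end}")
        if not (isinstance(self.n_steps, (int, np.integer)) and self.n_steps >= 1):
            raise GridError(f"n_steps must be an integer >= 1, got {self.n_steps}")

    @property
    def dt(self) -> float:
        return self.t_end / self.n_steps

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_steps + 1)


@dataclass
class TrajectoryEnsemble:
    """A seeded collection of simulated paths on a common time grid.

    Attributes
    ----------
    grid
        The :class:`TimeGrid` the paths live on.
    values
        Array of shape ``(n_paths, n_steps + 1)``; column 0 is the shared
        initial condition.
    seed
        Master seed; per-path streams are spawned from it, so extending
        ``n_paths`` never alters earlier paths.
    method
        ``"euler_maruyama"``, ``"exact"`` or ``"deterministic"``.
    quantity
        What the state variable is: ``"gc_fraction"``,
        ``"mutation_count"`` or ``"population"``.
    increments
        Driving noise, shape ``(n_paths, n_steps)``.  For Euler-Maruyama
        these are the Brownian increments dB_i (required by the
        Radon-Nikodym reweighting); for the exact scheme they are the
        per-step integrated noise terms, which are *not* raw Brownian
        increments.
    exit_flags
        Per-path flag marking a first exit from the open interval (0, 1);
        only meaningful for ``quantity == "gc_fraction"``.
    """

    grid: TimeGrid
    values: np.ndarray
    seed: int
    method: Literal["euler_maruyama", "exact", "deterministic"]
    quantity: Literal["gc_fraction", "mutation_count", "population"] = "gc_fraction"
    increments: Optional[np.ndarray] = None
    exit_flags: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.n_steps + 1:
            raise GridError(
                f"values shape {self.values.shape} inconsistent with grid "
                f"(expected (n_paths, {self.grid.n_steps + 1}))"
            )
        if self.increments is not None:
            self.increments = np.asarray(self.increments, dtype=float)
            if self.increments.shape != (self.n_paths, self.grid.n_steps):
                raise GridError(
                    f"increments shape {self.increments.shape} inconsistent "
                    f"with values shape {self.values.shape}"
                )

    @property
    def n_paths(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def terminal(self) -> np.ndarray:
        """State values at the final grid time, one per path."""
        return self.values[:, -1]

    @property
    def n_exited(self) -> int:
        """Number of paths that left (0, 1) at some grid time."""
        if self.exit_flags is None:
            return 0
        return int(self.exit_flags.sum())


# ---------------------------------------------------------------------------
# Closed-form operations
# ---------------------------------------------------------------------------

def deterministic_gc(params: RateParameters, t) -> np.ndarray | float:
    """Noise-free GC fraction at time ``t``.

    Solves dF/dt = a F + b (1 - F) from ``F(0) = F0``:

        F(t) = -b/(a-b) + (F0 + b/(a-b)) * exp((a-b) t) ,

    with the limit branch ``F(t) = F0 + b t`` when ``a = b``.  Values are
    returned unclamped; a warning is emitted if the result leaves [0, 1].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("t must be non-negative")
    if params.is_degenerate:
        out = params.F0 + params.b * t_arr
    else:
        eq = params.equilibrium_gc
        out = eq + (params.F0 - eq) * np.exp(params.rate_gap * t_arr)
    _warn_if_outside_unit(out)
    return out if np.ndim(t) else float(out)


def expected_gc(params: RateParameters, t) -> np.ndarray | float:
    """Expectation of the stochastic GC fraction at time ``t``.

    The Brownian term has zero mean, so E[F_t] coincides with the
    deterministic trajectory; for ``F0 = 0`` this is the SNP GC-content
    form ``b/(a-b) (exp((a-b) t) - 1)`` (equivalently ``b t`` at
    ``a = b``).
    """
    return deterministic_gc(params, t)


def variance_gc(
    params: RateParameters,
    sched: PerturbationSchedule,
    t: float,
    tol: float = QUADRATURE_ABS_TOL,
) -> float:
    """Variance of ``F_t`` via the Ito isometry.

    Computes ``int_0^t c(s)^2 exp(2 (a-b) (t-s)) ds`` by adaptive
    quadrature with absolute tolerance ``tol``, falling back to a
    composite trapezoid on ``10^4`` nodes if adaptive quadrature reports
    non-convergence.  ``c`` is treated as an arbitrary black box.
    """
    if t < 0 or t > sched.domain_end + 1e-12:
        raise ParameterError(
            f"t={t} outside the schedule domain [0, {sched.domain_end}]"
        )
    if t == 0:
        return 0.0
    lam2 = 2.0 * params.rate_gap

    def integrand(s):
        c = sched.c(s)
        return c * c * np.exp(lam2 * (t - s))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", integrate.IntegrationWarning)
        value, abserr = integrate.quad(
            integrand, 0.0, t, epsabs=tol, epsrel=0.0, limit=200
        )
        trouble = any(
            issubclass(w.category, integrate.IntegrationWarning) for w in caught
        )
    if trouble or not math.isfinite(value):
        s = np.linspace(0.0, t, TRAPEZOID_FALLBACK_NODES + 1)
        fallback = float(np.trapezoid(integrand(s), s))
        if not math.isfinite(fallback):
            raise QuadratureError(
                f"variance quadrature failed at t={t}: adaptive value "
                f"{value!r} (abserr {abserr!r}), trapezoid fallback {fallback!r}"
            )
        logger.warning(
            "adaptive quadrature did not converge at t=%g; using composite "
            "trapezoid fallback (%d nodes)", t, TRAPEZOID_FALLBACK_NODES,
        )
        value = fallback
    return max(value, 0.0)


def _warn_if_outside_unit(values) -> None:
    arr = np.asarray(values)
    if np.any(arr < 0) or np.any(arr > 1):
        warnings.warn(
            "GC fraction left the open interval (0, 1); the model's "
            "constraint 0 < F_t < 1 is a statement about validity, values "
            "are reported unclamped",
            RuntimeWarning,
            stacklevel=3,
        )
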
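"""Mutation-rate estimation from SNP GC-content observations.

The expectation of the GC process started at ``F0 = 0``,

    f(x) = b/(a-b) (e^{(a-b) x} - 1) ,

evaluated with the core-genome GC fraction ``x`` in place of time, is
the classical regression model for SNP GC content versus core GC
content.  Because the Brownian term has zero mean it plays no role in
estimating ``a`` (AT->GC) and ``b`` (GC->AT): the rates are recovered by
nonlinear weighted least squares on observed ``(x, f)`` pairs.  The
standard regime ``a < b`` is enforced by the reparameterisation
``a = b - e^delta`` with ``(b, delta)`` free, which keeps the fit inside
the regime without explicit constraints and degrades gracefully to the
linear limit ``f = b x`` as ``delta -> -inf``.

Also provided: a synthetic ``(x, f)`` generator (uniform ``x``, additive
truncated-Gaussian noise on ``f``) so parameter recovery is testable
without external data, and a sequence utility reporting GC fraction and
Chargaff parity deviations from FASTA input.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import optimize

from .model_core import AB_DEGENERACY_TOL, ParameterError

__all__ = [
    "SNPObservations",
    "FitResult",
    "predict_snp_gc",
    "fit_rates",
    "generate_snp_data",
    "gc_content",
    "chargaff_report",
    "gc_content_fasta",
    "CompositionReport",
]

#: Nucleotides entering the GC-fraction denominator (U is mapped to T).
_CANONICAL = frozenset("ACGT")

#: Parameter convergence tolerance of the least-squares fit.
_FIT_XTOL = 1e-10

#: Lower bound on delta in a = b - e^delta; e^-30 ~ 1e-13 is numerically
#: indistinguishable from the a = b limit.
_DELTA_MIN = -30.0


# ---------------------------------------------------------------------------
# Observations container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPObservations:
    """Paired (core-genome GC fraction, SNP GC fraction) records.

    ``x`` must be strictly inside (0, 1); ``f`` finite.  ``weights``
    default to 1.  Serialised as 2-column tab-delimited text with header
    ``core_gc<TAB>snp_gc`` (optional third column ``weight``).
    """

    x: np.ndarray
    f: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.f.shape:
            raise ParameterError("x and f must be 1-d arrays of equal length")
        if not np.all((self.x > 0) & (self.x < 1)):
            raise ParameterError("all core GC fractions x must lie strictly in (0, 1)")
        if not np.all(np.isfinite(self.f)):
            raise ParameterError("SNP GC fractions f must be finite")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != self.x.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ParameterError("weights must be non-negative, finite, same length")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.x.size

    def effective_weights(self) -> np.ndarray:
        return self.weights if self.weights is not None else np.ones_like(self.x)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"core_gc": self.x, "snp_gc": self.f})
        if self.weights is not None:
            df["weight"] = self.weights
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path | io.IOBase) -> "SNPObservations":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = {"core_gc", "snp_gc"} - set(df.columns)
        if missing:
            raise ParameterError(
                f"observation table missing column(s): {sorted(missing)}"
            )
        w = df["weight"].to_numpy() if "weight" in df.columns else None
        return cls(x=df["core_gc"].to_numpy(), f=df["snp_gc"].to_numpy(), weights=w)


@dataclass(frozen=True)
class FitResult:
    """Recovered rates and diagnostics of the least-squares fit."""

    a_hat: float
    b_hat: float
    rss: float
    converged: bool
    stderr: tuple[float, float]
    n_obs: int
    n_iter: int
    message: str = ""

    @property
    def rate_gap(self) -> float:
        return self.a_hat - self.b_hat


# ---------------------------------------------------------------------------
# Model curve and fitting
# ---------------------------------------------------------------------------

def predict_snp_gc(a: float, b: float, x) -> np.ndarray | float:
    """SNP GC fraction predicted at core GC fraction ``x``.

    Evaluates ``b/(a-b) (e^{(a-b) x} - 1)`` with the series limit
    ``b x`` when ``a = b`` (removable singularity).  Smooth and, for
    ``b > 0`` and ``a < b``, increasing in ``x`` with ``f(0) = 0``.
    """
    x_arr = np.asarray(x, dtype=float)
    lam = a - b
    if abs(lam) < AB_DEGENERACY_TOL:
        out = b * x_arr
    else:
        out = b * np.expm1(lam * x_arr) / lam
    return out if np.ndim(x) else float(out)


def _model_and_jacobian(b: float, delta: float, x: np.ndarray):
    """Model values and d(model)/d(b, delta) under a = b - e^delta."""
    lam = -math.exp(delta)
    if abs(lam) < AB_DEGENERACY_TOL:
        h = x.copy()
        dh_dlam = 0.5 * x * x
    else:
        e = np.exp(lam * x)
        h = (e - 1.0) / lam
        dh_dlam = (x * e * lam - (e - 1.0)) / (lam * lam)
    m = b * h
    dm_db = h
    dm_ddelta = b * dh_dlam * lam  # chain rule: dlam/ddelta = -e^delta = lam
    return m, dm_db, dm_ddelta


def fit_rates(
    obs: SNPObservations,
    init: Optional[tuple[float, float]] = None,
) -> FitResult:
    """Weighted least-squares estimate of the mutation rates (a, b).

    Minimises ``sum_i w_i (f_i - f(x_i; a, b))^2`` over the regime
    ``a < b`` via the substitution ``a = b - e^delta`` (``b`` and
    ``delta`` free), with analytic Jacobian and parameter tolerance
    1e-10.  Standard errors come from the Gauss-Newton covariance
    ``s^2 (J^T W J)^{-1}`` propagated to the (a, b) scale.

    Parameters
    ----------
    obs
        At least 3 records with >= 3 distinct ``x`` values (two free
        parameters plus a residual degree of freedom).
    init
        Starting values ``(a0, b0)``; defaults to ``(-2, 1)``.
    """
    n = len(obs)
    if n < 3:
        raise ParameterError(f"need >= 3 observations for a 2-parameter fit, got {n}")
    if np.unique(obs.x).size < 3:
        raise ParameterError(
            "observations are degenerate: fewer than 3 distinct core GC values"
        )
    a0, b0 = init if init is not None else (-2.0, 1.0)
    if a0 >= b0:
        raise ParameterError(f"initial values must satisfy a0 < b0, got ({a0}, {b0})")
    sw = np.sqrt(obs.effective_weights())
    x, f = obs.x, obs.f

    def residuals(theta):
        m, _, _ = _model_and_jacobian(theta[0], theta[1], x)
        return sw * (f - m)

    def jacobian(theta):
        _, dm_db, dm_ddelta = _model_and_jacobian(theta[0], theta[1], x)
        return np.column_stack((-sw * dm_db, -sw * dm_ddelta))

    theta0 = np.array([b0, math.log(b0 - a0)])
    sol = optimize.least_squares(
        residuals, theta0, jac=jacobian,
        bounds=([-np.inf, _DELTA_MIN], [np.inf, 30.0]),
        xtol=_FIT_XTOL, ftol=1e-14, gtol=1e-12, max_nfev=500,
    )
    if sol.status <= 0:
        raise ParameterError(
            f"rate fit did not converge after {sol.nfev} evaluations: {sol.message}"
        )
    b_hat = float(sol.x[0])
    a_hat = b_hat - math.exp(float(sol.x[1]))
    rss = float(np.sum(sol.fun**2))
    stderr = _gauss_newton_stderr(a_hat, b_hat, x, sw, rss, n)
    return FitResult(
        a_hat=a_hat, b_hat=b_hat, rss=rss, converged=True, stderr=stderr,
        n_obs=n, n_iter=int(sol.nfev), message=str(sol.message),
    )


def _gauss_newton_stderr(
    a: float, b: float, x: np.ndarray, sw: np.ndarray, rss: float, n: int
) -> tuple[float, float]:
    """Approximate standard errors of (a_hat, b_hat)."""
    lam = a - b
    if abs(lam) < AB_DEGENERACY_TOL:
        h = x.copy()
        dh_dlam = 0.5 * x * x
    else:
        e = np.exp(lam * x)
        h = (e - 1.0) / lam
        dh_dlam = (x * e * lam - (e - 1.0)) / (lam * lam)
    # d model/d a = b dh/dlam ; d model/d b = h - b dh/dlam
    J = np.column_stack((sw * b * dh_dlam, sw * (h - b * dh_dlam)))
    dof = max(n - 2, 1)
    try:
        cov = rss / dof * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return float(se[0]), float(se[1])
    except np.linalg.LinAlgError:
        return math.nan, math.nan


def generate_snp_data(
    a: float,
    b: float,
    n: int,
    noise_sd: float,
    x_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> SNPObservations:
    """Synthetic (core GC, SNP GC) observations from the model curve.

    ``x`` is uniform on ``x_range`` (a sub-interval of (0, 1));
    ``f = f(x; a, b) + Normal(0, noise_sd)`` truncated to [0, 1].
    Reproducible from ``seed``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    lo, hi = x_range
    if not (0.0 < lo < hi < 1.0):
        raise ParameterError(
            f"x_range must be a non-empty sub-interval of (0, 1), got {x_range}"
        )
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n)
    f = predict_snp_gc(a, b, x)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=n), 0.0, 1.0)
    return SNPObservations(x=x, f=np.asarray(f, dtype=float))


# ---------------------------------------------------------------------------
# Sequence composition utility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionReport:
    """GC fraction and Chargaff intra-strand parity deviations.

    Percentages are of the effective length (canonical A/C/G/T after
    mapping U to T; ambiguity codes excluded).  Parity deviations are
    ``|%A - %T|`` and ``|%G - %C|`` in percentage points — near zero for
    genomes obeying Chargaff's second parity rule.
    """

    gc_fraction: float
    pct_a: float
    pct_c: float
    pct_g: float
    pct_t: float
    at_parity_deviation: float
    gc_parity_deviation: float
    effective_length: int


def _canonical_counts(sequence: str) -> Counter:
    seq = sequence.upper().replace("U", "T")
    counts = Counter(seq)
    return Counter({nt: counts[nt] for nt in _CANONICAL})


def gc_content(sequence: str) -> float:
    """GC fraction ``(G + C) / (A + C + G + T)`` of a nucleotide string.

    Case-insensitive; U counts as T; ambiguity codes (N, R, Y, ...) and
    gaps are excluded from the denominator.  Raises on an effectively
    empty sequence.
    """
    counts = _canonical_counts(sequence)
    total = sum(counts.values())
    if total == 0:
        raise ParameterError("sequence contains no unambiguous A/C/G/T/U nucleotides")
    return (counts["G"] + counts["C"]) / total


def chargaff_report(sequence: str) -> CompositionReport:
    """Full composition report: GC fraction plus Chargaff parity deviations."""
    counts = _canonical_counts(sequence)
    total = sum(counts.values())
    if total == 0:
        raise ParameterError("sequence contains no unambiguous A/C/G/T/U nucleotides")
    pct = {nt: 100.0 * counts[nt] / total for nt in "ACGT"}
    return CompositionReport(
        gc_fraction=(counts["G"] + counts["C"]) / total,
        pct_a=pct["A"], pct_c=pct["C"], pct_g=pct["G"], pct_t=pct["T"],
        at_parity_deviation=abs(pct["A"] - pct["T"]),
        gc_parity_deviation=abs(pct["G"] - pct["C"]),
        effective_length=total,
    )


def gc_content_fasta(path: str | Path) -> dict[str, CompositionReport]:
    """Per-record composition reports for a (multi-record) FASTA file."""
    reports: dict[str, CompositionReport] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        reports[record.id] = chargaff_report(str(record.seq))
    if not reports:
        raise ParameterError(f"no FASTA records found in {path}")
    return reports
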
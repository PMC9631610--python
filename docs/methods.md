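# Methods

## Model and assumptions

The state variable is the genomic GC fraction `F_t` of a
non-recombining, asexually reproducing organism whose genome satisfies
Chargaff's intra-strand parity (%G ≈ %C, %A ≈ %T), so that a single
fraction summarises base composition. Mutational drift is linear:
AT→GC events at rate `a` act on the GC pool `F`, GC→AT events at rate
`b` on the AT pool `1 − F`, giving `dF/dt = aF + b(1 − F)`. Both rates
receive a common white-noise perturbation scaled by a deterministic
measurable schedule `c(t) ≥ 0`; because the perturbation enters the two
terms with opposite-signed state coefficients that sum to one, the SDE
has *additive* noise:

    dF_t = (a F_t + b (1 − F_t)) dt + c(t) dB_t .

Assumptions worth making explicit:

- `a` and `b` are constants (time-varying rates are out of scope).
- The standard regime is `a − b < 0`, under which the noise-free
  dynamics relax toward the equilibrium `−b/(a−b)`; constructing
  parameters outside it requires an explicit override, and every closed
  form remains valid there.
- The constraint `0 < F_t < 1` is a statement about model validity, not
  something the SDE enforces. Closed forms and simulated paths are
  returned **unclamped**; leaving `[0, 1]` triggers a warning (closed
  forms) or per-path exit flags (simulators). An opt-in clamp to
  `[1e−6, 1 − 1e−6]` exists but is off by default because it biases
  every comparison against the closed-form moments.
- Time is dimensionless; all reference scenarios use `T = 1`.

The degenerate case `a = b` is a removable singularity of the closed
forms (`0/0`); below `|a − b| < 1e−10` the implementation switches to
the analytic limits (`F0 + b t` for the trajectory, `b x` for the SNP
curve). The threshold is far above double-precision cancellation error
and far below any biologically meaningful rate gap.

## Closed forms and quadrature

`Var(F_t) = ∫₀ᵗ c(s)² e^{2(a−b)(t−s)} ds` has no antiderivative for
general `c`, which the library treats as a black-box callable. The
integral uses adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`)
with absolute tolerance 1e−10; if the adaptive rule signals
non-convergence the value is recomputed on a 10⁴-node composite
trapezoid and a warning is logged, and only if that is also non-finite
does the call raise. Against a 10⁶-node trapezoid oracle the adaptive
values agree to better than 1e−6 for all scenario schedules, and to
1e−8 against the analytic antiderivative for constant `c`.

## Simulation schemes

Two independent samplers are provided; their agreement is itself a test.

**Euler–Maruyama.** `F_{i+1} = F_i + (aF_i + b(1−F_i))Δs + c(s_i)ΔB_i`
with `ΔB_i ~ N(0, Δs)` and left-endpoint (Itô, non-anticipating)
evaluation of `c`. Because the diffusion coefficient is
state-independent, EM is already strong order 1.0; no Milstein or
higher-order scheme is warranted. A textbook discretisation of the
stochastic integral is sometimes printed with an extra `Δs` factor
multiplying the white-noise increment; read literally this
double-counts the time step and shrinks the variance by a factor `Δs`,
which is incompatible with the Itô-isometry variance. The
implementation uses the Brownian-increment reading throughout; the
literal one survives only behind the `literal_ds_factor` debug flag of
`stochastic_integral`, with a test documenting its variance collapse.

**Exact sampler.** The linear SDE's solution is Gaussian around the
deterministic propagation, so each step draws
`F_{i+1} = eq + (F_i − eq)e^{(a−b)Δs} + ξ_i` with
`Var(ξ_i) = ∫_{s_i}^{s_{i+1}} c(s)² e^{2(a−b)(s_{i+1}−s)} ds`, evaluated
per step by 20-point Gauss–Legendre (exact to machine precision for the
smooth scenario schedules). Marginal moments are exact at any step
count — a one-step grid and a 500-step grid give statistically
indistinguishable terminal distributions.

**Randomness.** One master seed spawns an independent
`SeedSequence` child per path; enlarging an ensemble never changes
earlier paths, and identical seeds give bit-identical ensembles.

## Girsanov drift removal

With `Y_t = e^{−(a−b)t} F_t` the SDE reduces to
`dY = b e^{−(a−b)t} dt + c(t) e^{−(a−b)t} dB`. The deterministic drift
`u(t) = b/c(t)` and exponential martingale
`M_T = exp(−∫u dB − ½∫u² ds)` define a measure `Q` under which `Y` is a
driftless stochastic integral. The construction needs the *reciprocal*
of `c`, hence strict positivity on `[0, T]`; the classical monotone-`c`
(invertibility) framing is carried as advisory metadata and produces a
warning, not an error, when absent. A schedule vanishing anywhere on
the grid — e.g. `c(t) = √t/2` at `t = 0` — raises a domain error naming
the offending time.

Log weights are accumulated as
`−Σ u(s_i)ΔB_i − ½ Σ u(s_i)² Δs` (left endpoints, the same increments
that drove the EM paths) and exponentiated through a shifted, clipped
transform, since `∫u² ds` is large for small `c`. For deterministic
`u` the Novikov condition reduces to finiteness of `exp(½∫u² ds)`,
reported as a diagnostic; exponents above 700 are reported as `inf`.

The validation experiment estimates `E_Q[Y_T − Y_0]` as the
`M_T`-weighted sample mean and applies a 4-standard-error criterion:
driftless under `Q` while the unweighted mean matches the closed-form
physical drift `∫₀ᵀ b e^{−(a−b)s} ds`. Exact-scheme ensembles cannot be
reweighted (they store integrated noise, not Brownian increments), so
the validation uses EM with 300 steps — fine enough that discretisation
bias is far below Monte-Carlo noise at 10⁵ paths. The weight
distribution at the reference configuration (`u ≡ 2`, `T = 1`) is
lognormal with log-variance 4, so weighted estimates are heavy-tailed;
standard errors are computed from the weighted sample itself, which is
what makes the 4-SE criterion honest.

## Stochastic Luria–Delbrück model

Population growth with randomly perturbed rate `k + pW_t` is geometric
Brownian motion; the mutation count is `M_t = P_t μ` with
`M_t = P₀μ exp((k − p²/2)t + pB_t)`. Paths are sampled by the exact
lognormal update, so `E[M_t] = P₀μe^{kt}` and
`Var[M_t] = (P₀μ)²e^{2kt}(e^{p²t} − 1)` hold at every grid time. `p` is
a constant (that is what makes the solution analytic). As `k → p²/2`
the median path flattens while the mean keeps growing — the
fluctuation-dominated regime; the test suite asserts the mean/median
ratio grows with `p`. One statistical caveat: at `p = 2` (`σ² = 4` at
`T = 1`) the raw-scale sample variance is driven by a fourth moment of
order `e^{32}` and is uninformative at any feasible ensemble size, so
the variance identity is verified on the log scale there (log-increment
mean `(k − p²/2)Δt` and variance `p²Δt`), and on the raw scale only for
`p ≤ √2` within a fourth-moment-based Monte-Carlo error bound.

Counts are real-valued intensities, not integers — the model is
continuous. `poisson_counts` is an optional extension drawing integer
counts around the intensities for fluctuation-style analyses; the
AT/GC decomposition takes `α, β` as the unperturbed constants unless
the caller supplies instantaneous perturbed values (both entry points
are exposed because the model itself does not specify which applies at
an evaluation instant). Cumulative load `∫₀ᵗ M_s ds` is a pathwise
composite trapezoid.

## Rate estimation

The expectation started from `F₀ = 0`, evaluated at `t = x` (the
core-genome GC fraction), is the SNP GC-content regression curve
`f(x) = b/(a−b)(e^{(a−b)x} − 1)`. `F₀ = 0` is fixed, not a fit
parameter, and `x` is used as the abscissa without unit conversion —
the identification is taken as given, which is also why the Brownian
term never enters the estimation. The fit is nonlinear weighted least
squares with the regime constraint enforced by the substitution
`a = b − e^δ` (`b, δ` free, `δ ∈ [−30, 30]`), analytic Jacobian, and
parameter tolerance 1e−10. The reparameterisation degrades gracefully:
on data from the `a = b` limit the fit converges to the linear model
`f = bx` with `â − b̂ → 0⁻` and no numerical failure. Standard errors
are Gauss–Newton (`s²(JᵀWJ)⁻¹` in the `(a, b)` coordinates).

The synthetic generator draws `x` uniformly on a sub-interval of
(0, 1) (default `[0.05, 0.95]`) and adds Gaussian noise truncated to
`[0, 1]` on `f` — the least-structured observation-error model
consistent with least squares; the model curve itself supplies the
signal. What it deliberately does not emulate: phylogenetic correlation
between species-level observations, heteroscedastic measurement error,
or core-genome construction artefacts. Parameter-recovery results
therefore show correctness of the estimator under its own assumptions,
not robustness to those real-data features. Default generator
conditions for recovery experiments: `n = 200`, `noise_sd = 0.01`,
truth `(a, b) = (−2, 1)`.

## Reference scenarios and simulation sizes

The GC-process scenario family fixes `a = −2, b = 1, F₀ = 1/2, T = 1`
and varies the schedule: `c(t) = √t/2` (growing perturbations —
runaway-ratchet reading), `(T−t)/2` and `(T−t)²/2` (perturbations
quenched by mounting selective pressure). The mutation-model family
fixes `P₀ = 1, μ = 5, k = 1` with `p ∈ {1/2, √2, 2}`. Validation sizes
were chosen so Monte-Carlo error, not scheme error, dominates: 10⁴
paths × 1000 EM steps for moment recovery, 10⁵ paths × 300 steps for
the measure-change experiment, 10⁵ paths for the mutation moments.
Variance of the GC process as a function of time is monotone
non-decreasing only when `c` is non-decreasing (for decaying schedules
`dV/dt = c(t)² + 2(a−b)V` turns negative near `T`), and the tests
assert monotonicity exactly in that regime.

## Known limitations

- Additive noise can push `F` outside `[0, 1]` on pathological
  parameter sets (large `c`, `F₀` near a boundary); exit flags report
  this, but no reflecting/absorbing boundary variant is provided.
- The Girsanov module covers deterministic drifts `u(t)` only;
  path-dependent changes of measure are out of scope.
- The estimator assumes independent observations; no phylogenetic
  weighting is applied beyond user-supplied per-record weights.
- The classical integer-valued Luria–Delbrück mutant-count distribution
  (Lea–Coulson) is not implemented; the Poisson wrapper is a
  convenience, not that distribution.
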
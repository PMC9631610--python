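# gcsde

Stochastic modelling of genomic GC-content evolution in non-recombining,
asexually reproducing organisms whose genomes obey Chargaff's parity
rules.

## The model

The genomic GC fraction `F_t` evolves under an AT→GC mutation rate `a`
and a GC→AT mutation rate `b`. When both rates are perturbed by Gaussian
white noise scaled by a deterministic, time-varying function `c(t)` — a
proxy for (inverse) selective pressure — the dynamics become the linear
SDE

    dF_t = (a F_t + b (1 − F_t)) dt + c(t) dB_t ,

with explicit solution (integrating factor `e^{−(a−b)t}`, regime
`a − b < 0`)

    F_t = −b/(a−b) + (F_0 + b/(a−b)) e^{(a−b)t} + ∫₀ᵗ c(s) e^{(a−b)(t−s)} dB_s .

The Brownian term has zero mean, so `E[F_t]` is the deterministic curve;
its variance follows from the Itô isometry,

    Var(F_t) = ∫₀ᵗ c(s)² e^{2(a−b)(t−s)} ds .

The package implements, as a tested library plus CLI:

- **Closed forms** (`model_core`): deterministic solution, expectation,
  Itô-isometry variance by adaptive quadrature, for arbitrary
  black-box schedules `c(t)`.
- **Path simulation** (`sde_sim`): Euler–Maruyama and the exact
  linear-SDE sampler, which serve as mutual oracles, plus the
  discretised stochastic integral.
- **Girsanov drift removal** (`girsanov`): the drift `u(t) = b/c(t)`,
  Radon–Nikodym weights `M_T`, the Novikov diagnostic, and a Monte-Carlo
  validation that the reweighted process is driftless — GC content just
  as likely to rise as to fall, the mutation-accumulation regime of
  repair-knockout laboratory evolution experiments.
- **Stochastic Luria–Delbrück model** (`luria_delbruck`): mutation
  counts `M_t = P_t μ` on a geometric-Brownian population `P_t`, the
  Chargaff AT/GC decomposition `M = |g α F| + |g β (1−F)|`, and
  cumulative mutation load `∫₀ᵗ M_s ds`.
- **Rate estimation** (`estimation`): the SNP GC-content curve
  `f(x) = b/(a−b)(e^{(a−b)x} − 1)` versus core-genome GC content `x`,
  fitted by constrained nonlinear least squares; a synthetic-data
  generator; a FASTA GC/Chargaff-parity utility.

## Worked example

```python
import gcsde as g

params = g.RateParameters(a=-2.0, b=1.0, F0=0.5)
sched = g.sqrt_schedule(0.5, 1.0)          # c(t) = sqrt(t)/2
grid = g.TimeGrid(t_end=1.0, n_steps=1000)

ens = g.simulate_em(params, sched, grid, n_paths=10_000, seed=1)
print(f"terminal mean     {ens.terminal.mean():.4f}")
print(f"closed-form mean  {g.deterministic_gc(params, 1.0):.4f}")
print(f"terminal variance {ens.terminal.var(ddof=1):.5f}")
print(f"Ito-isometry var  {g.variance_gc(params, sched, 1.0):.5f}")

obs = g.generate_snp_data(a=-2.0, b=1.0, n=200, noise_sd=0.01, seed=1)
fit = g.fit_rates(obs)
print(f"a_hat = {fit.a_hat:.3f} +/- {fit.stderr[0]:.3f}")
print(f"b_hat = {fit.b_hat:.3f} +/- {fit.stderr[1]:.3f}")
```

prints

```
terminal mean     0.3417
closed-form mean  0.3416
terminal variance 0.03427
Ito-isometry var  0.03474
a_hat = -2.010 +/- 0.039
b_hat = 0.998 +/- 0.011
```

The 10 000-path ensemble mean reproduces the closed-form expectation
`1/3 + (1/6)e^{−3} ≈ 0.3416` to Monte-Carlo precision, the terminal
sample variance matches the Itô-isometry integral within sampling
error, and least squares on 200 noisy synthetic SNP observations
recovers the generating rates `(a, b) = (−2, 1)` within the reported
standard errors.

The same scenarios are available from a shell:

```sh
gcsde simulate --config examples/scenario_sqrt.ini --out run1
gcsde make-snp-data --a -2 --b 1 --n 200 --noise-sd 0.01 --seed 1 --out obs.tsv
gcsde fit obs.tsv
```

All tables are tab-separated with 17-significant-digit floats; repeated
runs with the same config and seed are byte-identical.

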
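# Methods

## Error model

Measurement errors are modelled as a zero-mean Gaussian process with
exponentially decaying autocorrelation `exp(−Δt_ij/τ)` (Gauss–Markov). On
an equispaced grid this process is Markov, so the whole path can be drawn
sequentially from the bivariate-normal conditional law: given the previous
error `x`, the next error is normal with mean `ρ·(σ_i/σ_{i−1})·x` and
variance `(1−ρ²)·σ_i²`, where `ρ = exp(−Δt/τ)`. Two properties are worth
stating because the tests rely on them:

* **Exact marginals.** By induction, every `X_i` is exactly
  `N(0, σ_i²)` — the recursion neither inflates nor shrinks the
  variance, including in the heteroscedastic case where `σ_i` follows the
  signal.
* **Exact correlation decay.** For constant σ the lag-k autocorrelation is
  `ρ^k`, i.e. the process is the standard stationary AR(1) with parameter
  ρ.

Degenerate points: when `σ(p_{i−1}) = 0` (a zero signal under relative
error) the previous error is zero almost surely and the conditional mean
ratio `σ_i/σ_{i−1}` is 0/0; the mean term is defined as 0, which restarts
the chain cleanly. `τ = ∞` gives `ρ = 1`: one draw scaled along the σ
profile. `ε = 0` returns the input bitwise.

Error processes for distinct species are mutually independent — the model
defines correlation along time only. Each species consumes an independent,
stable substream derived from `(seed, species index)` via
`numpy.random.SeedSequence` spawn keys, so adding a species never changes
another species' draws. Noisy values are *not* clipped at zero by default:
a measurement error may produce a negative reading, and clipping would
distort the error law near zero; a `clip_at_zero` flag exists for users
who want detector-like behaviour.

Variance postulates shipped: `relative` (`σ = ε|p|`, the study's case) and
`constant` (`σ = ε` in signal units). Other kernels (non-exponential
correlation) and other variance functions are out of scope.

## Reactor model

The simulated system is the three-step reversible transesterification
network in a perfectly mixed, constant-volume, isothermal flow-through
vessel: `dC_j/dt = R_j(C, k) + (C_j,feed − C_j)/τ_res`, feed = pure
methanol at the inlet level, initial charge = triglyceride plus the same
methanol level. Infinite residence time degenerates to a closed batch.
This is the textbook semi-batch balance consistent with "equal flow in and
out, characterized by a residence time"; since every recovery target here
is self-consistency (simulate, corrupt, re-fit the same model), the
conclusions do not hinge on this reconstruction.

Three linear invariants follow from stoichiometry and are used as
integrator checks: the glyceride backbone `TG+DG+MG+GL`, the methyl pool
`MeOH+E1+E2+E3`, and the acyl pool `3TG+2DG+MG+E1+E2+E3` are conserved in
a closed batch; in semi-batch the backbone decays exactly as
`B(0)·exp(−t/τ_res)` because the feed carries none.

**Numerics.** LSODA (via `scipy.integrate.odeint`) with the analytic
Jacobian of the mass-action network; defaults rtol = 1e-9, atol = 1e-11.
These are one decade tighter than strictly needed for plotting because the
package's own reproducibility contract ("halving the tolerances moves no
sampled value by more than 1e-7 relative") fails at 1e-8 (measured
3.3e-7) and holds comfortably at 1e-9 (1.8e-8), at no measurable runtime
cost. Output is evaluated exactly on the requested grid. Negative solver
excursions smaller than 1e-7 in magnitude are floored to zero for rate
evaluation — with atol = 1e-11 such excursions are tolerance noise near
zero crossings — while larger ones raise an integration failure. Units:
the rate constants are used numerically with concentrations in mol/L; the
recovery study is invariant to the unit convention as long as generation
and fitting share it.

**Horizon.** Default t_end = 3000 s (101 samples at Δt = 30 s) for every
residence time. By then the fastest experiment (τ_res = 200 s) is at
steady state and the slowest (2000 s) has passed its TG transient, which
is what makes all six constants identifiable from the set.

## Estimation

Six rate constants are fitted by trust-region-reflective least squares
(`scipy.optimize.least_squares`) on `log k`, which enforces positivity by
construction and makes the ×/÷ geometry of rate constants additive.
Finite-difference Jacobians use central differences; forward differences
are too crude in log space and can strand the optimizer in a shallow local
minimum when the start is far away (observed from a 10×-off start: ssq
stalls at 2.7e-3 instead of reaching ~1e-24). Tolerances 1e-10, max 500
iterations. A failed first start triggers up to four further seeded
starts, log-uniform within a factor of 10 of the initial guess; the
converged optimum with the lowest sum of squares wins.

**Weighting.** The default objective weights each residual by
`1/max(|observed|, 10⁻³ M)`. Rationale: the study's error is *relative*
(σ proportional to the signal), and weighted least squares with weights
`∝ 1/σ` is the maximum-likelihood estimator for independent Gaussian
errors — reciprocal-magnitude weights are the practical stand-in with the
true σ unknown. The unweighted objective (`weighting="none"`) is
dominated by the molar-scale TG/MeOH responses and leaves k4–k6, which
are informed mainly by the millimolar MG and GL responses, so weakly
determined that their estimates are visibly biased already at 1 % noise
(log-space positivity skews a flat likelihood upward). The 1 mM floor
keeps weights bounded where a signal crosses zero; results are
insensitive to the floor across 10⁻⁶–10⁻³ M. Neither choice affects
noiseless recovery, where the optimum is an exact zero of the residuals.
The error's serial correlation is ignored by the objective (generalized
least squares is out of scope); it widens the replicate spread but leaves
the estimator consistent.

**Simulation failures at trial k** (e.g. a solver abort at an extreme
parameter vector) are mapped to large penalty residuals (10⁶) with a
logged warning, which repels the optimizer without crashing the fit.

## Recovery study

For each error level the ideal series are simulated once; each of
`n_replicates` replicates gets independent Gauss–Markov errors (seeds
derived from `(base_seed, level index, replicate index, experiment
index)`, collision-free by construction), is fitted, and the per-constant
sample mean and std (n−1 denominator) over *converged* fits are
tabulated; non-converged fits are dropped and counted, never imputed. At
error level 0 all replicates are identical, so a single fit is run and
reported with zero spread. Fits are initialized at the generating truth:
the study measures estimator spread, not optimizer robustness (a
perturbed-init mode exists for the latter). The ± columns are replicate
sample standard deviations — with no noise they are exactly zero, which
is consistent with reference tables printing no ± on their 0 % rows.

Default study conditions: truth `K_TRUE_50C`, four residence times
2000/1000/500/200 s, error levels {0, 1, 2.5, 5, 7.5, 10} %, τ = 30 s,
Δt = 30 s, 100 replicates. Replicate counts in the heavier consistency
checks are scaled to the check's purpose: the 1 %-level mean check uses
the full 100 replicates, while the spread-versus-level trend check uses
25 per level — the trend statistic (sign of a Spearman correlation across
five levels) is insensitive to replicate count well below that.

## What the synthetic data do and do not emulate

The generator reproduces the two features that matter for testing
time-series estimators: signal-proportional error magnitude and
exponential error memory. It does not emulate outliers, drift,
quantization, missing samples, cross-species error correlation (e.g. from
a shared detector), or volume/temperature fluctuations in the reactor.
Passing the recovery study therefore demonstrates correctness of the
estimation machinery under the stated error model, not robustness of the
estimator to real-world artefacts outside it.

## Known limitations

* Only the 50 °C truth vector ships as a constant; other temperatures are
  supported only through user-supplied k vectors (no Arrhenius model).
* The replicate spreads depend on the weighting choice (see above); they
  quantify this estimator's precision, and should be compared across
  error levels rather than against spreads obtained with a different
  objective.
* Non-equispaced series are rejected rather than handled with per-step
  correlation coefficients; the error model is defined on a uniform grid.
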
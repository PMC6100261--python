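# insilico

Construction of in-silico data sets: superposition of Gauss–Markov
(exponentially correlated, normally distributed) measurement error onto
model-calculated time series, demonstrated on a semi-batch triglyceride
transesterification model with a full parameter-recovery study.

Testing a parameter-estimation procedure on real experimental data never
tells you whether the estimates are *right* — the truth is unknown. The
standard remedy is in-silico data: simulate a model whose parameters you
chose, superpose a realistic measurement error, fit the model back, and
compare estimates with the known truth. Realistic errors in experimental
time series are rarely independent from sample to sample; they carry a
"memory" that decays with the time elapsed between measurements. This
package generates exactly that kind of error and wraps the whole
simulate → corrupt → fit → tabulate loop.

## The error model

A measurement at time `t_i = t_0 + i·Δt` is `M_i = p_i + X_i`, where `p_i`
is the model-calculated (ideal) value and the errors `X_i` are zero-mean
normal with variance `σ_i² = σ²(p_i)` and exponentially decaying
correlation

    ρ(X_i, X_j) = exp(−(t_j − t_i)/τ),

with correlation time τ. On an equispaced grid this is a first-order
autoregressive (AR(1)) process with lag-one coefficient `ρ = exp(−Δt/τ)`,
generated by the conditional-normal recursion

    X_0 ~ N(0, σ₀²),
    X_i | X_{i−1} = x  ~  N(ρ·(σ_i/σ_{i−1})·x, (1−ρ²)·σ_i²).

The recursion keeps every marginal at exactly `N(0, σ_i²)` — no variance
inflation — while producing the exponential correlation decay. The default
variance postulate is relative error, `σ(p) = ε·|p|` (ε = 0.01 means
"1 %"); a constant-σ mode is also available.

## The kinetic test bed

Ideal series come from the stepwise reversible transesterification of a
triglyceride (TG) with methanol (MeOH) via diglyceride (DG) and
monoglyceride (MG) to glycerol (GL), releasing one fatty-acid methyl ester
(E1, E2, E3) per step:

    TG + MeOH ⇌ DG + E1   (k1, k2)
    DG + MeOH ⇌ MG + E2   (k3, k4)
    MG + MeOH ⇌ GL + E3   (k5, k6)

run in a perfectly mixed, constant-volume flow-through (semi-batch)
reactor with a pure-methanol feed:

    dC_j/dt = R_j(C, k) + (C_j,feed − C_j)/τ_res.

The reference system uses k = (0.0494, 0.1091, 0.2114, 1.2129, 2.4069,
0.0694), C_TG,0 = 1 M, C_MeOH,0 = 0.023 M, four residence times
τ_res ∈ {2000, 1000, 500, 200} s, Δt = 30 s, τ = 30 s. The six rate
constants are recovered by nonlinear least squares in log(k) space
(`scipy.optimize.least_squares`, relative weighting by default), and a
Monte-Carlo study tabulates mean ± std of each constant across noisy
replicates at error levels 1–10 %.

## Worked example

```python
import insilico as isd

truth = isd.RateConstants(*isd.K_TRUE_50C)

# 1. simulate one experiment (residence time 2000 s)
spec = isd.ReactorSpec(residence_time=2000.0)
ideal = isd.simulate_reactor(spec, truth)

# 2. superpose 2.5 % Gauss-Markov error (tau = 30 s)
noisy = isd.superpose_error(ideal, isd.NoiseSpec(epsilon=0.025, tau=30.0), seed=7)
print(ideal.column("TG")[:4])
print(noisy.column("TG")[:4])

# 3. fit all six rate constants from the four noiseless experiments,
#    starting ten-fold away from the truth
conditions = isd.default_conditions()
series = [isd.simulate_reactor(s, truth) for s in conditions]
exps = isd.ExperimentSet(tuple(zip(conditions, series)))
init = isd.RateConstants.from_array(truth.as_array() * 10)
fit = isd.fit_rate_constants(exps, init, seed=0)
print(fit.k_hat.as_array().round(4), fit.converged)
```

prints

```
[1.       0.96822  0.950518 0.935636]
[0.984248 0.995586 0.950695 0.982166]
[0.0494 0.1091 0.2114 1.2129 2.4069 0.0694] True
```

The first line is the calculated TG response at t = 0, 30, 60, 90 s; the
second is the same response with correlated 2.5 % error — note the
consecutive points pushed the same way by the error memory. The third line
shows the fit returning exactly the generating constants from noiseless
data despite the ten-fold-off start.

The same workflow is available from the shell:

```sh
insilico simulate --config run.yaml -o data/
insilico corrupt  --config run.yaml -i data/ideal_tau2000s.csv -o noisy.csv
insilico fit      --config run.yaml -i data/ -o fit.csv
insilico study    --config run.yaml -o study/
insilico plot     -i data/ -o figures/
```

where `run.yaml` holds the rate constants, reactor conditions, noise
levels and seeds (see `insilico/config.py` for the schema and defaults).

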
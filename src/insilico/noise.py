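"""Gauss-Markov (exponentially correlated) measurement-error generation.

The measurement model is ``M_i = p_i + X_i`` where the errors ``X_i`` are
zero-mean normal with variance ``sigma_i^2 = sigma^2(p_i)`` and exponentially
decaying correlation ``corr(X_i, X_j) = exp(-(t_j - t_i)/tau)``.  On an
equispaced grid this is exactly a (possibly heteroscedastic) first-order
autoregressive process with lag-one coefficient ``rho = exp(-dt/tau)``:

* the first error is drawn as ``N(0, sigma^2(p_0))``;
* each subsequent error, conditional on its predecessor, is
  ``N(rho * sigma_i / sigma_{i-1} * x_{i-1}, (1 - rho^2) * sigma_i^2)``.

The conditional law follows from dividing the bivariate zero-mean normal
density of ``(X_{i-1}, X_i)`` by the marginal of ``X_{i-1}``; the recursion
keeps every marginal at exactly ``N(0, sigma_i^2)`` — no variance inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries

VARIANCE_MODES = ("relative", "constant")


@dataclass(frozen=True)
class NoiseSpec:
    """How measurement error scales with the signal and decays with time.

    Parameters
    ----------
    epsilon : float
        Relative error fraction (0.01 means "1%"); the error std at ideal
        value ``p`` is ``epsilon * |p|`` in relative mode.  In constant mode
        ``epsilon`` is the absolute error std in signal units.
    tau : float
        Correlation time in seconds (> 0; ``inf`` gives a perfectly
        persistent error).
    variance_mode : str
        ``"relative"`` (default) for sigma proportional to the signal,
        ``"constant"`` for a signal-independent sigma.
    """

    epsilon: float
    tau: float = 30.0
    variance_mode: str = "relative"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.variance_mode not in VARIANCE_MODES:
            raise ValueError(
                f"variance_mode must be one of {VARIANCE_MODES}, "
                f"got {self.variance_mode!r}"
            )

    def sigma(self, p: np.ndarray | float) -> np.ndarray | float:
        """Error standard deviation at ideal value(s) ``p``."""
        if self.variance_mode == "relative":
            return self.epsilon * np.abs(p)
        return self.epsilon * np.ones_like(np.asarray(p, dtype=float))


@dataclass(frozen=True)
class ConditionalNormal:
    """Normal law of the next error given the realized previous error."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")


def correlation_coefficient(dt: float, tau: float) -> float:
    """Lag-one correlation ``rho = exp(-dt/tau)`` between consecutive errors.

    ``dt`` is the sampling interval and ``tau`` the correlation time, both in
    seconds.  Monotone decreasing in ``dt``, increasing in ``tau``;
    ``tau = inf`` returns 1 (perfectly persistent error).
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if math.isinf(tau):
        return 1.0
    return math.exp(-dt / tau)


def variance_function(p: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Relative-error variance postulate ``sigma^2(p) = (epsilon * |p|)^2``.

    Non-decreasing in |p|, vanishing at p = 0.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    return np.square(epsilon * np.abs(p))


def conditional_error_distribution(
    x_prev: float, sigma_prev: float, sigma_curr: float, rho: float
) -> ConditionalNormal:
    """Law of error X_i given X_{i-1} = ``x_prev``.

    Mean ``rho * sigma_curr / sigma_prev * x_prev`` and variance
    ``(1 - rho^2) * sigma_curr^2``.  When ``sigma_prev == 0`` the previous
    error is zero almost surely and the mean term is defined as 0, so the
    chain restarts cleanly at zero-valued ideal points.
    """
    if sigma_prev < 0 or sigma_curr < 0:
        raise ValueError("standard deviations must be >= 0")
    if abs(rho) > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    mean = 0.0 if sigma_prev == 0.0 else rho * (sigma_curr / sigma_prev) * x_prev
    variance = (1.0 - rho * rho) * sigma_curr * sigma_curr
    return ConditionalNormal(mean=mean, variance=variance)


def _species_rng(seed: int | np.random.SeedSequence, species_index: int) -> np.random.Generator:
    """Independent substream per species: adding a species never perturbs
    another species' draws."""
    if isinstance(seed, np.random.SeedSequence):
        base_entropy, base_key = seed.entropy, tuple(seed.spawn_key)
    else:
        base_entropy, base_key = int(seed), ()
    child = np.random.SeedSequence(
        entropy=base_entropy, spawn_key=base_key + (species_index,)
    )
    return np.random.default_rng(child)


def sample_error_sequence(
    sigmas: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one Gauss-Markov error path with per-point stds ``sigmas``."""
    sigmas = np.asarray(sigmas, dtype=float)
    n = sigmas.size
    x = np.zeros(n)
    if n == 0:
        return x
    innov = rng.standard_normal(n)
    x[0] = sigmas[0] * innov[0]
    cond_sd = math.sqrt(max(0.0, 1.0 - rho * rho))
    # inline of conditional_error_distribution, kept in lock-step by a test
    for i in range(1, n):
        s_prev, s_curr = sigmas[i - 1], sigmas[i]
        mean = 0.0 if s_prev == 0.0 else rho * (s_curr / s_prev) * x[i - 1]
        x[i] = mean + cond_sd * s_curr * innov[i]
    return x


def superpose_error(
    ideal: TimeSeries,
    spec: NoiseSpec,
    seed: int | np.random.SeedSequence,
    *,
    clip_at_zero: bool = False,
) -> TimeSeries:
    """Superpose Gauss-Markov error on an ideal series: ``M_i = p_i + X_i``.

    Each species column receives an independent error process (correlation
    acts only along time, never across species).  The lag-one coefficient
    ``rho = exp(-dt/tau)`` is computed once from the series' constant
    sampling interval.  Output is bitwise reproducible for a fixed seed.

    Noisy values are not clipped at zero by default — a measurement error
    may legitimately produce a negative reading; pass ``clip_at_zero=True``
    to floor the output.
    """
    if ideal.is_noisy:
        raise ValueError("input series is already noisy")
    rho = correlation_coefficient(ideal.dt if ideal.n_times > 1 else 0.0, spec.tau)
    noisy = np.empty_like(ideal.values)
    for j in range(ideal.n_species):
        p = ideal.values[:, j]
        sigmas = np.asarray(spec.sigma(p), dtype=float)
        rng = _species_rng(seed, j)
        noisy[:, j] = p + sample_error_sequence(sigmas, rho, rng)
    if clip_at_zero:
        np.maximum(noisy, 0.0, out=noisy)
    return ideal.with_values(noisy, is_noisy=True)
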
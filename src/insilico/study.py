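"""Monte-Carlo parameter-recovery study.

For each relative error level the ideal series of every experiment is
simulated once, then ``n_replicates`` independent noisy data sets are drawn
and fitted.  The tabulated mean and sample standard deviation of each rate
constant across converged replicate fits quantify the estimator's spread as
a function of the measurement-error level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import ExperimentSet, FitResult, fit_rate_constants
from .kinetics import K_TRUE_50C, RateConstants, ReactorSpec, default_conditions, simulate_reactor
from .noise import NoiseSpec, superpose_error
from .timeseries import TimeSeries

logger = logging.getLogger(__name__)

#: Relative error levels of the study, as fractions.
ERROR_LEVELS_DEFAULT = (0.0, 0.01, 0.025, 0.05, 0.075, 0.10)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one recovery study."""

    truth: RateConstants = field(
        default_factory=lambda: RateConstants(*K_TRUE_50C)
    )
    conditions: tuple[ReactorSpec, ...] = field(default_factory=default_conditions)
    error_levels: tuple[float, ...] = ERROR_LEVELS_DEFAULT
    tau: float = 30.0
    n_replicates: int = 100
    base_seed: int = 0
    init_at_truth: bool = True
    init_perturbation: float = 0.0  # log10 half-width when not init_at_truth

    def __post_init__(self) -> None:
        levels = tuple(float(e) for e in self.error_levels)
        if any(e < 0 for e in levels):
            raise ValueError("error levels must be non-negative")
        if list(levels) != sorted(levels):
            raise ValueError("error levels must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "error_levels", levels)
        object.__setattr__(self, "conditions", tuple(self.conditions))


@dataclass(frozen=True)
class StudyTable:
    """Per (error level, rate constant): mean, std, converged count."""

    frame: pd.DataFrame  # columns: error_pct, k_index, mean, std, n_converged

    def cell(self, error_pct: float, k_index: int) -> tuple[float, float, int]:
        f = self.frame
        row = f[(np.isclose(f["error_pct"], error_pct)) & (f["k_index"] == k_index)]
        if row.empty:
            raise KeyError(f"no cell for error={error_pct}%, k{k_index}")
        r = row.iloc[0]
        return float(r["mean"]), float(r["std"]), int(r["n_converged"])

    def to_pretty(self) -> str:
        """Human-readable layout: one block per error level, mean ± std."""
        lines = []
        for pct, block in self.frame.groupby("error_pct", sort=True):
            lines.append(f"error = {pct:g}%")
            for _, r in block.sort_values("k_index").iterrows():
                std = r["std"]
                spread = "" if np.isnan(std) else f" ± {std:.4f}"
                lines.append(
                    f"  k{int(r['k_index'])} = {r['mean']:.4f}{spread}"
                    f"   (n_converged = {int(r['n_converged'])})"
                )
        return "\n".join(lines)


def replicate_seed(
    base_seed: int, level_index: int, replicate: int, condition: int = 0
) -> np.random.SeedSequence:
    """Collision-free error stream for one (level, replicate, experiment)."""
    return np.random.SeedSequence(
        entropy=base_seed, spawn_key=(level_index, replicate, condition)
    )


def summarize_replicates(fits: list[FitResult]) -> pd.DataFrame:
    """Mean and sample std (n-1 denominator) per k over converged fits.

    Non-converged fits are excluded and counted; if none converged an error
    is raised.  With a single converged fit the std is NaN (undefined).
    """
    if not fits:
        raise ValueError("need at least one fit")
    converged = [f for f in fits if f.converged]
    n_dropped = len(fits) - len(converged)
    if n_dropped:
        logger.info("dropping %d non-converged fit(s) of %d", n_dropped, len(fits))
    if not converged:
        raise RuntimeError("no replicate fit converged")
    k_matrix = np.array([f.k_hat.as_array() for f in converged])
    means = k_matrix.mean(axis=0)
    stds = (
        k_matrix.std(axis=0, ddof=1)
        if len(converged) > 1
        else np.full(6, np.nan)
    )
    return pd.DataFrame(
        {
            "k_index": np.arange(1, 7),
            "mean": means,
            "std": stds,
            "n_converged": len(converged),
        }
    )


def run_recovery_study(config: StudyConfig) -> StudyTable:
    """Simulate, corrupt, fit and tabulate — fully seeded and reproducible.

    At error level 0 every replicate is identical, so a single fit is run
    and reported with zero spread across ``n_replicates`` nominal
    replicates.
    """
    ideal: list[TimeSeries] = [
        simulate_reactor(spec, config.truth) for spec in config.conditions
    ]
    init_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.base_seed, spawn_key=(0xF17,))
    )

    blocks: list[pd.DataFrame] = []
    for li, level in enumerate(config.error_levels):
        if level == 0.0:
            exps = ExperimentSet(tuple(zip(config.conditions, ideal)))
            fit = fit_rate_constants(exps, self_init(config, init_rng))
            if not fit.converged:
                raise RuntimeError("noiseless fit failed to converge")
            summary = pd.DataFrame(
                {
                    "k_index": np.arange(1, 7),
                    "mean": fit.k_hat.as_array(),
                    "std": 0.0,
                    "n_converged": config.n_replicates,
                }
            )
        else:
            spec = NoiseSpec(epsilon=level, tau=config.tau)
            fits = []
            for r in range(config.n_replicates):
                noisy = [
                    superpose_error(
                        series,
                        spec,
                        replicate_seed(config.base_seed, li, r, ci),
                    )
                    for ci, series in enumerate(ideal)
                ]
                exps = ExperimentSet(tuple(zip(config.conditions, noisy)))
                fits.append(fit_rate_constants(exps, self_init(config, init_rng)))
            summary = summarize_replicates(fits)
            if summary["n_converged"].iloc[0] == 0:
                raise RuntimeError(f"no converged fit at error level {level:.1%}")
        summary.insert(0, "error_pct", level * 100.0)
        blocks.append(summary)
    return StudyTable(pd.concat(blocks, ignore_index=True))


def self_init(config: StudyConfig, rng: np.random.Generator) -> RateConstants:
    """Fit initialization: the generating truth, optionally log-perturbed.

    The default (truth itself) makes the study measure estimator spread
    rather than optimizer robustness; a nonzero ``init_perturbation``
    switches to random inits for robustness studies.
    """
    if config.init_at_truth or config.init_perturbation == 0.0:
        return config.truth
    jitter = rng.uniform(
        -config.init_perturbation, config.init_perturbation, size=6
    ) * np.log(10.0)
    return RateConstants.from_array(config.truth.as_array() * np.exp(jitter))
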
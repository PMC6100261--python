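"""Run configuration: one YAML file drives simulate / corrupt / fit / study.

Example::

    kinetics:
      k: [0.0494, 0.1091, 0.2114, 1.2129, 2.4069, 0.0694]
      residence_times_s: [2000, 1000, 500, 200]
      c_tg0_M: 1.0
      c_meoh0_M: 0.023
      t_end_s: 3000
      dt_s: 30
    noise:
      epsilon: 0.01
      levels: [0, 0.01, 0.025, 0.05, 0.075, 0.10]
      tau_s: 30
      variance_mode: relative
      seed: 0
    study:
      n_replicates: 100
      base_seed: 0

All randomness flows from the seeds declared here; nothing consults the
wall clock or global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .kinetics import (
    C_MEOH0,
    C_TG0,
    DT_DEFAULT,
    K_TRUE_50C,
    RESIDENCE_TIMES,
    T_END_DEFAULT,
    RateConstants,
    ReactorSpec,
)
from .noise import NoiseSpec
from .study import ERROR_LEVELS_DEFAULT, StudyConfig


class ConfigError(ValueError):
    """Missing or inconsistent configuration keys."""


@dataclass(frozen=True)
class RunConfig:
    truth: RateConstants
    conditions: tuple[ReactorSpec, ...]
    noise: NoiseSpec
    error_levels: tuple[float, ...]
    seed: int
    n_replicates: int
    base_seed: int

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            truth=self.truth,
            conditions=self.conditions,
            error_levels=self.error_levels,
            tau=self.noise.tau,
            n_replicates=self.n_replicates,
            base_seed=self.base_seed,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    kin = raw.get("kinetics", {}) or {}
    noise = raw.get("noise", {}) or {}
    study = raw.get("study", {}) or {}

    try:
        k_values = kin.get("k", list(K_TRUE_50C))
        truth = RateConstants.from_array(k_values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: bad kinetics.k: {exc}") from exc

    residence_times = kin.get("residence_times_s", list(RESIDENCE_TIMES))
    c_tg0 = float(kin.get("c_tg0_M", C_TG0))
    c_meoh0 = float(kin.get("c_meoh0_M", C_MEOH0))
    t_end = float(kin.get("t_end_s", T_END_DEFAULT))
    dt = float(kin.get("dt_s", DT_DEFAULT))
    try:
        conditions = tuple(
            ReactorSpec(
                residence_time=float(tr),
                t_end=t_end,
                dt=dt,
                c_tg0=c_tg0,
                c_meoh0=c_meoh0,
            )
            for tr in residence_times
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: bad kinetics block: {exc}") from exc

    try:
        noise_spec = NoiseSpec(
            epsilon=float(noise.get("epsilon", 0.01)),
            tau=float(noise.get("tau_s", 30.0)),
            variance_mode=str(noise.get("variance_mode", "relative")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: bad noise block: {exc}") from exc

    levels = tuple(float(e) for e in noise.get("levels", ERROR_LEVELS_DEFAULT))
    return RunConfig(
        truth=truth,
        conditions=conditions,
        noise=noise_spec,
        error_levels=levels,
        seed=int(noise.get("seed", 0)),
        n_replicates=int(study.get("n_replicates", 100)),
        base_seed=int(study.get("base_seed", 0)),
    )
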
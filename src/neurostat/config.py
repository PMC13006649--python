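"""Run configuration, validation and shared file I/O.

A run is described by one YAML/JSON document with sections for the synthetic
generator, the network and its training, the smoother, the two controller
phase parameter sets and the plant.  The schema is strict: unknown keys are
rejected with their location, and cross-field invariants (for example
``baseline_lb < baseline_ub``) are enforced at load time, before anything
runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import controller as _controller
from . import mlp as _mlp
from . import plant as _plant
from . import smoothing as _smoothing
from . import synth as _synth

__all__ = ["RunConfig", "ConfigError", "load_config", "read_do_csv", "write_trajectory"]


class ConfigError(ValueError):
    """Configuration file violates the schema; message names key and constraint."""


class _Section(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class GeneratorSection(_Section):
    level_range: tuple[float, float] = (10.0, 70.0)
    slope_range: tuple[float, float] = (0.05, 0.5)
    drift_max: float = 2.0
    spike_height_range: tuple[float, float] = (5.0, 45.0)
    rise_width_range: tuple[float, float] = (1.0, 5.0)
    decay_width_range: tuple[float, float] = (2.0, 15.0)
    gap_range: tuple[float, float] = (3.0, 30.0)
    noise_sd_range: tuple[float, float] = (0.0, 1.0)
    trend_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    trace_length_min: int = 240
    windows_per_trace: int = 10
    include_noise: bool = True
    overlapping_windows: bool = True

    def build(self) -> _synth.GeneratorParams:
        return _synth.GeneratorParams(**self.model_dump())


class ModelSection(_Section):
    input_size: int = 60
    hidden_sizes: tuple[int, ...] = (1024, 512, 256, 128)
    activation: str = "relu"

    def build(self) -> _mlp.ModelConfig:
        return _mlp.ModelConfig(**self.model_dump())


class TrainingSection(_Section):
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    min_learning_rate: float = 1e-5
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 10
    val_fraction: float = 0.1

    def build(self) -> _mlp.TrainingConfig:
        return _mlp.TrainingConfig(**self.model_dump())


class SmootherSection(_Section):
    window_length: int = 15
    poly_order: int = 2

    def build(self) -> _smoothing.CausalSavitzkyGolay:
        return _smoothing.CausalSavitzkyGolay(self.window_length, self.poly_order)


class ControllerPhaseSection(_Section):
    baseline_lb: float = 25.0
    baseline_ub: float = 50.0
    baseline_increase: float = 15.0
    threshold_increase: float = 40.0
    v_glc: float = 21.0
    v_ns: float = 1.0
    induction_time: float = 10.0
    agitate_step: float = 20.0
    air_step: float = 0.05
    agitate_min: float = 400.0
    agitate_max: float = 800.0
    air_min: float = 0.5
    air_max: float = 1.5
    max_pulse_duration: float = 3.0
    iptg_dose_mmol_per_l: float = 0.3

    def build(self) -> _controller.ControllerParams:
        try:
            return _controller.ControllerParams(**self.model_dump())
        except ValueError as exc:
            raise ConfigError(f"controller phase parameters invalid: {exc}") from exc


class ControllerSection(_Section):
    o2_cooldown_min: float = 10.0
    growth: ControllerPhaseSection = ControllerPhaseSection()
    # induction phase: by default override the three feeding setpoints
    induction: ControllerPhaseSection | None = None
    induction_baseline_increase: float = 5.0
    induction_threshold_increase: float = 10.0
    induction_v_glc: float = 7.0

    def build(self) -> _controller.PhaseParamSet:
        growth = self.growth.build()
        if self.induction is not None:
            return _controller.PhaseParamSet(growth, self.induction.build())
        try:
            return _controller.PhaseParamSet.with_induction_overrides(
                growth,
                baseline_increase=self.induction_baseline_increase,
                threshold_increase=self.induction_threshold_increase,
                v_glc=self.induction_v_glc,
            )
        except ValueError as exc:
            raise ConfigError(f"controller.induction_*: {exc}") from exc


class PlantSection(_Section):
    mu_max: float = 0.6
    Ks: float = 0.05
    Ko: float = 5.0
    Yxs: float = 0.5
    yo: float = 0.8
    c_o2_sat: float = 0.0075
    kla_a: float = 50.0
    kla_b: float = 2.0
    kla_c: float = 0.4
    do_sat: float = 100.0
    feed_glucose: float = 500.0
    initial_biomass: float = 0.12
    initial_glucose: float = 10.0
    initial_do: float = 100.0
    initial_volume: float = 0.7
    sensor_noise_sd: float = 0.3
    sensor_lag_tau: float = 30.0

    def build(self) -> _plant.PlantParams:
        return _plant.PlantParams(**self.model_dump())


class RunConfig(_Section):
    """Validated top-level run configuration with all defaults applied."""

    seed: int = 0
    duration_h: float = 24.0
    model_path: str | None = None
    output_dir: str = "."
    generator: GeneratorSection = GeneratorSection()
    model: ModelSection = ModelSection()
    training: TrainingSection = TrainingSection()
    smoother: SmootherSection = SmootherSection()
    controller: ControllerSection = ControllerSection()
    plant: PlantSection = PlantSection()

    def config_hash(self) -> str:
        """Stable hash of the effective configuration, for run logs."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except pydantic.ValidationError as exc:
        locs = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"{path}: {locs}") from exc
    # trigger cross-field invariant checks eagerly so errors carry locations
    cfg.controller.build()
    return cfg


def read_do_csv(path: str | Path) -> pd.DataFrame:
    """Read a DO time series CSV with columns ``time_s`` and ``do_percent``.

    Malformed numeric cells are reported with their row numbers; an empty
    file yields an empty frame rather than an exception.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=["time_s", "do_percent"])
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "do_percent") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_rows = []
    for col in ("time_s", "do_percent"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_rows.extend((int(i) + 2, col) for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if bad_rows:
        desc = ", ".join(f"line {line} ({col})" for line, col in bad_rows[:10])
        raise ValueError(f"{path}: non-numeric values at {desc}")
    if df[["time_s", "do_percent"]].isna().any().any():
        rows = df.index[df[["time_s", "do_percent"]].isna().any(axis=1)] + 2
        raise ValueError(f"{path}: missing values at lines {list(rows[:10])}")
    return df


def write_trajectory(traj: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory frame to CSV (full float precision round-trip)."""
    traj.to_csv(path, index=False, float_format="%.12g")
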
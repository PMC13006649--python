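"""Synthetic dissolved-oxygen signal generation for baseline-recognition training.

During DO-stat fed-batch operation the dissolved-oxygen (DO) trace consists of a
slowly varying *baseline* — set by the balance between oxygen transfer and
cellular uptake — punctuated by sharp upward spikes whenever glucose runs out
and the oxygen uptake rate collapses.  The baseline itself cannot be measured
by any physical sensor, so the recognition model is trained on synthetic traces
whose ground-truth baseline is known by construction.

A trace is built in three layers:

1. a baseline trajectory (stable with bounded drift, or a linear ramp up/down),
2. a train of depletion spikes, each with a linear rise to its apex and an
   exponential relaxation back to the baseline, and
3. optional Gaussian sensor noise,

and is finally clipped to the physical range [0, 100] % air saturation.
Training windows are 60-minute slices cut from longer traces, labelled with the
baseline value at the slice's final minute.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

WINDOW_LEN = 60
TREND_KINDS = ("stable", "increasing", "decreasing")

__all__ = [
    "WINDOW_LEN",
    "TREND_KINDS",
    "GeneratorParams",
    "BaselineTrajectory",
    "SpikeSpec",
    "SyntheticDataset",
    "spike_profile",
    "generate_baseline_trajectory",
    "sample_spike_train",
    "superimpose_spikes",
    "generate_dataset",
    "split_dataset",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Distribution parameters of the synthetic-trace generator.

    All ranges are (low, high) bounds of uniform draws.  The defaults span the
    regimes seen in DO-stat operation: spike heights of a few tens of %DO,
    rises of minutes, recoveries of up to a quarter hour, and baselines in the
    mid-range of the probe.  Every value is an assumption, not a constant, and
    can be overridden per run.
    """

    level_range: tuple[float, float] = (10.0, 70.0)  # baseline level, %DO
    slope_range: tuple[float, float] = (0.05, 0.5)  # ramp |slope|, %DO/min
    drift_max: float = 2.0  # max |drift| of a "stable" baseline, %DO
    spike_height_range: tuple[float, float] = (5.0, 45.0)  # %DO above baseline
    rise_width_range: tuple[float, float] = (1.0, 5.0)  # min
    decay_width_range: tuple[float, float] = (2.0, 15.0)  # min
    gap_range: tuple[float, float] = (3.0, 30.0)  # min between spikes
    noise_sd_range: tuple[float, float] = (0.0, 1.0)  # Gaussian sd, %DO
    trend_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    trace_length_min: int = 240
    windows_per_trace: int = 10
    include_noise: bool = True
    overlapping_windows: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class BaselineTrajectory:
    """Ground-truth DO baseline, one value per minute, in % air saturation."""

    values: np.ndarray
    trend_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < WINDOW_LEN:
            raise ValueError(f"baseline needs >= {WINDOW_LEN} minute values")
        if self.trend_kind not in TREND_KINDS:
            raise ValueError(f"unknown trend_kind {self.trend_kind!r}")


@dataclass(frozen=True)
class SpikeSpec:
    """One glucose-depletion DO spike: linear rise, exponential relaxation."""

    onset_index: float  # minutes from trace start
    height: float  # %DO above baseline at the apex
    rise_width: float  # minutes, onset -> apex
    decay_width: float  # minutes, apex -> return to baseline

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("spike height must be > 0")
        if self.rise_width < 1 or self.decay_width < 1:
            raise ValueError("spike widths must be >= 1 minute")
        if self.onset_index < 0:
            raise ValueError("spike onset must be >= 0")

    @property
    def end_index(self) -> float:
        return self.onset_index + self.rise_width + self.decay_width


# Relaxation constant: the shifted exponential reaches exactly zero at the end
# of decay_width while staying close to a pure exp(-3 t / decay_width) decay.
_DECAY_RATE = 3.0


def spike_profile(t: np.ndarray, spike: SpikeSpec) -> np.ndarray:
    """Evaluate the spike's additive DO contribution at times ``t`` (minutes).

    Zero outside [onset, onset + rise_width + decay_width]; linear from 0 to
    ``height`` over the rise; a zero-shifted exponential back to 0 over the
    decay.  Continuous, with its maximum exactly ``height`` at the apex.
    """
    t = np.asarray(t, dtype=float)
    rel = t - spike.onset_index
    out = np.zeros_like(rel)
    rising = (rel >= 0) & (rel < spike.rise_width)
    out[rising] = spike.height * rel[rising] / spike.rise_width
    d = rel - spike.rise_width
    decaying = (d >= 0) & (d <= spike.decay_width)
    z = d[decaying] / spike.decay_width
    shift = np.exp(-_DECAY_RATE)
    out[decaying] = spike.height * (np.exp(-_DECAY_RATE * z) - shift) / (1.0 - shift)
    return out


def generate_baseline_trajectory(
    length_min: int,
    trend_kind: str,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> BaselineTrajectory:
    """Draw one baseline trajectory of ``length_min`` minutes.

    ``stable`` baselines are a constant level plus a smooth random drift whose
    total excursion is bounded by ``params.drift_max`` (exactly constant when
    that bound is zero).  ``increasing``/``decreasing`` baselines are linear
    ramps with |slope| drawn from ``params.slope_range``.  Values are clipped
    to [0, 100], which preserves monotonicity of the ramps.
    """
    if length_min < WINDOW_LEN:
        raise ValueError(f"length_min must be >= {WINDOW_LEN}")
    if trend_kind not in TREND_KINDS:
        raise ValueError(f"unknown trend_kind {trend_kind!r}")

    level = rng.uniform(*params.level_range)
    t = np.arange(length_min, dtype=float)
    if trend_kind == "stable":
        values = np.full(length_min, level)
        if params.drift_max > 0:
            walk = np.cumsum(rng.normal(size=length_min))
            walk -= walk[0]
            peak = np.max(np.abs(walk))
            if peak > 0:
                amp = rng.uniform(0.0, params.drift_max)
                values = values + walk * (amp / peak)
    else:
        slope = rng.uniform(*params.slope_range)
        if trend_kind == "decreasing":
            slope = -slope
        values = level + slope * t
    return BaselineTrajectory(np.clip(values, 0.0, 100.0), trend_kind)


def sample_spike_train(
    length_min: int, params: GeneratorParams, rng: np.random.Generator
) -> list[SpikeSpec]:
    """Draw a non-overlapping sequence of spikes covering a trace.

    Consecutive spikes are separated by an inter-spike gap (previous spike's
    end to next onset) drawn from ``params.gap_range``; the first onset is a
    single gap draw from the trace start.
    """
    spikes: list[SpikeSpec] = []
    onset = rng.uniform(*params.gap_range)
    while onset < length_min:
        spike = SpikeSpec(
            onset_index=onset,
            height=rng.uniform(*params.spike_height_range),
            rise_width=rng.uniform(*params.rise_width_range),
            decay_width=rng.uniform(*params.decay_width_range),
        )
        spikes.append(spike)
        onset = spike.end_index + rng.uniform(*params.gap_range)
    return spikes


def superimpose_spikes(
    baseline: BaselineTrajectory,
    spikes: Sequence[SpikeSpec],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Baseline + spike train + Gaussian sensor noise, clipped to [0, 100]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(baseline.values.size, dtype=float)
    y = baseline.values.copy()
    for spike in spikes:
        y += spike_profile(t, spike)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=y.size)
    return np.clip(y, 0.0, 100.0)


@dataclass
class SyntheticDataset:
    """Labelled 60-minute DO windows: features ``X`` (n, 60) and baseline labels ``y``.

    ``trend_kind`` and ``spike_at_label`` carry per-window provenance (the
    source trace's trend and whether a spike overlaps the labelled final
    minute); they are generator bookkeeping, not model inputs.
    """

    X: np.ndarray
    y: np.ndarray
    seed: int | None = None
    generator_params: GeneratorParams | None = None
    trend_kind: np.ndarray | None = None
    spike_at_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != WINDOW_LEN:
            raise ValueError(f"X must have shape (n, {WINDOW_LEN})")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per window")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SyntheticDataset":
        return SyntheticDataset(
            self.X[idx],
            self.y[idx],
            seed=self.seed,
            generator_params=self.generator_params,
            trend_kind=None if self.trend_kind is None else self.trend_kind[idx],
            spike_at_label=None
            if self.spike_at_label is None
            else self.spike_at_label[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"do_{i:02d}": self.X[:, i] for i in range(WINDOW_LEN)}
        cols["baseline_label"] = self.y
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        """Write windows as CSV plus a JSON sidecar of seed and parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "generator_params": None
            if self.generator_params is None
            else self.generator_params.to_dict(),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SyntheticDataset":
        path = Path(path)
        df = pd.read_csv(path)
        want = [f"do_{i:02d}" for i in range(WINDOW_LEN)]
        missing = [c for c in want + ["baseline_label"] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        seed = None
        params = None
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            seed = meta.get("seed")
            if meta.get("generator_params"):
                params = GeneratorParams.from_dict(meta["generator_params"])
        return cls(
            df[want].to_numpy(), df["baseline_label"].to_numpy(), seed, params
        )


def _windows_from_trace(
    trace_rng: np.random.Generator, params: GeneratorParams, n_windows: int
):
    """Simulate one trace and slice ``n_windows`` labelled windows from it."""
    kind = TREND_KINDS[
        trace_rng.choice(len(TREND_KINDS), p=np.asarray(params.trend_weights))
    ]
    length = params.trace_length_min
    baseline = generate_baseline_trajectory(length, kind, params, trace_rng)
    spikes = sample_spike_train(length, params, trace_rng)
    noise_sd = (
        trace_rng.uniform(*params.noise_sd_range) if params.include_noise else 0.0
    )
    trace = superimpose_spikes(baseline, spikes, noise_sd, trace_rng)

    if params.overlapping_windows:
        starts = trace_rng.integers(0, length - WINDOW_LEN + 1, size=n_windows)
    else:
        n_slots = length // WINDOW_LEN
        slots = trace_rng.permutation(n_slots)[: min(n_windows, n_slots)]
        starts = slots * WINDOW_LEN
    ends = starts + WINDOW_LEN - 1
    idx = starts[:, None] + np.arange(WINDOW_LEN)[None, :]
    X = trace[idx]
    y = baseline.values[ends]
    covered = np.zeros(length, dtype=bool)
    t = np.arange(length)
    for s in spikes:
        covered |= (t >= s.onset_index) & (t <= s.end_index)
    return X, y, kind, covered[ends]


def generate_dataset(
    n: int, params: GeneratorParams | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate ``n`` labelled windows (default corpus size: 15,000).

    Windows are cut from long simulated traces (``params.windows_per_trace``
    windows per trace) so that partial spikes can appear at window edges, as in
    streaming deployment.  Per-trace random streams are spawned from the master
    seed, so the dataset is a pure function of ``(n, params, seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or GeneratorParams()
    wpt = params.windows_per_trace
    n_traces = -(-n // wpt)
    children = np.random.SeedSequence(seed).spawn(n_traces)
    Xs, ys, kinds, spiked = [], [], [], []
    for i in range(n_traces):
        k = min(wpt, n - i * wpt)
        X, y, kind, sp = _windows_from_trace(
            np.random.default_rng(children[i]), params, k
        )
        Xs.append(X)
        ys.append(y)
        kinds.extend([kind] * k)
        spiked.append(sp)
    return SyntheticDataset(
        np.concatenate(Xs),
        np.concatenate(ys),
        seed=seed,
        generator_params=params,
        trend_kind=np.asarray(kinds),
        spike_at_label=np.concatenate(spiked),
    )


def split_dataset(
    ds: SyntheticDataset, ratio: float, seed: int = 0
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Shuffled disjoint split; the first part gets ``floor(n * ratio)`` windows."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(ds)
    perm = np.random.default_rng(seed).permutation(n)
    n_first = int(n * ratio)
    return ds.subset(np.sort(perm[:n_first])), ds.subset(np.sort(perm[n_first:]))
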
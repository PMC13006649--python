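"""Baseline-relative DO-stat control logic.

The controller consumes one DO sensor sample per second, aggregates samples
into a 60-minute sliding window of one-minute means, and once per minute runs
the recognition model on the window to obtain the raw baseline, which a causal
Savitzky-Golay filter turns into ``baseline_smooth``.  All decisions are made
relative to that smoothed baseline:

* **Oxygen supply** (evaluated once per minute): when ``baseline_smooth``
  falls below ``baseline_lb`` the broth is judged oxygen-deficient and
  agitation/aeration are stepped up (+20 rpm, +0.05 L/min by default); when it
  exceeds ``baseline_ub`` they are stepped down; both clamped to configured
  limits.  Steps are rate-limited to one per ``o2_cooldown_min`` minutes
  (default 10).  Stepping every minute while the bound is violated is unstable
  under recognition lag: the recogniser, by design, attributes a steep
  supply-driven DO climb to a depletion spike rather than to a baseline shift,
  so the smoothed baseline stays below the bound, the controller keeps
  stepping, and the widening DO-baseline gap eventually crosses the feed-start
  threshold and triggers feeding into a glucose-rich broth.  The cooldown
  gives the recogniser time to absorb each new oxygen-supply plateau into the
  baseline before the next step fires.
* **Glucose feeding** (every second): a pulse starts when the real-time DO
  rises above ``baseline_smooth + threshold_increase`` (glucose depleted) and
  stops when it falls below ``baseline_smooth + baseline_increase``; a pulse
  lasting a full ``max_pulse_duration`` (3 min) is forcibly stopped regardless
  of DO, guarding against sensor-delay overfeeding.
* **Nitrogen feeding**: latched on at a fixed rate from the first glucose
  trigger onward, never switched off.
* **Induction** (one-shot): when runtime exceeds ``induction_time`` the IPTG
  dose is fired, the temperature setpoint drops 37 -> 28 degC, and the
  induction-phase parameter set (``baseline_increase``, ``threshold_increase``,
  ``v_glc``) replaces the growth-phase set.

All threshold comparisons are strict; ties produce no action.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mlp import TrainedBaselineModel
from .plant import PlantParams, PlantState, SimulationError, step_plant
from .smoothing import CausalSavitzkyGolay
from .synth import WINDOW_LEN

__all__ = [
    "ControllerParams",
    "PhaseParamSet",
    "ProcessSample",
    "ActuatorCommand",
    "Controller",
    "OrderingError",
    "ClosedLoopResult",
    "run_closed_loop",
]


class OrderingError(ValueError):
    """Samples must arrive in strictly increasing time order."""


@dataclass(frozen=True)
class ControllerParams:
    """Named setpoints of one control phase (units in field comments)."""

    baseline_lb: float = 25.0  # %DO: below -> oxygen-deficient
    baseline_ub: float = 50.0  # %DO: above -> oxygen-excessive
    baseline_increase: float = 15.0  # %DO above baseline_smooth: feed stop
    threshold_increase: float = 40.0  # %DO above baseline_smooth: feed start
    v_glc: float = 21.0  # g glucose / L broth / h while pulsing
    v_ns: float = 1.0  # g yeast extract / L broth / h, latched
    induction_time: float = 10.0  # h
    agitate_step: float = 20.0  # rpm per oxygen adjustment
    air_step: float = 0.05  # L/min per oxygen adjustment
    agitate_min: float = 400.0  # rpm (initial manual setting)
    agitate_max: float = 800.0  # rpm (process maximum)
    air_min: float = 0.5  # L/min (initial manual setting)
    air_max: float = 1.5  # L/min (process maximum)
    max_pulse_duration: float = 3.0  # min, forced feed stop
    iptg_dose_mmol_per_l: float = 0.3  # practical optimum dose

    def __post_init__(self) -> None:
        if not self.baseline_lb < self.baseline_ub:
            raise ValueError("baseline_lb must be < baseline_ub")
        if not self.threshold_increase > self.baseline_increase >= 0:
            raise ValueError("need threshold_increase > baseline_increase >= 0")
        if self.v_glc <= 0:
            raise ValueError("v_glc must be > 0")
        if self.max_pulse_duration <= 0:
            raise ValueError("max_pulse_duration must be > 0")


@dataclass(frozen=True)
class PhaseParamSet:
    """Growth-phase and induction-phase parameter sets."""

    growth: ControllerParams
    induction: ControllerParams

    @classmethod
    def with_induction_overrides(
        cls,
        growth: ControllerParams,
        baseline_increase: float,
        threshold_increase: float,
        v_glc: float,
    ) -> "PhaseParamSet":
        """Induction set = growth set with the three feeding setpoints swapped."""
        return cls(
            growth,
            replace(
                growth,
                baseline_increase=baseline_increase,
                threshold_increase=threshold_increase,
                v_glc=v_glc,
            ),
        )


@dataclass(frozen=True)
class ProcessSample:
    """One per-second acquisition: runtime (h), DO reading (% air saturation)."""

    timestamp: float  # s since inoculation
    do_realtime: float  # % air saturation

    @property
    def runtime(self) -> float:
        return self.timestamp / 3600.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.do_realtime <= 100.0:
            raise ValueError("do_realtime must be within [0, 100] % air saturation")


@dataclass
class ActuatorCommand:
    agitate_rate: float  # rpm
    air_flow: float  # L/min
    glucose_pump_on: bool = False
    nitrogen_pump_on: bool = False
    temperature_setpoint: float = 37.0  # degC
    iptg_dose_mmol_per_l: float = 0.0  # one-shot dose command
    feed_pulse_elapsed: float = 0.0  # min since current pulse started


# baseline_increase == 0 ties the feed-stop threshold to baseline_smooth itself

class Controller:
    """Stateful NeuroStat-Ctrl decision engine (one instance per batch)."""

    def __init__(
        self,
        model: TrainedBaselineModel,
        smoother: CausalSavitzkyGolay | None = None,
        phase_params: PhaseParamSet | None = None,
        minute_aggregation: str = "mean",
        o2_cooldown_min: float = 10.0,
    ) -> None:
        if minute_aggregation not in ("mean", "last"):
            raise ValueError("minute_aggregation must be 'mean' or 'last'")
        if o2_cooldown_min < 1.0:
            raise ValueError("o2_cooldown_min must be >= 1 minute")
        self.o2_cooldown_min = o2_cooldown_min
        self._last_o2_step_s: float | None = None
        self.model = model
        self.smoother = smoother or CausalSavitzkyGolay()
        self.phase_params = phase_params or PhaseParamSet.with_induction_overrides(
            ControllerParams(), baseline_increase=5.0, threshold_increase=10.0, v_glc=7.0
        )
        self.minute_aggregation = minute_aggregation

        self.phase = "growth"
        self.minute_values: deque[float] = deque(maxlen=WINDOW_LEN)
        self._second_buffer: list[float] = []
        self._current_minute: int | None = None
        self._last_time: float | None = None
        self.raw_baseline: float | None = None
        self.baseline_smooth: float | None = None
        self.feeding_active = False
        self.nitrogen_started = False
        self.induced = False
        self._pulse_start_s: float | None = None
        self.actuators = ActuatorCommand(
            agitate_rate=self.params.agitate_min, air_flow=self.params.air_min
        )
        self.event_log: list[dict] = []

    @property
    def params(self) -> ControllerParams:
        return getattr(self.phase_params, self.phase)

    def _log(self, t: float, event: str, **detail) -> None:
        self.event_log.append({"time_s": t, "event": event, **detail})

    # ------------------------------------------------------------------ ingest

    def ingest_sample(self, sample: ProcessSample) -> ActuatorCommand:
        """Process one per-second sample; returns the current actuator command."""
        if self._last_time is not None and sample.timestamp <= self._last_time:
            raise OrderingError(
                f"sample at t={sample.timestamp}s not after t={self._last_time}s"
            )
        self._last_time = sample.timestamp
        minute = int(sample.timestamp // 60)
        if self._current_minute is None:
            self._current_minute = minute
        elif minute > self._current_minute:
            self._finish_minute(sample.timestamp)
            self._current_minute = minute
        self._second_buffer.append(sample.do_realtime)

        # per-second decisions
        self.decide_induction(sample)
        self.decide_glucose_feed(sample)
        self.decide_nitrogen_feed(sample)
        return self.actuators

    def _finish_minute(self, now_s: float) -> None:
        if not self._second_buffer:
            return
        if self.minute_aggregation == "mean":
            value = float(np.mean(self._second_buffer))
        else:
            value = float(self._second_buffer[-1])
        self._second_buffer.clear()
        self.minute_values.append(value)
        self.update_baseline(now_s)
        self.decide_oxygen(now_s)

    # ----------------------------------------------------------- per minute

    def update_baseline(self, now_s: float) -> None:
        """Run the MLP + smoother once per completed minute (after warm-up)."""
        if len(self.minute_values) < WINDOW_LEN:
            return
        self.raw_baseline = float(
            self.model.predict(np.asarray(self.minute_values))
        )
        self.baseline_smooth = self.smoother.update(self.raw_baseline)
        self._log(
            now_s,
            "baseline_update",
            raw=self.raw_baseline,
            smooth=self.baseline_smooth,
        )

    def decide_oxygen(self, now_s: float) -> None:
        if self.baseline_smooth is None:
            return
        p = self.params
        a = self.actuators
        outside = (
            self.baseline_smooth < p.baseline_lb
            or self.baseline_smooth > p.baseline_ub
        )
        if not outside:
            return
        if (
            self._last_o2_step_s is not None
            and now_s - self._last_o2_step_s < self.o2_cooldown_min * 60.0 - 1e-9
        ):
            return
        self._last_o2_step_s = now_s
        if self.baseline_smooth < p.baseline_lb:
            new_rpm = min(a.agitate_rate + p.agitate_step, p.agitate_max)
            new_air = min(a.air_flow + p.air_step, p.air_max)
            if (new_rpm, new_air) != (a.agitate_rate, a.air_flow):
                a.agitate_rate, a.air_flow = new_rpm, new_air
                self._log(now_s, "oxygen_up", agitate_rpm=new_rpm, air_lpm=new_air)
        else:
            new_rpm = max(a.agitate_rate - p.agitate_step, p.agitate_min)
            new_air = max(a.air_flow - p.air_step, p.air_min)
            if (new_rpm, new_air) != (a.agitate_rate, a.air_flow):
                a.agitate_rate, a.air_flow = new_rpm, new_air
                self._log(now_s, "oxygen_down", agitate_rpm=new_rpm, air_lpm=new_air)

    # ----------------------------------------------------------- per second

    def decide_glucose_feed(self, sample: ProcessSample) -> None:
        if self.baseline_smooth is None:
            return
        p = self.params
        t = sample.timestamp
        if self.feeding_active:
            elapsed_min = (t - self._pulse_start_s) / 60.0
            self.actuators.feed_pulse_elapsed = elapsed_min
            if elapsed_min >= p.max_pulse_duration:
                self._stop_feed(t, forced=True)
            elif sample.do_realtime < self.baseline_smooth + p.baseline_increase:
                self._stop_feed(t, forced=False)
        else:
            if sample.do_realtime > self.baseline_smooth + p.threshold_increase:
                self.feeding_active = True
                self._pulse_start_s = t
                self.actuators.glucose_pump_on = True
                self.actuators.feed_pulse_elapsed = 0.0
                if not self.nitrogen_started:
                    self.nitrogen_started = True
                    self._log(t, "nitrogen_start", v_ns=p.v_ns)
                self._log(
                    t,
                    "feed_start",
                    do=sample.do_realtime,
                    baseline_smooth=self.baseline_smooth,
                    v_glc=p.v_glc,
                )

    def _stop_feed(self, t: float, forced: bool) -> None:
        duration_min = (t - self._pulse_start_s) / 60.0
        self.feeding_active = False
        self.actuators.glucose_pump_on = False
        self.actuators.feed_pulse_elapsed = 0.0
        self._pulse_start_s = None
        self._log(
            t,
            "feed_stop_forced" if forced else "feed_stop",
            duration_min=duration_min,
        )

    def decide_nitrogen_feed(self, sample: ProcessSample) -> None:
        # latch: on from the first glucose trigger, never off again
        self.actuators.nitrogen_pump_on = self.nitrogen_started

    def decide_induction(self, sample: ProcessSample) -> None:
        if self.induced:
            return
        if sample.runtime > self.params.induction_time:
            self.induced = True
            self.phase = "induction"
            self.actuators.temperature_setpoint = 28.0
            self.actuators.iptg_dose_mmol_per_l = self.params.iptg_dose_mmol_per_l
            self._log(
                sample.timestamp,
                "induction",
                iptg_mmol_per_l=self.actuators.iptg_dose_mmol_per_l,
                temperature_c=28.0,
            )


@dataclass
class ClosedLoopResult:
    """Trajectory and event log of a closed-loop run."""

    trajectory: pd.DataFrame
    events: list[dict]
    controller: Controller
    final_plant_state: PlantState

    def feed_pulses(self) -> pd.DataFrame:
        """Start/stop times and durations (min) of every glucose pulse."""
        pulses = []
        start = None
        for ev in self.events:
            if ev["event"] == "feed_start":
                start = ev["time_s"]
            elif ev["event"] in ("feed_stop", "feed_stop_forced") and start is not None:
                pulses.append(
                    {
                        "start_s": start,
                        "stop_s": ev["time_s"],
                        "duration_min": ev["duration_min"],
                        "forced": ev["event"] == "feed_stop_forced",
                    }
                )
                start = None
        return pd.DataFrame(pulses, columns=["start_s", "stop_s", "duration_min", "forced"])

    def write_csv(self, path) -> None:
        self.trajectory.to_csv(path, index=False)

    def plot(self, ax=None):
        """Plot DO, smoothed baseline, residual glucose and agitation vs time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        t = self.trajectory.time_s / 3600.0
        ax.plot(t, self.trajectory.do_realtime, lw=0.5, label="DO (%)")
        ax.plot(t, self.trajectory.baseline_smooth, lw=1.5, label="baseline_smooth (%)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("% air saturation")
        ax2 = ax.twinx()
        ax2.plot(t, self.trajectory.glucose_g_l, color="tab:red", lw=0.8,
                 label="glucose (g/L)")
        ax2.set_ylabel("glucose (g/L)")
        ax.legend(loc="upper left")
        ax2.legend(loc="upper right")
        return ax


def run_closed_loop(
    plant: PlantParams,
    model: TrainedBaselineModel,
    smoother: CausalSavitzkyGolay | None = None,
    phase_params: PhaseParamSet | None = None,
    duration_h: float = 24.0,
    seed: int = 0,
    record_every_s: int = 1,
    o2_cooldown_min: float = 10.0,
) -> ClosedLoopResult:
    """Simulate the plant under full NeuroStat-Ctrl control at 1-s resolution.

    Each second the plant advances one Euler step, the sensor reading is fed
    to the controller, and the controller's actuator command is applied to the
    next step.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    ctrl = Controller(model, smoother, phase_params, o2_cooldown_min=o2_cooldown_min)
    state = PlantState.initial(plant)
    n = int(duration_h * 3600)
    cols = (
        "time_s do_realtime raw_baseline baseline_smooth agitate_rpm air_lpm "
        "glc_pump ns_pump temp_c glucose_g_l biomass volume_l feeding"
    ).split()
    n_rec = n // record_every_s
    rec = {c: np.full(n_rec, np.nan) for c in cols}
    k = 0
    act = ctrl.actuators
    for i in range(n):
        p = ctrl.params
        state = step_plant(
            state,
            plant,
            1.0,
            rng,
            glucose_feed_rate=p.v_glc if act.glucose_pump_on else 0.0,
            nitrogen_feed_rate=p.v_ns if act.nitrogen_pump_on else 0.0,
            agitate_rpm=act.agitate_rate,
            air_lpm=act.air_flow,
        )
        sample = ProcessSample(timestamp=state.time, do_realtime=state.sensor_do)
        act = ctrl.ingest_sample(sample)
        if (i + 1) % record_every_s == 0 and k < n_rec:
            rec["time_s"][k] = state.time
            rec["do_realtime"][k] = state.sensor_do
            rec["raw_baseline"][k] = math.nan if ctrl.raw_baseline is None else ctrl.raw_baseline
            rec["baseline_smooth"][k] = (
                math.nan if ctrl.baseline_smooth is None else ctrl.baseline_smooth
            )
            rec["agitate_rpm"][k] = act.agitate_rate
            rec["air_lpm"][k] = act.air_flow
            rec["glc_pump"][k] = float(act.glucose_pump_on)
            rec["ns_pump"][k] = float(act.nitrogen_pump_on)
            rec["temp_c"][k] = act.temperature_setpoint
            rec["glucose_g_l"][k] = state.glucose
            rec["biomass"][k] = state.biomass
            rec["volume_l"][k] = state.volume
            rec["feeding"][k] = float(ctrl.feeding_active)
            k += 1
    return ClosedLoopResult(
        trajectory=pd.DataFrame(rec),
        events=ctrl.event_log,
        controller=ctrl,
        final_plant_state=state,
    )
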
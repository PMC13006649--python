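"""Controller decision rules: the verbatim DO-stat decision table.

Oxygen steps of +-20 rpm / +-0.05 L/min against the baseline band, feed
start above baseline_smooth + threshold_increase, feed stop below
baseline_smooth + baseline_increase, the 3-minute forced stop, the nitrogen
latch at 1.0 g/L/h and the one-shot induction with the 37 -> 28 degC shift.
"""

import numpy as np
import pytest

from neurostat.controller import (
    ActuatorCommand,
    Controller,
    ControllerParams,
    OrderingError,
    PhaseParamSet,
    ProcessSample,
)
from neurostat.smoothing import CausalSavitzkyGolay


class StubModel:
    """Recognition stub: reports the window's final value as the baseline."""

    def predict(self, window):
        return np.asarray(window, dtype=float)[-1]


def make_controller(**growth_overrides) -> Controller:
    growth = ControllerParams(**growth_overrides)
    phases = PhaseParamSet.with_induction_overrides(
        growth, baseline_increase=0.0, threshold_increase=10.0, v_glc=7.0
    )
    return Controller(StubModel(), CausalSavitzkyGolay(5, 1), phases)


def prime(ctrl: Controller, baseline: float, t0: float = 3600.0) -> Controller:
    """Skip warm-up: install a smoothed baseline directly."""
    ctrl.baseline_smooth = baseline
    ctrl.raw_baseline = baseline
    ctrl._last_time = t0 - 1
    return ctrl


class TestOxygenControl:
    def test_deficiency_steps_up(self):
        ctrl = prime(make_controller(), baseline=20.0)
        assert (ctrl.actuators.agitate_rate, ctrl.actuators.air_flow) == (400.0, 0.5)
        ctrl.decide_oxygen(3600)
        assert ctrl.actuators.agitate_rate == 420.0
        assert ctrl.actuators.air_flow == pytest.approx(0.55)

    def test_excess_steps_down(self):
        ctrl = prime(make_controller(), baseline=55.0)
        ctrl.actuators.agitate_rate, ctrl.actuators.air_flow = 420.0, 0.55
        ctrl.decide_oxygen(3600)
        assert ctrl.actuators.agitate_rate == 400.0
        assert ctrl.actuators.air_flow == pytest.approx(0.50)

    def test_dead_band_no_change(self):
        ctrl = prime(make_controller(), baseline=35.0)
        ctrl.actuators.agitate_rate, ctrl.actuators.air_flow = 500.0, 0.7
        ctrl.decide_oxygen(3600)
        assert (ctrl.actuators.agitate_rate, ctrl.actuators.air_flow) == (500.0, 0.7)

    def test_clamped_at_limits(self):
        ctrl = prime(make_controller(), baseline=10.0)
        ctrl.actuators.agitate_rate, ctrl.actuators.air_flow = 790.0, 1.48
        ctrl.decide_oxygen(3600)
        assert ctrl.actuators.agitate_rate == 800.0
        assert ctrl.actuators.air_flow == 1.5
        ctrl2 = prime(make_controller(), baseline=60.0)
        ctrl2.decide_oxygen(3600)  # already at minima
        assert (ctrl2.actuators.agitate_rate, ctrl2.actuators.air_flow) == (400.0, 0.5)


class TestGlucoseFeed:
    def test_start_above_threshold(self):
        # baseline 25, threshold_increase 40: DO 66 > 65 starts the pulse
        ctrl = prime(make_controller(), baseline=25.0)
        ctrl.decide_glucose_feed(ProcessSample(3600, 66.0))
        assert ctrl.feeding_active and ctrl.actuators.glucose_pump_on

    def test_tie_produces_no_action(self):
        ctrl = prime(make_controller(), baseline=25.0)
        ctrl.decide_glucose_feed(ProcessSample(3600, 65.0))  # exactly at threshold
        assert not ctrl.feeding_active

    def test_stop_below_baseline_increase(self):
        # baseline 25, baseline_increase 15: DO 39 < 40 stops the pulse
        ctrl = prime(make_controller(), baseline=25.0)
        ctrl.decide_glucose_feed(ProcessSample(3600, 66.0))
        ctrl.decide_glucose_feed(ProcessSample(3610, 39.0))
        assert not ctrl.feeding_active and not ctrl.actuators.glucose_pump_on
        stop = [e for e in ctrl.event_log if e["event"] == "feed_stop"]
        assert len(stop) == 1

    def test_forced_stop_after_three_minutes(self):
        ctrl = prime(make_controller(), baseline=25.0)
        t = 3600.0
        ctrl.decide_glucose_feed(ProcessSample(t, 70.0))
        for dt in range(1, 181):  # DO stuck high for 3 min
            ctrl.decide_glucose_feed(ProcessSample(t + dt, 70.0))
        assert not ctrl.feeding_active
        assert any(e["event"] == "feed_stop_forced" for e in ctrl.event_log)
        stop = next(e for e in ctrl.event_log if e["event"] == "feed_stop_forced")
        assert stop["duration_min"] == pytest.approx(3.0, abs=1 / 60)

    def test_no_decision_during_warmup(self):
        ctrl = make_controller()  # baseline_smooth is None
        ctrl.decide_glucose_feed(ProcessSample(30.0, 95.0))
        assert not ctrl.feeding_active


class TestNitrogenLatch:
    def test_off_before_first_trigger(self):
        ctrl = prime(make_controller(), baseline=25.0)
        ctrl.decide_nitrogen_feed(ProcessSample(3600, 30.0))
        assert not ctrl.actuators.nitrogen_pump_on

    def test_latched_on_first_glucose_trigger_and_stays_on(self):
        ctrl = prime(make_controller(), baseline=25.0)
        ctrl.decide_glucose_feed(ProcessSample(3600, 66.0))
        ctrl.decide_nitrogen_feed(ProcessSample(3600, 66.0))
        assert ctrl.actuators.nitrogen_pump_on
        assert any(e["event"] == "nitrogen_start" for e in ctrl.event_log)
        # pulse ends; nitrogen stays on
        ctrl.decide_glucose_feed(ProcessSample(3610, 39.0))
        ctrl.decide_nitrogen_feed(ProcessSample(3610, 39.0))
        assert ctrl.actuators.nitrogen_pump_on
        assert ctrl.params.v_ns == 1.0


class TestInduction:
    def test_strictly_after_induction_time(self):
        ctrl = make_controller(induction_time=10.0)
        ctrl.decide_induction(ProcessSample(9.99 * 3600, 50.0))
        assert not ctrl.induced
        assert ctrl.actuators.temperature_setpoint == 37.0

    def test_one_shot_dose_temperature_and_phase_switch(self):
        ctrl = make_controller(induction_time=10.0)
        ctrl.decide_induction(ProcessSample(10.0 * 3600 + 1, 50.0))
        assert ctrl.induced
        assert ctrl.phase == "induction"
        assert ctrl.actuators.temperature_setpoint == 28.0
        assert ctrl.actuators.iptg_dose_mmol_per_l == pytest.approx(0.3)
        # induction parameter set is live: baseline_increase 0, v_glc 7
        assert ctrl.params.baseline_increase == 0.0
        assert ctrl.params.threshold_increase == 10.0
        assert ctrl.params.v_glc == 7.0

    def test_no_second_dose(self):
        ctrl = make_controller(induction_time=10.0)
        ctrl.decide_induction(ProcessSample(10.0 * 3600 + 1, 50.0))
        ctrl.decide_induction(ProcessSample(12.0 * 3600, 50.0))
        doses = [e for e in ctrl.event_log if e["event"] == "induction"]
        assert len(doses) == 1


class TestIngest:
    def test_minute_aggregate_is_mean(self):
        ctrl = make_controller()
        for s in range(60):
            ctrl.ingest_sample(ProcessSample(float(s), 30.0))
        # rollover happens on the first sample of the next minute
        ctrl.ingest_sample(ProcessSample(60.0, 50.0))
        assert len(ctrl.minute_values) == 1
        assert ctrl.minute_values[0] == pytest.approx(30.0)

    def test_mean_of_mixed_samples(self):
        ctrl = make_controller()
        ctrl.ingest_sample(ProcessSample(0.0, 20.0))
        ctrl.ingest_sample(ProcessSample(1.0, 40.0))
        ctrl.ingest_sample(ProcessSample(60.0, 99.0))
        assert ctrl.minute_values[-1] == pytest.approx(30.0)

    def test_window_trimmed_to_sixty_minutes(self):
        ctrl = make_controller()
        t = 0.0
        for minute in range(62):
            ctrl.ingest_sample(ProcessSample(t, float(minute % 100)))
            t += 60.0
        assert len(ctrl.minute_values) == 60

    def test_out_of_order_sample_rejected(self):
        ctrl = make_controller()
        ctrl.ingest_sample(ProcessSample(10.0, 30.0))
        with pytest.raises(OrderingError):
            ctrl.ingest_sample(ProcessSample(9.0, 30.0))
        with pytest.raises(OrderingError):
            ctrl.ingest_sample(ProcessSample(10.0, 30.0))

    def test_baseline_update_cadence_after_warmup(self):
        ctrl = make_controller()
        t = 0.0
        for minute in range(130):  # ~2.2 h of one-sample minutes
            ctrl.ingest_sample(ProcessSample(t, 30.0))
            t += 60.0
        updates = [e for e in ctrl.event_log if e["event"] == "baseline_update"]
        # one update per completed minute once the 60-min window is full
        assert len(updates) == 130 - 60
        assert ctrl.raw_baseline == pytest.approx(30.0, abs=1e-9)

    def test_invalid_sample_rejected(self):
        with pytest.raises(ValueError):
            ProcessSample(0.0, 101.0)
        with pytest.raises(ValueError):
            ProcessSample(0.0, -1.0)


class TestParamValidation:
    def test_bounds_and_orderings(self):
        with pytest.raises(ValueError):
            ControllerParams(baseline_lb=50, baseline_ub=25)
        with pytest.raises(ValueError):
            ControllerParams(baseline_increase=45, threshold_increase=40)
        with pytest.raises(ValueError):
            ControllerParams(v_glc=0)
        with pytest.raises(ValueError):
            ControllerParams(max_pulse_duration=0)
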
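"""Minimal fed-batch *E. coli* plant model for closed-loop controller exercise.

This simulator is openly synthetic: its job is to produce realistic DO-stat
dynamics — glucose-limited Monod growth, oxygen transfer against cellular
uptake, sharp DO spikes on glucose depletion, volume increase with feeding,
and a lagged, noisy DO sensor — so the controller and recognition model can be
exercised closed-loop without a bioreactor.  It is not a predictive model of
*E. coli* physiology; every kinetic constant is configuration.

State (per litre of broth): biomass X (g/L), glucose S (g/L), dissolved
oxygen DO (% air saturation), volume V (L).  Explicit-Euler update at dt <= 1 s:

    mu   = mu_max * S / (Ks + S) * DO / (Ko + DO)
    dX   = mu X dt - X (F/V) dt
    dS   = (-mu X / Yxs + F c_feed / V - S F/V) dt
    dDO  = [ kLa(rpm, air) (do_sat - DO) - OUR ] dt
    OUR  = yo * (mu X / Yxs) / c_o2_sat * 100      (%DO per hour)
    kLa  = kla_a * (rpm/400)^kla_b * (air/0.5)^kla_c

where F is the feed pump flow (L/h) delivering 500 g/L glucose stock.  The
DO Monod term makes growth oxygen-limited once biomass outgrows the oxygen
transfer capacity, which caps glucose uptake at the transfer limit — this is
what keeps depletion-spike periods in the minutes range (instead of collapsing
to seconds) as biomass accumulates, as in a real oxygen-transfer-bounded
reactor.  The sensor reading is a first-order lag of the true DO plus
Gaussian noise, clipped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PlantParams", "PlantState", "SimulationError", "step_plant", "run_open_loop"]

FEED_GLUCOSE_G_PER_L = 500.0  # feed stock concentration


class SimulationError(RuntimeError):
    """Plant state became non-finite; carries the last valid state."""

    def __init__(self, message: str, last_state: "PlantState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class PlantParams:
    """Kinetic, transfer and sensor constants of the synthetic plant.

    Defaults produce growth-phase depletion-spike periods of roughly 3-15
    minutes under the default feeding parameters — the cadence of DO-stat
    operation — compressing to small, frequent top-up pulses once the tight
    induction-phase thresholds take over; initial conditions are a 10 g/L
    glucose batch in 0.7 L.  The inoculum is sized so the dissolved-oxygen
    decline stays gentle until the controller's 60-minute window has warmed
    up; a steeper early crash would force the oxygen loop into a sustained
    ramp that the baseline recogniser would read as a depletion spike.
    """

    mu_max: float = 0.6  # 1/h
    Ks: float = 0.05  # g/L
    Ko: float = 5.0  # %DO half-saturation of oxygen-limited growth
    Yxs: float = 0.5  # g biomass / g glucose
    yo: float = 0.8  # g O2 / g glucose consumed
    c_o2_sat: float = 0.0075  # g O2 / L at saturation (~37 C broth)
    kla_a: float = 50.0  # 1/h at 400 rpm, 0.5 L/min
    kla_b: float = 2.0  # agitation exponent
    kla_c: float = 0.4  # aeration exponent
    do_sat: float = 100.0  # % air saturation
    feed_glucose: float = FEED_GLUCOSE_G_PER_L
    initial_biomass: float = 0.12  # g/L after inoculation
    initial_glucose: float = 10.0  # g/L batch glucose
    initial_do: float = 100.0  # % air saturation
    initial_volume: float = 0.7  # L
    sensor_noise_sd: float = 0.3  # %DO
    sensor_lag_tau: float = 30.0  # s

    def kla(self, agitate_rpm: float, air_lpm: float) -> float:
        """Volumetric O2 transfer coefficient (1/h); monotone in both inputs."""
        return (
            self.kla_a
            * (max(agitate_rpm, 1e-9) / 400.0) ** self.kla_b
            * (max(air_lpm, 1e-9) / 0.5) ** self.kla_c
        )


@dataclass
class PlantState:
    biomass: float  # g/L
    glucose: float  # g/L
    do_percent: float  # true dissolved oxygen, % air saturation
    volume: float  # L
    time: float = 0.0  # s
    sensor_do: float | None = None  # lagged + noisy reading, % air saturation

    def __post_init__(self) -> None:
        if self.sensor_do is None:
            self.sensor_do = self.do_percent

    @classmethod
    def initial(cls, params: PlantParams) -> "PlantState":
        return cls(
            biomass=params.initial_biomass,
            glucose=params.initial_glucose,
            do_percent=params.initial_do,
            volume=params.initial_volume,
        )


def step_plant(
    state: PlantState,
    params: PlantParams,
    dt: float,
    rng: np.random.Generator,
    glucose_feed_rate: float = 0.0,  # V_glc, g glucose / L broth / h
    nitrogen_feed_rate: float = 0.0,  # g / L broth / h (volume effect only)
    agitate_rpm: float = 400.0,
    air_lpm: float = 0.5,
) -> PlantState:
    """Advance the plant by ``dt`` seconds (explicit Euler; ``dt`` <= 1 s)."""
    if dt <= 0 or dt > 1.0:
        raise ValueError("dt must be in (0, 1] second for Euler stability")
    dt_h = dt / 3600.0
    X, S, DO, V = state.biomass, state.glucose, state.do_percent, state.volume

    mu = (
        params.mu_max * S / (params.Ks + S) * DO / (params.Ko + DO)
        if S > 0
        else 0.0
    )
    qs = mu * X / params.Yxs  # g glucose / L / h
    # pump flows (L/h) delivering v g glucose (or nitrogen mass) per L broth per h
    F_glc = glucose_feed_rate * V / params.feed_glucose
    F_ns = nitrogen_feed_rate * V / 100.0  # 100 g/L yeast-extract stock
    F = F_glc + F_ns
    D = F / V  # dilution rate, 1/h

    kla = params.kla(agitate_rpm, air_lpm)
    our = params.yo * qs / params.c_o2_sat * 100.0  # %DO / h

    X_new = X + (mu * X - D * X) * dt_h
    S_new = S + (-qs + F_glc * params.feed_glucose / V - D * S) * dt_h
    DO_new = DO + (kla * (params.do_sat - DO) - our) * dt_h
    V_new = V + F * dt_h

    X_new = max(X_new, 0.0)
    S_new = max(S_new, 0.0)
    DO_new = min(max(DO_new, 0.0), 100.0)

    # first-order sensor lag + Gaussian noise; the noiseless lagged value is
    # carried separately so noise does not integrate into the lag state
    alpha = dt / (params.sensor_lag_tau + dt) if params.sensor_lag_tau > 0 else 1.0
    prev_lagged = getattr(state, "_lagged", state.sensor_do)
    lagged = prev_lagged + alpha * (DO_new - prev_lagged)
    noise = rng.normal(0.0, params.sensor_noise_sd) if params.sensor_noise_sd > 0 else 0.0
    sensor = min(max(lagged + noise, 0.0), 100.0)

    new = PlantState(
        biomass=X_new,
        glucose=S_new,
        do_percent=DO_new,
        volume=V_new,
        time=state.time + dt,
        sensor_do=sensor,
    )
    new._lagged = lagged
    if not all(
        math.isfinite(v) for v in (X_new, S_new, DO_new, V_new, sensor)
    ):
        raise SimulationError(f"non-finite plant state at t={state.time}s", state)
    return new


def run_open_loop(
    params: PlantParams,
    actuator_schedule,
    duration_s: float,
    seed: int = 0,
    dt: float = 1.0,
):
    """Run the plant under a fixed actuator schedule; returns a record dict.

    ``actuator_schedule(t_seconds)`` must return a mapping with keys
    ``glucose_feed_rate``, ``nitrogen_feed_rate``, ``agitate_rpm``,
    ``air_lpm`` (missing keys default to off / initial oxygen settings).
    """
    rng = np.random.default_rng(seed)
    state = PlantState.initial(params)
    n = int(duration_s / dt)
    rec = {
        k: np.empty(n)
        for k in ("time_s", "do_true", "do_sensor", "glucose", "biomass", "volume")
    }
    for i in range(n):
        act = dict(actuator_schedule(state.time))
        state = step_plant(
            state,
            params,
            dt,
            rng,
            glucose_feed_rate=act.get("glucose_feed_rate", 0.0),
            nitrogen_feed_rate=act.get("nitrogen_feed_rate", 0.0),
            agitate_rpm=act.get("agitate_rpm", 400.0),
            air_lpm=act.get("air_lpm", 0.5),
        )
        rec["time_s"][i] = state.time
        rec["do_true"][i] = state.do_percent
        rec["do_sensor"][i] = state.sensor_do
        rec["glucose"][i] = state.glucose
        rec["biomass"][i] = state.biomass
        rec["volume"][i] = state.volume
    return rec
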
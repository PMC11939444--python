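"""Thermal budget and PID/PWM hot-water temperature regulation.

Two independent questions about sample heating are answered here.

First, a worst-case lossless budget: if every joule of the incident RF
power flux were retained by the liquid in the dish, how much would it
warm over the exposure?  ``delta_t_budget`` evaluates

    dT = P_EMG * Surf_petri * dt / (C * V)

with the duration in hours and the volumetric heat capacity in
Wh/(m^3 K), so the result is in kelvin.

Second, the box's temperature regulation: a PT100 sensor feeds a PID
controller whose output sets the duty cycle of a 5 s PWM signal driving
a hot-water pump.  The loop is simulated against a first-order-plus-
dead-time (FOPDT) plant; controller gains come from Internal Model
Control (IMC) tuning; hood openings (sample insertion/removal) appear
as transient disturbances on the sensed air temperature.  The module
also identifies FOPDT parameters back from a recorded step response, so
simulated plants can be recovered and scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

#: Volumetric heat capacity of water, Wh/(m^3 K).
WATER_HEAT_CAPACITY_WH_M3K = 1160.0
#: Typical volumetric heat capacity of kidney tissue, Wh/(m^3 K).
KIDNEY_HEAT_CAPACITY_WH_M3K = 1012.0


# ---------------------------------------------------------------------------
# lossless heating budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalBudget:
    """Inputs of the lossless radiative-heating budget.

    Units are part of the contract: duration in hours, heat capacity in
    Wh/(m^3 K), so no hidden conversions occur.
    """

    dish_diameter_m: float
    incident_power_w_per_m2: float
    duration_h: float
    heat_capacity_wh_per_m3k: float
    volume_m3: float

    def __post_init__(self) -> None:
        for name in ("dish_diameter_m", "duration_h",
                     "heat_capacity_wh_per_m3k", "volume_m3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.incident_power_w_per_m2 < 0:
            raise ValueError("incident power flux must be >= 0")

    @property
    def surface_m2(self) -> float:
        return math.pi * self.dish_diameter_m ** 2 / 4.0


def delta_t_budget(budget: ThermalBudget) -> float:
    """Worst-case lossless temperature rise in kelvin."""
    return (budget.incident_power_w_per_m2 * budget.surface_m2 * budget.duration_h
            / (budget.heat_capacity_wh_per_m3k * budget.volume_m3))


# ---------------------------------------------------------------------------
# plant, controller and simulation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantModel:
    """First-order-plus-dead-time thermal plant.

    dT/dt = (ambient + K*u(t - theta) - T)/tau, with u the heating duty
    in [0, 1].  ``hood_open_disturbance_c`` is the additive offset on
    the sensed air temperature while the hood is open (fast air
    exchange; negative = cooling).
    """

    static_gain: float = 30.0
    time_constant_s: float = 600.0
    dead_time_s: float = 20.0
    ambient_temp_c: float = 22.0
    hood_open_disturbance_c: float = -0.9

    def __post_init__(self) -> None:
        if self.time_constant_s <= 0:
            raise ValueError("time constant must be positive")
        if self.dead_time_s < 0:
            raise ValueError("dead time must be >= 0")


@dataclass(frozen=True)
class PIDGains:
    kp: float
    ki: float = 0.0
    kd: float = 0.0
    setpoint_c: float = 37.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("PID gains must be >= 0")


@dataclass(frozen=True)
class PWMConfig:
    period_s: float = 5.0
    duty_min: float = 0.0
    duty_max: float = 1.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("PWM period must be positive")
        if not (self.duty_min < self.duty_max):
            raise ValueError("duty_min must be below duty_max")


@dataclass
class TemperatureTrace:
    """Sensed temperature, applied duty and hood events over time."""

    time_s: np.ndarray
    temp_c: np.ndarray
    duty: np.ndarray
    events: List[Tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.duty = np.asarray(self.duty, dtype=float)
        if len(self.time_s) == 0:
            raise ValueError("trace must be non-empty")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace time must be strictly increasing")


def imc_pid_gains(plant: PlantModel, closed_loop_tau_s: float,
                  setpoint_c: float = 37.0) -> PIDGains:
    """IMC tuning of a PI(D) controller for an FOPDT plant.

    kp = tau / (K * (lambda_c + theta)), integral time Ti = tau (so
    ki = kp/tau), derivative off by default -- the usual IMC-PI rule for
    slow thermal plants.
    """
    if closed_loop_tau_s <= 0:
        raise ValueError("closed-loop time constant must be positive")
    if plant.static_gain == 0:
        raise ValueError("plant static gain is zero: loop gain undefined")
    kp = plant.time_constant_s / (plant.static_gain
                                  * (closed_loop_tau_s + plant.dead_time_s))
    ki = kp / plant.time_constant_s
    return PIDGains(kp=kp, ki=ki, kd=0.0, setpoint_c=setpoint_c)


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

def _check_schedule(schedule: Sequence[Tuple[float, float]], duration_s: float) -> None:
    prev_close = -math.inf
    for t_open, t_close in schedule:
        if not (0 <= t_open < t_close <= duration_s):
            raise ValueError(
                f"hood event ({t_open}, {t_close}) outside the simulation span")
        if t_open < prev_close:
            raise ValueError("hood events overlap")
        prev_close = t_close


def simulate_regulation(plant: PlantModel, gains: PIDGains, pwm: PWMConfig,
                        schedule: Sequence[Tuple[float, float]] = (),
                        duration_s: float = 3600.0, dt_s: float = 0.5,
                        start_temp_c: Optional[float] = None,
                        sensor_noise_sd_c: float = 0.0,
                        seed: Optional[int] = None) -> TemperatureTrace:
    """Simulate the PID/PWM regulation loop.

    The plant state integrates explicitly at ``dt_s`` (must be at most a
    tenth of the PWM period); the controller recomputes the duty once per
    PWM period from the sensed temperature, with the PWM averaged to its
    mean value within each period.  Anti-windup holds the integrator
    while the output saturates.  Hood-open intervals add the plant's
    disturbance offset to the sensed temperature.  Runs are reproducible
    bit-for-bit given the seed.
    """
    if dt_s > pwm.period_s / 10.0:
        raise ValueError("integration step must be <= pwm.period_s / 10")
    schedule = list(schedule)
    _check_schedule(schedule, duration_s)
    rng = np.random.default_rng(seed)

    n = int(round(duration_s / dt_s)) + 1
    times = np.arange(n) * dt_s
    temps = np.empty(n)
    duties = np.empty(n)

    t_state = plant.ambient_temp_c if start_temp_c is None else start_temp_c
    # bumpless start: if launched at the setpoint, preload the integrator
    # with the equilibrium duty so the loop holds rather than dipping
    equil_duty = (gains.setpoint_c - plant.ambient_temp_c) / plant.static_gain
    integ = min(max(equil_duty, pwm.duty_min), pwm.duty_max) \
        if (start_temp_c is not None
            and abs(start_temp_c - gains.setpoint_c) < 1e-9 and gains.ki > 0) else 0.0
    prev_meas = None
    duty = min(max(integ * (1.0 if gains.ki > 0 else 0.0), pwm.duty_min), pwm.duty_max)

    n_delay = max(int(round(plant.dead_time_s / dt_s)), 0)
    delay_buf = [duty] * n_delay  # u applied now reaches the plant n_delay steps later

    steps_per_period = max(int(round(pwm.period_s / dt_s)), 1)

    def hood_open(t: float) -> bool:
        return any(t_open <= t < t_close for t_open, t_close in schedule)

    for k in range(n):
        t = times[k]
        meas = t_state + (plant.hood_open_disturbance_c if hood_open(t) else 0.0)
        if sensor_noise_sd_c > 0:
            meas += rng.normal(0.0, sensor_noise_sd_c)

        if k % steps_per_period == 0:  # controller runs once per PWM period
            err = gains.setpoint_c - meas
            deriv = 0.0
            if gains.kd > 0 and prev_meas is not None:
                deriv = -(meas - prev_meas) / pwm.period_s  # derivative on measurement
            raw = gains.kp * err + integ + gains.kd * deriv
            duty = min(max(raw, pwm.duty_min), pwm.duty_max)
            saturated = raw != duty
            if gains.ki > 0 and not saturated:
                integ += gains.ki * err * pwm.period_s
            prev_meas = meas

        temps[k] = meas
        duties[k] = duty

        if n_delay:
            delayed = delay_buf.pop(0)
            delay_buf.append(duty)
        else:
            delayed = duty
        t_state += dt_s * (plant.ambient_temp_c + plant.static_gain * delayed
                           - t_state) / plant.time_constant_s

    events = []
    for t_open, t_close in schedule:
        events.append((t_open, "hood_open"))
        events.append((t_close, "hood_close"))
    return TemperatureTrace(time_s=times, temp_c=temps, duty=duties,
                            events=sorted(events))


def simulate_step_response(plant: PlantModel, step_duty: float,
                           duration_s: float = 4800.0, dt_s: float = 0.5,
                           noise_sd_c: float = 0.0,
                           seed: Optional[int] = None) -> TemperatureTrace:
    """Open-loop response to a duty step applied at t = 0 from ambient."""
    n = int(round(duration_s / dt_s)) + 1
    times = np.arange(n) * dt_s
    temps = np.empty(n)
    t_state = plant.ambient_temp_c
    n_delay = max(int(round(plant.dead_time_s / dt_s)), 0)
    delay_buf = [0.0] * n_delay
    rng = np.random.default_rng(seed)
    for k in range(n):
        temps[k] = t_state
        if n_delay:
            delayed = delay_buf.pop(0)
            delay_buf.append(step_duty)
        else:
            delayed = step_duty
        t_state += dt_s * (plant.ambient_temp_c + plant.static_gain * delayed
                           - t_state) / plant.time_constant_s
    if noise_sd_c > 0:
        temps = temps + rng.normal(0.0, noise_sd_c, size=n)
    return TemperatureTrace(time_s=times, temp_c=temps,
                            duty=np.full(n, step_duty))


def identify_fopdt(step_trace: TemperatureTrace,
                   step_magnitude: float) -> PlantModel:
    """Fit FOPDT parameters (K, tau, theta) to an open-loop step response.

    The step is assumed applied at t = 0 from a settled initial state.
    A least-squares fit of T(t) = T0 + K*du*(1 - exp(-(t-theta)/tau))
    for t > theta recovers the parameters; T0 is fitted jointly (the
    first sample is noisy), and heuristic estimates (63.2% rise time,
    response onset) seed the fit.
    """
    if step_magnitude == 0:
        raise ValueError("zero input step: plant unidentifiable")
    t = step_trace.time_s
    y = step_trace.temp_c
    t0_temp = float(np.median(y[: max(len(y) // 100, 3)]))
    # settling check: the last two 10% windows must agree relative to the
    # total rise, otherwise the steady-state gain is not observable
    rise = y[-1] - t0_temp
    if abs(rise) < 1e-12:
        raise ValueError("no response to the step: plant unidentifiable")
    win_a = y[(t >= t[-1] * 0.8) & (t < t[-1] * 0.9)]
    tail = y[t >= t[-1] * 0.9]
    if abs(tail.mean() - win_a.mean()) > 0.01 * abs(rise):
        raise ValueError("trace has not settled: cannot identify steady-state gain")
    y_ss = tail.mean()
    k_guess = (y_ss - t0_temp) / step_magnitude

    frac = (y - t0_temp) / (y_ss - t0_temp)
    onset_idx = np.argmax(frac > 0.02)
    theta_guess = max(t[onset_idx] - (t[1] - t[0]), 0.0)
    idx_63 = np.argmax(frac >= 0.632)
    tau_guess = max(t[idx_63] - theta_guess, t[1] - t[0])

    def model(tt, k, tau, theta, t0):
        out = np.where(tt > theta,
                       1.0 - np.exp(-np.clip(tt - theta, 0, None) / tau), 0.0)
        return t0 + k * step_magnitude * out

    popt, _ = curve_fit(model, t, y,
                        p0=[k_guess, tau_guess, theta_guess, t0_temp],
                        maxfev=20000)
    k_fit, tau_fit, theta_fit, t0_fit = popt
    return PlantModel(static_gain=float(k_fit), time_constant_s=float(tau_fit),
                      dead_time_s=float(max(theta_fit, 0.0)),
                      ambient_temp_c=float(t0_fit))


# ---------------------------------------------------------------------------
# trace summaries
# ---------------------------------------------------------------------------

def trace_metrics(trace: TemperatureTrace, setpoint_c: float = 37.0,
                  band_c: float = 0.2,
                  settle_exclusion_s: float = 600.0) -> dict:
    """Deterministic regulation summary of a trace.

    The steady-state analysis window starts at the first sample inside
    the +/- band (excluding the warm-up) and excludes each hood event
    window plus ``settle_exclusion_s`` after its close.  Returns max
    deviation inside the analysis window, band occupancy, the overall
    max deviation, and per-event re-entry (settle) times.
    """
    t = trace.time_s
    dev = np.abs(trace.temp_c - setpoint_c)
    in_band = dev <= band_c
    if not in_band.any():
        return {"max_deviation_c": float(dev.max()),
                "overall_max_deviation_c": float(dev.max()),
                "band_occupancy": 0.0, "settle_times_s": [], "t_steady_s": None}
    t_steady = t[np.argmax(in_band)]

    opens = sorted(tt for tt, lbl in trace.events if lbl == "hood_open")
    closes = sorted(tt for tt, lbl in trace.events if lbl == "hood_close")
    excluded = np.zeros_like(t, dtype=bool)
    for t_open, t_close in zip(opens, closes):
        excluded |= (t >= t_open) & (t <= t_close + settle_exclusion_s)
    analysis = (t >= t_steady) & ~excluded

    settle_times = []
    for t_close in closes:
        after = (t >= t_close) & in_band
        settle_times.append(float(t[np.argmax(after)] - t_close) if after.any()
                            else math.inf)

    occupancy = float(in_band[analysis].mean()) if analysis.any() else float("nan")
    max_dev = float(dev[t >= t_steady].max())
    return {"max_deviation_c": max_dev,
            "overall_max_deviation_c": float(dev.max()),
            "band_occupancy": occupancy,
            "settle_times_s": settle_times,
            "t_steady_s": float(t_steady)}
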
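"""Nest temperature-logger analysis of incubation feeding trips.

Loggers under incubating nests record temperature every 2 minutes to the
nearest 0.1 degC.  A female's feeding trip shows up as a run of cooling
steps; a trip event is defined as at least two consecutive 2-minute
periods each dropping by at least 0.2 degC (single-step drops, e.g. from
egg turning, are excluded).  Control loggers buried nearby measure the
natural rate of such drops, which is subtracted per duration bin to give
the daily rate of true feeding trips and their mean duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_INTERVAL_MIN = 2
QUANTUM_DEGC = 0.1
#: Minimum per-step drop (degC) and minimum run length for a trip event.
DROP_THRESHOLD_DEGC = 0.2
MIN_RUN_STEPS = 2


def quantise(temps) -> np.ndarray:
    """Round a temperature series to the 0.1 degC logger resolution."""
    return np.round(np.asarray(temps, dtype=float), 1)


@dataclass
class LoggerTrace:
    temperatures: np.ndarray            # degC, one sample per 2 minutes
    is_control: bool = False

    def __post_init__(self):
        self.temperatures = quantise(self.temperatures)

    @property
    def duration_days(self) -> float:
        return (len(self.temperatures) - 1) * SAMPLE_INTERVAL_MIN / 1440.0

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "minute": np.arange(len(self.temperatures)) * SAMPLE_INTERVAL_MIN,
            "temperature": self.temperatures,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, is_control: bool = False) -> "LoggerTrace":
        df = pd.read_csv(path)
        return cls(df["temperature"].to_numpy(), is_control=is_control)


def detect_drops(trace: LoggerTrace | np.ndarray) -> list[tuple[int, int]]:
    """Detect trip events: maximal runs of cooling steps.

    Returns (start sample index, duration in minutes) for every maximal
    run of >= 2 consecutive 2-minute steps each with a temperature drop
    of at least 0.2 degC.  Differences are evaluated on the quantised
    deci-degC integers, so detection is exact at logger resolution and
    invariant to adding a constant to the trace.
    """
    temps = trace.temperatures if isinstance(trace, LoggerTrace) else quantise(trace)
    deci = np.rint(temps * 10).astype(np.int64)
    drops = np.diff(deci) <= -int(round(DROP_THRESHOLD_DEGC * 10))
    events = []
    i = 0
    n = len(drops)
    while i < n:
        if drops[i]:
            j = i
            while j < n and drops[j]:
                j += 1
            if j - i >= MIN_RUN_STEPS:
                events.append((i, (j - i) * SAMPLE_INTERVAL_MIN))
            i = j
        else:
            i += 1
    return events


@dataclass
class TripDistribution:
    durations_min: np.ndarray           # bin centres: 4, 6, 8, ... minutes
    nest_rates_per_day: np.ndarray
    control_rates_per_day: np.ndarray
    net_rates_per_day: np.ndarray       # max(0, nest - control) per bin
    mean_trip_minutes: float            # nan when all net rates are zero

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.mean_trip_minutes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "duration_min": self.durations_min,
            "nest_rate_per_day": self.nest_rates_per_day,
            "control_rate_per_day": self.control_rates_per_day,
            "net_rate_per_day": self.net_rates_per_day,
        })


def _binned_rates(traces: list[LoggerTrace], durations: np.ndarray) -> np.ndarray:
    """Pooled events per day for each duration bin across traces."""
    total_days = sum(t.duration_days for t in traces)
    counts = np.zeros(len(durations))
    index = {int(d): i for i, d in enumerate(durations)}
    for t in traces:
        for _start, dur in detect_drops(t):
            if int(dur) in index:
                counts[index[int(dur)]] += 1
    return counts / total_days if total_days > 0 else counts


def net_trip_distribution(
    nest_traces: list[LoggerTrace],
    control_traces: list[LoggerTrace],
    max_duration_min: int | None = None,
) -> TripDistribution:
    """Trip-length distribution net of the natural drop rate.

    Daily event rates per duration bin (4, 6, 8, ... minutes) are
    computed for nest and control loggers; the control rate is
    subtracted (clamped at zero, rates cannot be negative) and the
    arithmetic mean duration of the net discrete distribution returned.
    """
    if not nest_traces or not control_traces:
        raise ValueError("need at least one nest trace and one control trace")
    all_durs = [
        dur
        for t in nest_traces + control_traces
        for _s, dur in detect_drops(t)
    ]
    top = max_duration_min or (max(all_durs) if all_durs else 4)
    durations = np.arange(MIN_RUN_STEPS * SAMPLE_INTERVAL_MIN, top + 1, SAMPLE_INTERVAL_MIN)
    nest = _binned_rates(nest_traces, durations)
    control = _binned_rates(control_traces, durations)
    net = np.maximum(0.0, nest - control)
    total = net.sum()
    mean = float((durations @ net) / total) if total > 0 else float("nan")
    return TripDistribution(
        durations_min=durations,
        nest_rates_per_day=nest,
        control_rates_per_day=control,
        net_rates_per_day=net,
        mean_trip_minutes=mean,
    )


@dataclass
class TraceThermalParams:
    """Thermal model of the synthetic logger trace generator."""

    nest_temp_c: float = 36.0           # incubated equilibrium temperature
    ambient_mean_c: float = 15.0
    ambient_amplitude_c: float = 4.0    # daily sinusoid of ambient
    nest_amplitude_c: float = 1.5       # daily sinusoid leaking into the nest
    cooling_rate_per_hr: float = 3.0    # toward ambient while off the nest
    rewarm_minutes: float = 0.0         # instantaneous return by default


def simulate_trace(
    trip_schedule: list[tuple[float, float]],
    n_days: float = 1.0,
    thermal: TraceThermalParams | None = None,
    noise_sd_c: float = 0.0,
    seed: int = 0,
) -> LoggerTrace:
    """Generate a synthetic nest-logger trace with known trips.

    ``trip_schedule`` lists (start minute, duration minutes) off-nest
    bouts; they must not overlap.  While incubated the nest sits at its
    equilibrium plus a small daily sinusoid; during a trip temperature
    decays exponentially toward ambient; rewarming is instantaneous.
    Gaussian noise is added and the trace quantised to 0.1 degC.
    """
    thermal = thermal or TraceThermalParams()
    sched = sorted(trip_schedule)
    for (s0, d0), (s1, _d1) in zip(sched, sched[1:]):
        if s0 + d0 > s1:
            raise ValueError("overlapping trips in schedule")
    total_min = int(n_days * 1440)
    t_min = np.arange(0, total_min + 1, SAMPLE_INTERVAL_MIN, dtype=float)
    phase = 2 * np.pi * (t_min / 1440.0 - 0.25)   # ambient peaks mid-afternoon
    ambient = thermal.ambient_mean_c + thermal.ambient_amplitude_c * np.sin(phase)
    temps = thermal.nest_temp_c + thermal.nest_amplitude_c * np.sin(phase)
    k = thermal.cooling_rate_per_hr
    for start, dur in sched:
        in_trip = (t_min >= start) & (t_min <= start + dur)
        if not in_trip.any():
            continue
        dt_hr = (t_min[in_trip] - start) / 60.0
        base = thermal.nest_temp_c + thermal.nest_amplitude_c * np.sin(
            2 * np.pi * (start / 1440.0 - 0.25)
        )
        temps[in_trip] = ambient[in_trip] + (base - ambient[in_trip]) * np.exp(-k * dt_hr)
    if noise_sd_c > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd_c, len(temps))
    return LoggerTrace(temps)
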
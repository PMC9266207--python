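"""Voltage-clamp protocol descriptors and simulated sweep acquisition.

Three stock protocols are provided, matching standard whole-cell
characterization of transient sodium current:

* current-voltage family: 50 ms depolarizing steps, -80..+60 mV in 5 mV
  increments, from a holding potential of -100 mV (fluoride internal) or
  -80 mV (fluoride-free internal);
* steady-state inactivation: 500 ms conditioning prepulses, -130..+40 mV in
  10 mV increments, followed by a 20 ms test pulse to 0 mV;
* recovery from fast inactivation: paired pulses to 0 mV separated by a
  repolarizing gap at -80 mV of increasing duration.

Simulated sweeps are artifact-free: no leak, no capacitive transient, no
series-resistance error (the synthetic-recordings module adds leak and noise
where a realistic cell is wanted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import markov
from .errors import InvalidParameterError, ProtocolMismatchError
from .markov import MacroscopicCurrentParams, RateConstants

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "iv_protocol",
    "ssi_protocol",
    "recovery_protocol",
    "run_protocol",
    "measure_peak",
    "measure_persistent",
    "iv_curve",
    "ssi_curve",
    "recovery_curve",
]

#: dead time (ms) excluded after a step edge so the instantaneous ohmic jump
#: never wins the peak search
PEAK_SETTLE_MS = 0.05


@dataclass
class VoltageProtocol:
    """A family of piecewise-constant command-voltage sweeps.

    ``sweeps[i]`` is a tuple of ``(level_mV, duration_ms)`` segments;
    ``sweep_values[i]`` is the value of the sweep-varying parameter
    (step level, prepulse level or gap duration).  ``measure_segment`` is the
    index of the segment whose current is measured; ``reference_segment``
    (recovery protocol only) holds the conditioning pulse.
    """

    kind: str
    holding: float
    sweeps: list[tuple[tuple[float, float], ...]]
    sweep_values: list[float]
    sweep_param: str
    dt: float = 0.025
    measure_segment: int = 0
    reference_segment: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if not self.sweeps:
            raise InvalidParameterError("protocol needs at least one sweep")
        if len(self.sweeps) != len(self.sweep_values):
            raise InvalidParameterError("sweep_values must match sweeps")
        for sw in self.sweeps:
            for _, dur in sw:
                if dur <= 0:
                    raise InvalidParameterError("segment durations must be > 0")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def segment_bounds(self, isweep: int) -> list[tuple[float, float]]:
        """(t_start, t_end) in ms for every segment of one sweep."""
        bounds, t = [], 0.0
        for _, dur in self.sweeps[isweep]:
            bounds.append((t, t + dur))
            t += dur
        return bounds

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "holding": self.holding,
            "sweeps": [[list(seg) for seg in sw] for sw in self.sweeps],
            "sweep_values": list(map(float, self.sweep_values)),
            "sweep_param": self.sweep_param,
            "dt": self.dt,
            "measure_segment": self.measure_segment,
            "reference_segment": self.reference_segment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            kind=d["kind"],
            holding=d["holding"],
            sweeps=[tuple(tuple(seg) for seg in sw) for sw in d["sweeps"]],
            sweep_values=list(d["sweep_values"]),
            sweep_param=d["sweep_param"],
            dt=d.get("dt", 0.025),
            measure_segment=d.get("measure_segment", 0),
            reference_segment=d.get("reference_segment"),
        )


def iv_protocol(
    holding: float = -100.0,
    v_start: float = -80.0,
    v_stop: float = 60.0,
    dv: float = 5.0,
    duration: float = 50.0,
    dt: float = 0.025,
) -> VoltageProtocol:
    """Current-voltage step family (transient/persistent current protocol)."""
    levels = np.arange(v_start, v_stop + 0.5 * dv, dv)
    return VoltageProtocol(
        kind="iv",
        holding=holding,
        sweeps=[((float(v), duration),) for v in levels],
        sweep_values=[float(v) for v in levels],
        sweep_param="step_mV",
        dt=dt,
        measure_segment=0,
    )


def ssi_protocol(
    holding: float = -100.0,
    v_start: float = -130.0,
    v_stop: float = 40.0,
    dv: float = 10.0,
    prepulse_ms: float = 500.0,
    test_mv: float = 0.0,
    test_ms: float = 20.0,
    dt: float = 0.025,
) -> VoltageProtocol:
    """Steady-state inactivation (availability) protocol."""
    levels = np.arange(v_start, v_stop + 0.5 * dv, dv)
    return VoltageProtocol(
        kind="ssi",
        holding=holding,
        sweeps=[((float(v), prepulse_ms), (test_mv, test_ms)) for v in levels],
        sweep_values=[float(v) for v in levels],
        sweep_param="prepulse_mV",
        dt=dt,
        measure_segment=1,
    )


def recovery_protocol(
    holding: float = -100.0,
    gaps_ms: Sequence[float] | None = None,
    conditioning_mv: float = 0.0,
    conditioning_ms: float = 50.0,
    recovery_mv: float = -80.0,
    test_mv: float = 0.0,
    test_ms: float = 20.0,
    dt: float = 0.025,
) -> VoltageProtocol:
    """Paired-pulse recovery-from-fast-inactivation protocol.

    Gap durations default to 12 log-spaced points between 0.5 and 100 ms.
    """
    if gaps_ms is None:
        gaps_ms = np.logspace(np.log10(0.5), np.log10(100.0), 12)
    sweeps = [
        ((conditioning_mv, conditioning_ms), (recovery_mv, float(g)),
         (test_mv, test_ms))
        for g in gaps_ms
    ]
    return VoltageProtocol(
        kind="recovery",
        holding=holding,
        sweeps=sweeps,
        sweep_values=[float(g) for g in gaps_ms],
        sweep_param="gap_ms",
        dt=dt,
        measure_segment=2,
        reference_segment=0,
    )


@dataclass
class SweepSet:
    """Current traces produced by running one protocol against one channel.

    ``traces[i]`` (pA) and ``times[i]`` (ms) are aligned per sweep; sweeps of
    a protocol whose varying parameter is a duration (recovery) have unequal
    lengths, so traces are stored as a list of 1-D arrays.  ``commands[i]``
    holds the command voltage at every sample.
    """

    protocol: VoltageProtocol
    times: list[np.ndarray]
    traces: list[np.ndarray]
    commands: list[np.ndarray]
    capacitance_pf: float | None = None
    condition: str | None = None
    seed: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        return len(self.traces)

    @property
    def sweep_values(self) -> list[float]:
        return self.protocol.sweep_values

    @property
    def dt(self) -> float:
        return self.protocol.dt


def _command_array(t: np.ndarray, segments, holding: float) -> np.ndarray:
    """Command voltage at each sample; t=0 belongs to the first segment."""
    v = np.empty_like(t)
    edges, t0 = [], 0.0
    for level, dur in segments:
        edges.append((t0, t0 + dur, level))
        t0 += dur
    v[:] = holding
    for start, stop, level in edges:
        v[(t > start - 1e-12) & (t <= stop + 1e-12)] = level
    v[0] = edges[0][2]
    return v


def run_protocol(
    protocol: VoltageProtocol,
    rates: RateConstants,
    mp: MacroscopicCurrentParams,
    dt: float | None = None,
) -> SweepSet:
    """Integrate the channel through every sweep of a protocol.

    Each sweep starts from the stationary occupancy at the holding potential.
    Returns the macroscopic current traces, scaled by the condition's density
    factor.
    """
    dt = protocol.dt if dt is None else dt
    p_hold = markov.steady_state(protocol.holding, rates)
    times, traces, commands = [], [], []
    for sw in protocol.sweeps:
        t, P = markov.integrate_occupancy(p_hold, sw, rates, dt=dt)
        v = _command_array(t, sw, protocol.holding)
        i = markov.current(P[:, markov.OPEN], v, mp, rates.density_scale)
        times.append(t)
        traces.append(i)
        commands.append(v)
    return SweepSet(protocol=protocol, times=times, traces=traces,
                    commands=commands)


def _window(ss: SweepSet, isweep: int, segment: int | None) -> tuple[float, float]:
    proto = ss.protocol
    segment = proto.measure_segment if segment is None else segment
    bounds = proto.segment_bounds(isweep)
    if not 0 <= segment < len(bounds):
        raise ProtocolMismatchError(
            f"segment {segment} outside the {len(bounds)}-segment sweep")
    return bounds[segment]


def measure_peak(
    ss: SweepSet,
    isweep: int,
    segment: int | None = None,
    settle_ms: float = PEAK_SETTLE_MS,
) -> tuple[float, float]:
    """Signed peak current and its time within the measured step.

    The extremum of the signed current (largest magnitude, sign preserved) is
    searched inside the segment window, excluding ``settle_ms`` after the step
    edge.
    """
    t0, t1 = _window(ss, isweep, segment)
    t, i = ss.times[isweep], ss.traces[isweep]
    if t.size == 0:
        raise ProtocolMismatchError("empty sweep")
    mask = (t > t0 + settle_ms) & (t <= t1 + 1e-12)
    if not mask.any():
        raise ProtocolMismatchError("measurement window outside the trace")
    k = int(np.argmax(np.abs(i[mask])))
    return float(i[mask][k]), float(t[mask][k])


def measure_persistent(
    ss: SweepSet,
    isweep: int,
    segment: int | None = None,
    window_ms: float = 5.0,
) -> float:
    """Mean signed current over the final ``window_ms`` of the measured step."""
    t0, t1 = _window(ss, isweep, segment)
    if t1 - t0 < window_ms - 1e-9:
        raise ProtocolMismatchError(
            f"step is {t1 - t0:g} ms, shorter than the {window_ms:g} ms window")
    t, i = ss.times[isweep], ss.traces[isweep]
    mask = (t >= t1 - window_ms - 1e-12) & (t <= t1 + 1e-12)
    if not mask.any():
        raise ProtocolMismatchError("persistent-current window outside the trace")
    return float(i[mask].mean())


def iv_curve(ss: SweepSet) -> pd.DataFrame:
    """Peak and persistent current per step voltage of an I-V sweep set."""
    rows = []
    for k in range(ss.n_sweeps):
        peak, t_peak = measure_peak(ss, k)
        rows.append({
            "step_mV": ss.sweep_values[k],
            "peak_pA": peak,
            "t_peak_ms": t_peak,
            "persistent_pA": measure_persistent(ss, k),
        })
    return pd.DataFrame(rows)


def ssi_curve(ss: SweepSet) -> pd.DataFrame:
    """Test-pulse peak current against prepulse potential (raw, unnormalized)."""
    rows = []
    for k in range(ss.n_sweeps):
        peak, _ = measure_peak(ss, k)
        rows.append({"prepulse_mV": ss.sweep_values[k], "test_peak_pA": peak})
    return pd.DataFrame(rows)


def recovery_curve(ss: SweepSet) -> pd.DataFrame:
    """Recovered fraction (test peak / conditioning peak) per gap duration."""
    ref_seg = ss.protocol.reference_segment
    if ref_seg is None:
        raise ProtocolMismatchError("protocol has no conditioning segment")
    rows = []
    for k in range(ss.n_sweeps):
        cond, _ = measure_peak(ss, k, segment=ref_seg)
        test, _ = measure_peak(ss, k)
        rows.append({
            "gap_ms": ss.sweep_values[k],
            "conditioning_peak_pA": cond,
            "test_peak_pA": test,
            "fraction": test / cond if cond != 0 else np.nan,
        })
    return pd.DataFrame(rows)
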
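"""Single-compartment pacemaking-neuron simulations.

The membrane carries the Markov Nav1.6 current (one or more channel
populations, e.g. a 50/50 wild-type/mutant split for heterozygous
expression), a fast delayed-rectifier K+ current (Hodgkin-Huxley n^4 with
fast, high-threshold kinetics of the Purkinje type), an ohmic leak whose
reversal supplies the depolarizing drive for spontaneous pacemaking, and
optional hyperpolarization-activated (h-type), BK-like and slow AHP-type
(SK-like) K+ currents behind config flags:

    C dV/dt = -(I_Na + I_K + I_leak [+ I_h + I_BK]) + I_stim

Na occupancies are propagated with per-voltage matrix exponentials
precomputed on a fine voltage grid (exact for frozen V, conservation to
machine precision); V and the HH gates use exponential-Euler updates.  The
auxiliary-conductance densities are calibrated once so that the 100% wild
type neuron is a stable spontaneous pacemaker in the tens-of-Hz range; all
condition comparisons are relative, which this calibration preserves.

Units: mV, ms, mS/cm2, uA/cm2, uF/cm2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import markov
from .errors import IntegrationInstabilityError, InvalidParameterError
from .markov import RateConstants, get_preset

__all__ = [
    "NeuronConfig",
    "StimulusProtocol",
    "FiringResult",
    "PacemakerNeuron",
    "build_neuron",
    "simulate_spontaneous",
    "simulate_evoked",
    "detect_spikes",
]

SPIKE_THRESHOLD_MV = -20.0
SPIKE_REFRACTORY_MS = 1.0


@dataclass(frozen=True)
class NeuronConfig:
    """Composition and densities of the single-compartment model.

    ``composition`` lists ``(condition, fraction)`` pairs; fractions must be
    nonnegative and sum to 1.  Each population contributes
    ``fraction * density_scale * gna_bar`` to the Na conductance, so the
    Table-row density factors of mutant conditions are applied automatically.
    """

    composition: tuple[tuple[str | RateConstants, float], ...] = (("WT", 1.0),)
    gna_bar: float = 16.0        # mS/cm2, before density scaling
    gk_bar: float = 10.0         # fast delayed rectifier
    gleak: float = 0.12
    e_leak: float = -62.0
    e_na: float = 68.0
    e_k: float = -88.0
    gh_bar: float = 0.0          # optional h-current
    e_h: float = -30.0
    gbk_bar: float = 0.0         # optional BK-like fast K current
    gsk_bar: float = 0.2         # slow AHP-type K (SK-like rate governor)
    tau_n_base: float = 0.2      # DR gate time constant floor, ms
    tau_n_amp: float = 3.0       # DR gate time constant peak above floor, ms
    tau_sk: float = 50.0         # SK-like gate time constant, ms
    cm: float = 1.0
    v_init: float = -65.0
    dt: float = 0.005            # ms
    v_grid_min: float = -120.0
    v_grid_max: float = 80.0
    v_grid_step: float = 0.1

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.composition]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidParameterError(
                "composition fractions must be >= 0 and sum to 1")
        for name in ("gna_bar", "gk_bar", "gleak", "gh_bar", "gbk_bar", "gsk_bar"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.cm <= 0 or self.dt <= 0 or self.v_grid_step <= 0:
            raise InvalidParameterError("cm, dt and v_grid_step must be > 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-step stimulation: settle, then one step per amplitude."""

    amplitudes: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)  # uA/cm2
    baseline_ms: float = 1000.0
    step_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.baseline_ms <= 0 or self.step_ms <= 0:
            raise InvalidParameterError("durations must be > 0")


@dataclass
class FiringResult:
    """Detected spikes and firing statistics of one simulation."""

    spike_times_ms: np.ndarray
    frequency_hz: float
    window_ms: float
    evoked: pd.DataFrame | None = None
    trace: tuple[np.ndarray, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# Gate kinetics (delayed rectifier n, h-current q)
# ---------------------------------------------------------------------------

def _n_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 30.0) / 9.0))


def _tau_n(v: float, base: float = 0.2, amp: float = 3.0) -> float:
    return base + amp * math.exp(-((v + 45.0) / 35.0) ** 2)


def _q_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 90.0) / 7.0))


_TAU_Q = 300.0  # ms, slow h-gate


def _bk_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v / 10.0))


def _z_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 45.0) / 4.0))


_TAU_Z = 50.0  # ms, slow AHP gate (spike-count integrator)


# ---------------------------------------------------------------------------
# Fixed-step integration kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _kernel_impl(P, tables, weights, state, params, dt, nsteps,
                 stim_amp, istim0, istim1, vmin, inv_dv, nv, stride, vrec):
    # state: [V, n, q, z]
    # params: [gk, ek, gl, el, ena, cm, gh, eh, gbk, gsk,
    #          tau_n_base, tau_n_amp, tau_sk]
    nchan = P.shape[0]
    V = state[0]
    n = state[1]
    q = state[2]
    z = state[3]
    gk_bar = params[0]
    ek = params[1]
    gl = params[2]
    el = params[3]
    ena = params[4]
    cm = params[5]
    gh_bar = params[6]
    eh = params[7]
    gbk_bar = params[8]
    gsk_bar = params[9]
    taun_base = params[10]
    taun_amp = params[11]
    tau_sk = params[12]
    newp = np.empty(13)
    irec = 0
    for step in range(nsteps):
        idx = int((V - vmin) * inv_dv + 0.5)
        if idx < 0:
            idx = 0
        elif idx >= nv:
            idx = nv - 1
        gna = 0.0
        for c in range(nchan):
            for j in range(13):
                acc = 0.0
                for i in range(13):
                    acc += P[c, i] * tables[c, idx, i, j]
                newp[j] = acc
            for j in range(13):
                P[c, j] = newp[j]
            gna += weights[c] * P[c, 5]
        # HH gates, exponential (Rush-Larsen) update
        ninf = 1.0 / (1.0 + math.exp(-(V + 30.0) / 9.0))
        taun = taun_base + taun_amp * math.exp(-((V + 45.0) / 35.0) ** 2)
        n = ninf + (n - ninf) * math.exp(-dt / taun)
        qinf = 1.0 / (1.0 + math.exp((V + 90.0) / 7.0))
        q = qinf + (q - qinf) * math.exp(-dt / 300.0)
        zinf = 1.0 / (1.0 + math.exp(-(V + 45.0) / 4.0))
        z = zinf + (z - zinf) * math.exp(-dt / tau_sk)
        gk = gk_bar * n * n * n * n
        gh = gh_bar * q
        gbk = gbk_bar / (1.0 + math.exp(-V / 10.0))
        gsk = gsk_bar * z
        istim = stim_amp if (istim0 <= step < istim1) else 0.0
        gtot = gna + gk + gl + gh + gbk + gsk
        esum = gna * ena + (gk + gbk + gsk) * ek + gl * el + gh * eh + istim
        vinf = esum / gtot
        V = vinf + (V - vinf) * math.exp(-dt * gtot / cm)
        if (step + 1) % stride == 0:
            vrec[irec] = V
            irec += 1
    state[0] = V
    state[1] = n
    state[2] = q
    state[3] = z
    return irec


try:  # optional acceleration; the pure-python path is the reference
    from numba import njit as _njit

    _kernel_fast = _njit(cache=True, fastmath=False)(_kernel_impl)
except Exception:  # pragma: no cover - numba always present in CI image
    _kernel_fast = None


def _kernel_numpy(P, tables, weights, state, params, dt, nsteps,
                  stim_amp, istim0, istim1, vmin, inv_dv, nv, stride, vrec):
    """Vectorized fallback with identical arithmetic to the jit kernel."""
    nchan = P.shape[0]
    V, n, q, z = state[0], state[1], state[2], state[3]
    (gk_bar, ek, gl, el, ena, cm, gh_bar, eh, gbk_bar, gsk_bar,
     taun_base, taun_amp, tau_sk) = params
    irec = 0
    for step in range(nsteps):
        idx = min(max(int((V - vmin) * inv_dv + 0.5), 0), nv - 1)
        gna = 0.0
        for c in range(nchan):
            P[c] = P[c] @ tables[c, idx]
            gna += weights[c] * P[c, 5]
        n = _n_inf(V) + (n - _n_inf(V)) * math.exp(
            -dt / _tau_n(V, taun_base, taun_amp))
        q = _q_inf(V) + (q - _q_inf(V)) * math.exp(-dt / _TAU_Q)
        z = _z_inf(V) + (z - _z_inf(V)) * math.exp(-dt / tau_sk)
        gk = gk_bar * n ** 4
        gh = gh_bar * q
        gbk = gbk_bar * _bk_inf(V)
        gsk = gsk_bar * z
        istim = stim_amp if (istim0 <= step < istim1) else 0.0
        gtot = gna + gk + gl + gh + gbk + gsk
        vinf = (gna * params[4] + (gk + gbk + gsk) * ek + gl * el
                + gh * eh + istim) / gtot
        V = vinf + (V - vinf) * math.exp(-dt * gtot / cm)
        if (step + 1) % stride == 0:
            vrec[irec] = V
            irec += 1
    state[0], state[1], state[2], state[3] = V, n, q, z
    return irec


class PacemakerNeuron:
    """Runnable membrane model built from a :class:`NeuronConfig`."""

    def __init__(self, config: NeuronConfig):
        self.config = config
        self.rates: list[RateConstants] = []
        self.fractions: list[float] = []
        for cond, frac in config.composition:
            r = cond if isinstance(cond, RateConstants) else get_preset(cond)
            self.rates.append(r)
            self.fractions.append(float(frac))
        self.weights = np.array(
            [f * r.density_scale * config.gna_bar
             for f, r in zip(self.fractions, self.rates)])
        self._table_cache: dict[float, np.ndarray] = {}
        self.reset()

    # -- state -------------------------------------------------------------
    def reset(self) -> None:
        """Initialize V at v_init with channels at their fixed-V steady state."""
        cfg = self.config
        self.P = np.stack([markov.steady_state(cfg.v_init, r)
                           for r in self.rates])
        self.state = np.array([cfg.v_init, _n_inf(cfg.v_init),
                               _q_inf(cfg.v_init), _z_inf(cfg.v_init)])

    # -- propagator tables -------------------------------------------------
    def _tables(self, dt: float) -> np.ndarray:
        if dt not in self._table_cache:
            cfg = self.config
            grid = np.arange(cfg.v_grid_min, cfg.v_grid_max + 0.5 * cfg.v_grid_step,
                             cfg.v_grid_step)
            tabs = np.empty((len(self.rates), grid.size, 13, 13))
            for c, r in enumerate(self.rates):
                for k, v in enumerate(grid):
                    tabs[c, k] = expm(markov.build_generator(float(v), r) * dt)
            self._table_cache[dt] = np.ascontiguousarray(tabs)
        return self._table_cache[dt]

    # -- integration -------------------------------------------------------
    def run(
        self,
        duration_ms: float,
        stim_amp: float = 0.0,
        stim_window: tuple[float, float] | None = None,
        record_dt: float = 0.05,
        dt: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance the model, returning ``(t, V)`` sampled every record_dt.

        The model's state persists across calls, so a settle period and an
        analysis window can be run back to back.
        """
        cfg = self.config
        dt = cfg.dt if dt is None else dt
        nsteps = int(round(duration_ms / dt))
        stride = max(1, int(round(record_dt / dt)))
        tables = self._tables(dt)
        if stim_window is None:
            i0, i1 = (0, nsteps) if stim_amp else (0, 0)
        else:
            i0 = int(round(stim_window[0] / dt))
            i1 = int(round(stim_window[1] / dt))
        nrec = nsteps // stride
        vrec = np.empty(nrec)
        params = np.array([cfg.gk_bar, cfg.e_k, cfg.gleak, cfg.e_leak,
                           cfg.e_na, cfg.cm, cfg.gh_bar, cfg.e_h,
                           cfg.gbk_bar, cfg.gsk_bar, cfg.tau_n_base,
                           cfg.tau_n_amp, cfg.tau_sk])
        kernel = _kernel_fast if _kernel_fast is not None else _kernel_numpy
        inv_dv = 1.0 / cfg.v_grid_step
        nv = tables.shape[1]
        irec = kernel(self.P, tables, self.weights, self.state, params,
                      dt, nsteps, float(stim_amp), i0, i1,
                      cfg.v_grid_min, inv_dv, nv, stride, vrec)
        vrec = vrec[:irec]
        if not np.all(np.isfinite(vrec)) or not np.isfinite(self.state[0]):
            raise IntegrationInstabilityError("membrane potential diverged")
        t = dt * stride * np.arange(1, irec + 1)
        return t, vrec


def build_neuron(config: NeuronConfig) -> PacemakerNeuron:
    """Construct the membrane model for a Na-channel composition."""
    return PacemakerNeuron(config)


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = SPIKE_THRESHOLD_MV,
    refractory_ms: float = SPIKE_REFRACTORY_MS,
) -> np.ndarray:
    """Spike times from upward threshold crossings with a refractory lockout."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times: list[float] = []
    for k in crossings:
        if not times or t[k] - times[-1] >= refractory_ms:
            times.append(float(t[k]))
    return np.asarray(times)


def simulate_spontaneous(
    model: PacemakerNeuron,
    settle_ms: float = 1000.0,
    window_ms: float = 2000.0,
    keep_trace: bool = False,
) -> FiringResult:
    """Spontaneous firing: no injected current; spikes counted after settling."""
    if window_ms < 1000.0:
        raise InvalidParameterError("analysis window must be >= 1000 ms")
    model.reset()
    model.run(settle_ms)
    t, v = model.run(window_ms)
    spikes = detect_spikes(t, v)
    freq = 1000.0 * len(spikes) / window_ms
    return FiringResult(spike_times_ms=spikes, frequency_hz=freq,
                        window_ms=window_ms,
                        trace=(t, v) if keep_trace else None)


def simulate_evoked(
    model: PacemakerNeuron,
    stim: StimulusProtocol = StimulusProtocol(),
    keep_trace: bool = False,
) -> FiringResult:
    """Evoked firing: one current step per amplitude after a settle period.

    A zero-amplitude step reproduces spontaneous behaviour by construction.
    Returns the frequency-stimulus relation in ``result.evoked``; the scalar
    ``frequency_hz`` is the zero- (or lowest-) amplitude entry.
    """
    rows = []
    trace = None
    for amp in stim.amplitudes:
        model.reset()
        model.run(stim.baseline_ms)
        t, v = model.run(stim.step_ms, stim_amp=float(amp))
        spikes = detect_spikes(t, v)
        rows.append({"amplitude_uA_cm2": float(amp),
                     "n_spikes": len(spikes),
                     "frequency_hz": 1000.0 * len(spikes) / stim.step_ms})
        if keep_trace and trace is None:
            trace = (t, v)
    table = pd.DataFrame(rows)
    return FiringResult(
        spike_times_ms=np.array([]),
        frequency_hz=float(table["frequency_hz"].iloc[0]),
        window_ms=stim.step_ms,
        evoked=table,
        trace=trace,
    )
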
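"""Whole-cell recording analysis: conductance transform, Boltzmann fits,
decay/recovery kinetics, current density and the percent-change arithmetic
used to compare channel conditions.

Slope-sign convention: the activation Boltzmann
``G/Gmax = 1 / (1 + exp((V50 - V)/k))`` is fitted with ``k > 0`` (ascending);
the availability curve uses the same functional form with ``k < 0``
(descending).  Reported |k| is convention independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    FitError,
    InvalidParameterError,
    NoReversalError,
)
from .protocols import SweepSet, iv_curve, recovery_curve, ssi_curve

__all__ = [
    "BoltzmannFit",
    "DecayFit",
    "RecoveryFit",
    "conductance",
    "estimate_reversal",
    "fit_activation",
    "fit_inactivation",
    "fit_decay",
    "fit_recovery",
    "current_density",
    "percent_change",
    "round_percent",
    "midpoint_shift",
    "analyze_iv",
    "analyze_ssi",
    "analyze_recovery",
    "REFERENCE_GROUP_MEANS",
]

_MAX_NFEV = 10_000
_TOL = 1e-12


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters: curve = amplitude / (1 + exp((V50-V)/k))."""

    v50: float
    k: float
    amplitude: float
    residual_norm: float
    n_points: int

    def __call__(self, v: np.ndarray | float) -> np.ndarray:
        return _boltzmann(np.asarray(v, dtype=float),
                          self.amplitude, self.v50, self.k)

    def normalized(self, v: np.ndarray | float) -> np.ndarray:
        """Curve scaled to unit amplitude (0.5 exactly at V = V50)."""
        return _boltzmann(np.asarray(v, dtype=float), 1.0, self.v50, self.k)


@dataclass(frozen=True)
class DecayFit:
    """Biexponential decay of the transient current (tau_fast <= tau_slow)."""

    tau_fast: float
    tau_slow: float
    amp_fast: float
    amp_slow: float
    offset: float
    residual_norm: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.amp_fast * np.exp(-t / self.tau_fast)
                + self.amp_slow * np.exp(-t / self.tau_slow) + self.offset)


@dataclass(frozen=True)
class RecoveryFit:
    """Single-exponential recovery: fraction(t) = offset - amplitude*exp(-t/tau)."""

    tau: float
    amplitude: float
    offset: float
    residual_norm: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset - self.amplitude * np.exp(-t / self.tau)


def _boltzmann(v, amplitude, v50, k):
    return amplitude / (1.0 + np.exp((v50 - v) / k))


def conductance(i_nat: float | np.ndarray, v: float | np.ndarray,
                v_rev: float) -> np.ndarray | float:
    """Chord conductance G = I / (V - V_rev); pA / mV gives nS.

    Inward (negative) current below the reversal potential yields a positive
    conductance.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v == v_rev):
        raise InvalidParameterError("V equals V_rev: conductance undefined")
    g = np.asarray(i_nat, dtype=float) / (v - v_rev)
    return float(g) if g.ndim == 0 else g


def estimate_reversal(v: np.ndarray, i: np.ndarray) -> float:
    """Reversal potential from the zero crossing of the ascending I-V limb.

    Looks for a sign change at voltages above the peak-current voltage and
    linearly interpolates.  If the protocol stops just short of the reversal
    (still inward at the top step), the final ascending-limb segment is
    extrapolated, but by no more than 25 mV beyond the last point; anything
    further — or a non-ascending limb — raises :class:`NoReversalError`.
    """
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    k_peak = int(np.argmax(np.abs(i)))
    for k in range(k_peak, len(v) - 1):
        if i[k] == 0:
            return float(v[k])
        if i[k] < 0 <= i[k + 1]:
            frac = -i[k] / (i[k + 1] - i[k])
            return float(v[k] + frac * (v[k + 1] - v[k]))
    if i[-1] == 0:
        return float(v[-1])
    n_tail = min(5, len(v) - k_peak)
    if i[-1] < 0 and n_tail >= 2:
        slope, icpt = np.polyfit(v[-n_tail:], i[-n_tail:], 1)
        if slope > 0:
            v_rev = -icpt / slope
            if v[-1] < v_rev <= v[-1] + 25.0:
                return float(v_rev)
    raise NoReversalError("I-V relation has no zero crossing above the peak")


def _half_crossing(v: np.ndarray, y: np.ndarray, ascending: bool) -> float:
    """Linear-interpolated voltage where y crosses half of its maximum."""
    half = 0.5 * np.max(np.abs(y))
    yy = np.abs(y)
    rng = range(len(v) - 1) if ascending else range(len(v) - 2, -1, -1)
    for k in rng:
        lo, hi = sorted((yy[k], yy[k + 1]))
        if lo <= half <= hi and yy[k] != yy[k + 1]:
            frac = (half - yy[k]) / (yy[k + 1] - yy[k])
            return float(v[k] + frac * (v[k + 1] - v[k]))
    return float(v[len(v) // 2])


def _fit_boltzmann(v, y, k_sign: float) -> BoltzmannFit:
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.size < 5:
        raise FitError("need at least 5 points spanning the transition")
    amp0 = float(np.max(np.abs(y)))
    v50_0 = _half_crossing(v, y, ascending=k_sign > 0)
    k0 = 5.0 * k_sign
    if k_sign > 0:
        bounds = ([1e-12, -150.0, 0.1], [np.inf, 100.0, 50.0])
    else:
        bounds = ([1e-12, -150.0, -50.0], [np.inf, 100.0, -0.1])
    try:
        popt, _ = curve_fit(
            _boltzmann, v, y, p0=[amp0, v50_0, k0], bounds=bounds,
            maxfev=_MAX_NFEV, xtol=_TOL, ftol=_TOL, gtol=_TOL)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit failed: {exc}") from exc
    amplitude, v50, k = map(float, popt)
    resid = float(np.linalg.norm(y - _boltzmann(v, *popt)))
    return BoltzmannFit(v50=v50, k=k, amplitude=amplitude,
                        residual_norm=resid, n_points=v.size)


def fit_activation(v: np.ndarray, g: np.ndarray) -> BoltzmannFit:
    """Fit the conductance-voltage relation with an ascending Boltzmann.

    ``g`` may be raw (nS) or normalized; the fitted amplitude is G_max.
    """
    return _fit_boltzmann(v, g, k_sign=+1.0)


def fit_inactivation(v: np.ndarray, availability: np.ndarray) -> BoltzmannFit:
    """Fit normalized availability against prepulse potential (descending)."""
    return _fit_boltzmann(v, availability, k_sign=-1.0)


def _biexp(t, a_f, tau_f, a_s, tau_s, c):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + c


def fit_decay(
    t: np.ndarray,
    i: np.ndarray,
    step_onset_ms: float,
    step_end_ms: float,
    exclude_ms: float = 1.0,
) -> DecayFit:
    """Biexponential fit of the transient-current decay.

    The fit window starts ``exclude_ms`` (default 1.0 ms) after the step onset
    and runs to the step end; samples before the exclusion never contribute.
    Time constants are ordered so that ``tau_fast <= tau_slow``.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    mask = (t >= step_onset_ms + exclude_ms - 1e-12) & (t <= step_end_ms + 1e-12)
    if mask.sum() < 5:
        raise FitError("decay window holds fewer than 5 samples")
    tw = t[mask] - (step_onset_ms + exclude_ms)
    iw = i[mask]
    span = tw[-1] if tw[-1] > 0 else 1.0
    c0 = float(np.mean(iw[-max(3, iw.size // 20):]))
    a0 = float(iw[0] - c0)
    p0 = [0.7 * a0, span / 20.0, 0.3 * a0, span / 3.0, c0]
    lo = [-np.inf, 1e-4, -np.inf, 1e-4, -np.inf]
    hi = [np.inf, 50.0 * span, np.inf, 50.0 * span, np.inf]
    try:
        popt, _ = curve_fit(_biexp, tw, iw, p0=p0, bounds=(lo, hi),
                            maxfev=_MAX_NFEV, xtol=_TOL, ftol=_TOL, gtol=_TOL)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"biexponential fit failed: {exc}") from exc
    a_f, tau_f, a_s, tau_s, c = map(float, popt)
    if tau_f > tau_s:
        a_f, tau_f, a_s, tau_s = a_s, tau_s, a_f, tau_f
    resid = float(np.linalg.norm(iw - _biexp(tw, *popt)))
    return DecayFit(tau_fast=tau_f, tau_slow=tau_s, amp_fast=a_f,
                    amp_slow=a_s, offset=c, residual_norm=resid)


def _recovery_model(t, tau, a, c):
    return c - a * np.exp(-t / tau)


def fit_recovery(gaps_ms: np.ndarray, fractions: np.ndarray) -> RecoveryFit:
    """Single-exponential fit of recovered fraction against gap duration."""
    t = np.asarray(gaps_ms, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size < 4:
        raise FitError("need at least 4 gap durations")
    c0 = float(np.max(y))
    a0 = max(c0 - float(y[np.argmin(t)]), 1e-6)
    tau0 = float(np.median(t))
    try:
        popt, _ = curve_fit(
            _recovery_model, t, y, p0=[tau0, a0, c0],
            bounds=([1e-4, 0.0, -np.inf], [1e5, np.inf, np.inf]),
            maxfev=_MAX_NFEV, xtol=_TOL, ftol=_TOL, gtol=_TOL)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"recovery fit failed: {exc}") from exc
    tau, a, c = map(float, popt)
    resid = float(np.linalg.norm(y - _recovery_model(t, *popt)))
    return RecoveryFit(tau=tau, amplitude=a, offset=c, residual_norm=resid)


def current_density(peaks_pa: np.ndarray, capacitance_pf: float) -> np.ndarray:
    """Normalize peak currents (pA) to cell capacitance (pF) -> pA/pF."""
    if not (capacitance_pf and capacitance_pf > 0):
        raise InvalidParameterError("capacitance must be > 0")
    return np.asarray(peaks_pa, dtype=float) / capacitance_pf


def percent_change(reference: float, test: float) -> float:
    """Percent reduction of |test| relative to |reference|.

    ``100 * (|reference| - |test|) / |reference|``; positive = reduction,
    negative = increase.  Returns the raw (unrounded) value.
    """
    if reference == 0:
        raise InvalidParameterError("reference magnitude must be nonzero")
    return 100.0 * (abs(reference) - abs(test)) / abs(reference)


def round_percent(x: float) -> int:
    """Round to integer percent, half away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def midpoint_shift(fit_a: BoltzmannFit, fit_b: BoltzmannFit) -> float:
    """V50(a) - V50(b) in mV; positive = a depolarized relative to b."""
    return fit_a.v50 - fit_b.v50


# ---------------------------------------------------------------------------
# Sweep-set-level pipelines
# ---------------------------------------------------------------------------

def analyze_iv(ss: SweepSet, v_rev: float | None = None) -> dict:
    """Full I-V analysis: peaks, reversal, conductance and activation fit.

    If ``v_rev`` is not given it is estimated from the zero crossing of the
    ascending limb of the peak I-V relation.  Voltages at or above the
    reversal are excluded from the conductance transform.
    """
    points = iv_curve(ss)
    v = points["step_mV"].to_numpy()
    peaks = points["peak_pA"].to_numpy()
    if v_rev is None:
        v_rev = estimate_reversal(v, peaks)
    mask = v < v_rev - 1.0
    g = conductance(peaks[mask], v[mask], v_rev)
    fit = fit_activation(v[mask], g)
    out = {"points": points, "v_rev": float(v_rev),
           "conductance_nS": pd.DataFrame({"step_mV": v[mask], "G_nS": g}),
           "activation_fit": fit}
    if ss.capacitance_pf:
        out["density_pA_per_pF"] = pd.DataFrame({
            "step_mV": v,
            "density": current_density(peaks, ss.capacitance_pf),
        })
    return out


def analyze_ssi(ss: SweepSet) -> dict:
    """Steady-state inactivation analysis with max-normalized availability."""
    points = ssi_curve(ss)
    v = points["prepulse_mV"].to_numpy()
    peaks = points["test_peak_pA"].to_numpy()
    i_max = np.max(np.abs(peaks))
    if i_max == 0:
        raise FitError("all test-pulse currents are zero")
    avail = np.abs(peaks) / i_max
    fit = fit_inactivation(v, avail)
    points = points.assign(availability=avail)
    return {"points": points, "inactivation_fit": fit}


def analyze_recovery(ss: SweepSet) -> dict:
    """Recovery-from-fast-inactivation analysis."""
    points = recovery_curve(ss)
    fit = fit_recovery(points["gap_ms"].to_numpy(),
                       points["fraction"].to_numpy())
    return {"points": points, "recovery_fit": fit}


# ---------------------------------------------------------------------------
# Published experimental group means (inputs for worked-example comparisons).
# Current densities in pA/pF at the 0 mV step; activation midpoints in mV.
# ---------------------------------------------------------------------------
REFERENCE_GROUP_MEANS: dict[str, float] = {
    # R850Q cohort (fluoride-free internal)
    "R850Q_density_no_peptide": -191.8,
    "R850Q_density_CN21": -115.4,
    "R850Q_density_CN21Ala": -166.4,
    "R850Q_V50act_no_peptide": -13.07,
    "R850Q_V50act_CN21": -6.94,
    "R850Q_V50act_CN21Ala": -12.50,
    # WT vs R639C characterization (fluoride internal)
    "WT_density": -225.8,
    "R639C_density": -388.0,
    "WT_V50act": -14.91,
    "R639C_V50act": -19.99,
    # R639C CN21 cohort (fluoride-free internal)
    "R639C_density_no_peptide": -273.53,
    "R639C_density_CN21": -137.45,
    "R639C_density_CN21Ala": -334.45,
}
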
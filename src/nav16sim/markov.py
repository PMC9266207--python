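"""Thirteen-state Markov model of Nav1.6 gating.

The scheme is the resurgent-sodium kinetic model widely used for Purkinje-type
sodium currents: five closed states (C1..C5) coupled to an open state (O), an
open-blocked state (OB) entered at rate ``epsilon`` (held at 0 here, which
removes resurgent current), and a parallel tier of six inactivated states
(I1..I6).  Horizontal transitions along the closed tier carry the usual
4:3:2:1 subunit multiplicities; closed-state inactivation on/off rates grow
along the ladder through the allosteric factors

    alfac = (Oon / Con) ** (1/4)        (forward, C->I and inactivated-tier forward)
    btfac = (Ooff / Coff) ** (1/4)      (backward)

so that every closed/inactivated rectangle obeys detailed balance whenever the
two tiers share their voltage-dependent rates.  The inactivated tier carries
its own base rates (``alpha_i0``, ``beta_i0``), which partially uncouples the
voltage dependence of activation and inactivation; the six shipped parameter
conditions (wild type, two epilepsy mutants, each with and without CaMKII
inhibition) differ only in the handful of rates listed in their preset table.

Conventions
-----------
* State order: ``C1..C5, O, OB, I1..I6`` (indices 0..12).
* Row-vector master equation ``dp/dt = p @ Q``; rows of ``Q`` sum to zero.
* Rates in ms^-1, voltages in mV, currents in pA (``gbar`` in nS).
* Voltage dependence: ``alpha(V) = alpha0*exp(V/k_alpha)``,
  ``beta(V) = beta0*exp(-V/k_beta)``, ``zeta(V) = zeta0*exp(-V/k_zeta)``;
  ``gamma``, ``delta`` and all on/off inactivation rates are voltage
  independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .errors import (
    IntegrationInstabilityError,
    InvalidParameterError,
)

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "OPEN",
    "BLOCKED",
    "RateConstants",
    "MacroscopicCurrentParams",
    "PRESETS",
    "PRESET_NAMES",
    "get_preset",
    "load_presets",
    "save_presets",
    "build_generator",
    "steady_state",
    "integrate_occupancy",
    "validate_occupancy",
    "current",
]

STATE_NAMES = ("C1", "C2", "C3", "C4", "C5", "O", "OB",
               "I1", "I2", "I3", "I4", "I5", "I6")
N_STATES = 13
OPEN = 5
BLOCKED = 6
_I1 = 7

#: tolerance on sum(p) == 1 for occupancy vectors
OCCUPANCY_ATOL = 1e-8


@dataclass(frozen=True)
class RateConstants:
    """Full kinetic parameterization of one channel condition.

    Base rates are the values at 0 mV (ms^-1); ``k_alpha``/``k_beta``/
    ``k_zeta`` are e-fold voltage constants in mV.  ``density_scale``
    multiplies the maximal conductance and encodes relative current density
    between conditions.
    """

    alpha0: float = 150.0
    beta0: float = 3.0
    alpha_i0: float = 150.0
    beta_i0: float = 3.0
    gamma0: float = 150.0
    delta0: float = 40.0
    epsilon: float = 0.0
    zeta0: float = 0.03
    Con: float = 0.005
    Coff: float = 0.5
    Oon: float = 0.75
    Ooff: float = 0.005
    density_scale: float = 1.0
    k_alpha: float = 20.0
    k_beta: float = 20.0
    k_zeta: float = 25.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "alpha_i0", "beta_i0", "gamma0",
                     "delta0", "epsilon", "zeta0", "Con", "Coff", "Oon",
                     "Ooff", "density_scale", "k_alpha", "k_beta", "k_zeta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")
        if self.density_scale <= 0:
            raise InvalidParameterError("density_scale must be > 0")

    # -- derived allosteric factors (recomputed on access, so they can never
    #    fall out of sync with the on/off rates they are built from) --------
    @property
    def alfac(self) -> float:
        """Forward allosteric ladder factor, (Oon/Con)**(1/4).

        Defined as 1 for degenerate rate sets with no closed-state
        inactivation (Con = 0), where the ladder carries no flux anyway.
        """
        return (self.Oon / self.Con) ** 0.25 if self.Con > 0 else 1.0

    @property
    def btfac(self) -> float:
        """Backward allosteric ladder factor, (Ooff/Coff)**(1/4)."""
        return (self.Ooff / self.Coff) ** 0.25 if self.Coff > 0 else 1.0

    @property
    def a(self) -> float:
        """Combined allosteric factor (Oon*Coff / (Ooff*Con))**(1/4)."""
        return self.alfac / self.btfac

    def replace(self, **changes) -> "RateConstants":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        return cls(**d)


@dataclass(frozen=True)
class MacroscopicCurrentParams:
    """Maximal conductance (nS, before density scaling) and Na reversal (mV).

    The +68 mV default reversal is the Nernst potential for 140 mM external /
    10 mM internal Na+ at 22 degrees C.
    """

    gbar: float = 50.0
    E_Na: float = 68.0

    def __post_init__(self) -> None:
        if not (self.gbar > 0 and math.isfinite(self.gbar)):
            raise InvalidParameterError("gbar must be positive and finite")
        if not math.isfinite(self.E_Na):
            raise InvalidParameterError("E_Na must be finite")


# ---------------------------------------------------------------------------
# Shipped channel conditions.  Each condition lists only the rates that differ
# between conditions (density, Coff, Oon, Ooff, epsilon, alpha, beta, alpha_i,
# beta_i, gamma); everything else takes the canonical defaults above.
# ---------------------------------------------------------------------------
PRESETS: dict[str, RateConstants] = {
    "WT": RateConstants(),
    "WT+CN21": RateConstants(density_scale=0.300, Oon=1.3, alpha0=92.0),
    "R639C": RateConstants(density_scale=1.72, Coff=0.25, Ooff=0.007,
                           alpha0=277.5, beta0=3.7, alpha_i0=110.0,
                           beta_i0=4.0, gamma0=130.0),
    "R639C+CN21": RateConstants(density_scale=0.878, Coff=0.25, Ooff=0.007,
                                alpha0=277.5, beta0=3.7, alpha_i0=110.0,
                                beta_i0=4.0, gamma0=130.0),
    "R850Q": RateConstants(density_scale=1.23, Coff=0.4, Oon=1.018,
                           Ooff=0.018, alpha0=85.0, beta0=0.9,
                           alpha_i0=126.0, beta_i0=3.4, gamma0=137.0),
    "R850Q+CN21": RateConstants(density_scale=0.835, Coff=0.4, Oon=1.018,
                                Ooff=0.018, alpha0=50.3, beta0=0.9,
                                alpha_i0=250.0, beta_i0=4.0, gamma0=137.0),
}
PRESET_NAMES = tuple(PRESETS)


def get_preset(name: str) -> RateConstants:
    """Return the rate constants for a named shipped condition."""
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown condition {name!r}; shipped conditions: {', '.join(PRESETS)}"
        ) from None


def load_presets(path: str | Path) -> dict[str, RateConstants]:
    """Load a user-supplied JSON table of named conditions."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: RateConstants.from_dict(d) for name, d in raw.items()}


def save_presets(presets: dict[str, RateConstants], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in presets.items()}, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# Generator matrix
# ---------------------------------------------------------------------------

def build_generator(V: float, rates: RateConstants) -> np.ndarray:
    """Evaluate the 13x13 generator matrix Q at a command voltage.

    Convention ``dp/dt = p @ Q``: entry ``Q[i, j]`` (i != j) is the transition
    rate from state i to state j; diagonal entries make each row sum to zero.
    """
    if not math.isfinite(V):
        raise InvalidParameterError(f"voltage must be finite, got {V!r}")
    al = rates.alpha0 * math.exp(V / rates.k_alpha)
    be = rates.beta0 * math.exp(-V / rates.k_beta)
    al_i = rates.alpha_i0 * math.exp(V / rates.k_alpha)
    be_i = rates.beta_i0 * math.exp(-V / rates.k_beta)
    ze = rates.zeta0 * math.exp(-V / rates.k_zeta)
    af, bf = rates.alfac, rates.btfac

    Q = np.zeros((N_STATES, N_STATES))
    # closed tier C1..C5 (0..4): forward 4a,3a,2a,a; backward b,2b,3b,4b
    for n in range(4):
        Q[n, n + 1] = (4 - n) * al
        Q[n + 1, n] = (n + 1) * be
    # opening / closing
    Q[4, OPEN] = rates.gamma0
    Q[OPEN, 4] = rates.delta0
    # open-channel block (inactive when epsilon == 0)
    Q[OPEN, BLOCKED] = rates.epsilon
    Q[BLOCKED, OPEN] = ze
    # inactivated tier I1..I5 (7..11) mirrors the closed tier with its own
    # base rates scaled by the allosteric ladder factors
    for n in range(4):
        Q[_I1 + n, _I1 + n + 1] = (4 - n) * al_i * af
        Q[_I1 + n + 1, _I1 + n] = (n + 1) * be_i * bf
    # I5 <-> I6 mirrors C5 <-> O
    Q[11, 12] = rates.gamma0
    Q[12, 11] = rates.delta0
    # vertical inactivation ladder
    for n in range(5):
        Q[n, _I1 + n] = rates.Con * af ** n
        Q[_I1 + n, n] = rates.Coff * bf ** n
    Q[OPEN, 12] = rates.Oon
    Q[12, OPEN] = rates.Ooff

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_occupancy(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Check an occupancy vector (or array of them) and return it unchanged."""
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != N_STATES:
        raise InvalidParameterError(
            f"occupancy must have {N_STATES} entries, got shape {p.shape}")
    if np.any(p < -atol) or np.any(p > 1 + atol):
        raise IntegrationInstabilityError("occupancy left [0, 1] beyond tolerance")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > max(atol, OCCUPANCY_ATOL)):
        raise IntegrationInstabilityError("occupancy does not sum to 1")
    return p


def steady_state(V: float, rates: RateConstants) -> np.ndarray:
    """Stationary occupancy at a fixed voltage (left null vector of Q).

    Solves ``p @ Q = 0`` with ``sum(p) = 1`` by least squares on the
    normalization-augmented system; raises a linear-algebra error if the
    result is not a valid probability vector.
    """
    Q = build_generator(V, rates)
    A = np.vstack([Q.T, np.ones(N_STATES)])
    b = np.zeros(N_STATES + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-8 \
            or np.linalg.norm(p @ Q) > 1e-8:
        raise np.linalg.LinAlgError(
            "generator has no nonnegative stationary distribution")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def integrate_occupancy(
    p0: np.ndarray,
    segments: Sequence[tuple[float, float]],
    rates: RateConstants,
    dt: float = 0.025,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate occupancies through piecewise-constant voltage segments.

    Parameters
    ----------
    p0 : initial occupancy (13,)
    segments : sequence of ``(level_mV, duration_ms)``
    dt : sample interval, ms

    Returns ``(t, P)`` where ``t`` has shape (n,) starting at 0 and ``P`` has
    shape (n, 13); the initial condition is included as the first sample.
    Within a segment the generator is constant, so stepping uses the matrix
    exponential ``p_{k+1} = p_k @ expm(Q dt)``, which conserves probability to
    machine precision and is unconditionally stable.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    p = validate_occupancy(np.asarray(p0, dtype=float).copy())
    chunks_t: list[np.ndarray] = [np.array([0.0])]
    chunks_p: list[np.ndarray] = [p[None, :]]
    t0 = 0.0
    for level, duration in segments:
        if duration <= 0:
            raise InvalidParameterError("segment durations must be > 0")
        nsteps = max(1, int(round(duration / dt)))
        M = expm(build_generator(level, rates) * dt)
        block = np.empty((nsteps, N_STATES))
        for k in range(nsteps):
            p = p @ M
            block[k] = p
        chunks_p.append(block)
        chunks_t.append(t0 + dt * np.arange(1, nsteps + 1))
        t0 += nsteps * dt
    t = np.concatenate(chunks_t)
    P = np.concatenate(chunks_p, axis=0)
    validate_occupancy(P)
    return t, P


def current(
    popen: np.ndarray | float,
    V: np.ndarray | float,
    mp: MacroscopicCurrentParams,
    density_scale: float = 1.0,
) -> np.ndarray:
    """Macroscopic current I = density_scale * gbar * popen * (V - E_Na).

    ``popen`` and ``V`` broadcast against each other; with gbar in nS and V in
    mV the result is in pA (inward currents negative below the reversal).
    """
    popen = np.asarray(popen, dtype=float)
    if np.any(popen < -1e-9) or np.any(popen > 1 + 1e-9):
        raise InvalidParameterError("open probability must lie in [0, 1]")
    if density_scale <= 0:
        raise InvalidParameterError("density_scale must be > 0")
    return density_scale * mp.gbar * popen * (np.asarray(V, dtype=float) - mp.E_Na)
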
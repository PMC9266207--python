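"""Synthetic whole-cell recordings with known ground truth.

Emulates idealized patch-clamp acquisitions of the modeled channel: per-cell
capacitance and maximal conductance drawn from lognormal distributions,
optional linear leak, and additive i.i.d. Gaussian noise.  Series-resistance
and capacitive-transient artifacts are deliberately absent (experimental
recordings compensate them), so a zero-noise, zero-leak cell reproduces the
clean protocol simulation exactly — the property that makes every analysis
operation testable against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as nav_io
from .errors import InvalidParameterError
from .markov import MacroscopicCurrentParams, RateConstants, get_preset
from .protocols import SweepSet, VoltageProtocol, run_protocol

__all__ = ["SyntheticCellSpec", "GroundTruthRecord", "generate_cell",
           "generate_cohort"]

#: lognormal medians / log-sigmas for per-cell parameters when not pinned
CAPACITANCE_MEDIAN_PF = 12.0
CAPACITANCE_LOG_SIGMA = 0.25
GBAR_MEDIAN_NS = 50.0
GBAR_LOG_SIGMA = 0.30


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Recipe for one synthetic cell.

    ``condition`` is a shipped preset name or explicit
    :class:`~nav16sim.markov.RateConstants`.  ``capacitance_pf`` / ``gbar_ns``
    default to lognormal draws (medians above).  ``noise_sigma_pa`` is the
    standard deviation of the additive Gaussian noise; ``leak_g_ns`` adds a
    linear leak ``g_leak * (V - e_leak)``.
    """

    condition: str | RateConstants = "WT"
    capacitance_pf: float | None = None
    gbar_ns: float | None = None
    noise_sigma_pa: float = 20.0
    leak_g_ns: float = 0.0
    e_leak_mv: float = 0.0
    e_na_mv: float = 68.0
    seed: int = 0

    def rates(self) -> RateConstants:
        if isinstance(self.condition, RateConstants):
            return self.condition
        return get_preset(self.condition)

    def condition_name(self) -> str:
        return self.condition if isinstance(self.condition, str) else "custom"


@dataclass(frozen=True)
class GroundTruthRecord:
    """The generating parameters of one synthetic cell (serialized with it)."""

    condition: str
    rates: dict
    gbar_ns: float
    capacitance_pf: float
    noise_sigma_pa: float
    leak_g_ns: float
    e_leak_mv: float
    e_na_mv: float
    seed: int
    protocol_kind: str

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_cell_params(spec: SyntheticCellSpec,
                      rng: np.random.Generator) -> tuple[float, float]:
    cap = spec.capacitance_pf
    if cap is None:
        cap = float(np.exp(np.log(CAPACITANCE_MEDIAN_PF)
                           + CAPACITANCE_LOG_SIGMA * rng.standard_normal()))
    gbar = spec.gbar_ns
    if gbar is None:
        gbar = float(np.exp(np.log(GBAR_MEDIAN_NS)
                            + GBAR_LOG_SIGMA * rng.standard_normal()))
    if cap <= 0 or gbar <= 0:
        raise InvalidParameterError("capacitance and gbar must be > 0")
    return cap, gbar


def generate_cell(
    spec: SyntheticCellSpec,
    protocol: VoltageProtocol,
) -> tuple[SweepSet, GroundTruthRecord]:
    """Simulate one synthetic cell through a protocol.

    Deterministic given ``spec.seed``: the same spec and protocol always
    yield bit-identical sweeps.
    """
    rng = np.random.default_rng(spec.seed)
    cap, gbar = _draw_cell_params(spec, rng)
    rates = spec.rates()
    mp = MacroscopicCurrentParams(gbar=gbar, E_Na=spec.e_na_mv)
    ss = run_protocol(protocol, rates, mp)
    for k in range(ss.n_sweeps):
        tr = ss.traces[k]
        if spec.leak_g_ns > 0:
            tr = tr + spec.leak_g_ns * (ss.commands[k] - spec.e_leak_mv)
        if spec.noise_sigma_pa > 0:
            tr = tr + rng.normal(0.0, spec.noise_sigma_pa, tr.size)
        ss.traces[k] = tr
    ss.capacitance_pf = cap
    ss.condition = spec.condition_name()
    ss.seed = spec.seed
    ss.meta = {"gbar_ns": gbar, "noise_sigma_pa": spec.noise_sigma_pa,
               "leak_g_ns": spec.leak_g_ns}
    truth = GroundTruthRecord(
        condition=ss.condition, rates=rates.to_dict(), gbar_ns=gbar,
        capacitance_pf=cap, noise_sigma_pa=spec.noise_sigma_pa,
        leak_g_ns=spec.leak_g_ns, e_leak_mv=spec.e_leak_mv,
        e_na_mv=spec.e_na_mv, seed=spec.seed, protocol_kind=protocol.kind)
    return ss, truth


def generate_cohort(
    n_cells: int,
    spec: SyntheticCellSpec,
    protocols: dict[str, VoltageProtocol],
    out_dir: str | Path,
    seed: int = 0,
    overwrite: bool = False,
) -> dict:
    """Generate a directory of synthetic cells and write a manifest.

    The cohort seed controls per-cell seeds through a
    :class:`numpy.random.SeedSequence` spawn, so two cohorts built from the
    same arguments are file-for-file identical.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_cells)]
    manifest: dict = {"cohort_seed": seed, "n_cells": n_cells,
                      "condition": spec.condition_name(), "cells": []}
    for c in range(n_cells):
        cell_spec = SyntheticCellSpec(
            condition=spec.condition, capacitance_pf=spec.capacitance_pf,
            gbar_ns=spec.gbar_ns, noise_sigma_pa=spec.noise_sigma_pa,
            leak_g_ns=spec.leak_g_ns, e_leak_mv=spec.e_leak_mv,
            e_na_mv=spec.e_na_mv, seed=child_seeds[c])
        entry = {"cell": c, "seed": child_seeds[c], "files": {}}
        for pname, proto in protocols.items():
            ss, truth = generate_cell(cell_spec, proto)
            csv_path = out_dir / f"cell_{c:03d}_{pname}.csv"
            nav_io.write_sweep_csv(ss, csv_path)
            truth_path = out_dir / f"cell_{c:03d}_{pname}.truth.json"
            with open(truth_path, "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1)
            entry["files"][pname] = {"sweeps": csv_path.name,
                                     "truth": truth_path.name}
        manifest["cells"].append(entry)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
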
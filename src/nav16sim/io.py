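"""CSV/JSON readers and writers for sweep sets and protocols.

Sweeps are written as a plain comma-separated table — first column ``time_ms``,
one column per sweep (``sweep_000`` ...) — with a JSON sidecar
(``<stem>.json``) carrying the protocol descriptor, per-sweep command values,
capacitance, condition name, seed and a provenance block.  Ragged sweep
families (recovery protocols) are padded with empty cells.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .errors import SweepParseError
from .protocols import SweepSet, VoltageProtocol

__all__ = ["write_sweep_csv", "read_sweep_csv", "sidecar_path"]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def _provenance(meta: dict) -> dict:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return {
        "package": "nav16sim",
        "version": __version__,
        "config_sha1": hashlib.sha1(blob).hexdigest(),
    }


def write_sweep_csv(ss: SweepSet, path: str | Path) -> Path:
    """Write a sweep set as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = ss.n_sweeps
    lengths = [tr.size for tr in ss.traces]
    t_ref = ss.times[int(np.argmax(lengths))]
    with open(path, "w") as fh:
        fh.write("time_ms," + ",".join(f"sweep_{k:03d}" for k in range(n)) + "\n")
        for row in range(t_ref.size):
            cells = [f"{t_ref[row]:.6g}"]
            for k in range(n):
                cells.append(repr(float(ss.traces[k][row]))
                             if row < lengths[k] else "")
            fh.write(",".join(cells) + "\n")
    side = {
        "protocol": ss.protocol.to_dict(),
        "capacitance_pf": ss.capacitance_pf,
        "condition": ss.condition,
        "seed": ss.seed,
        "meta": ss.meta,
    }
    side["provenance"] = _provenance(side)
    with open(sidecar_path(path), "w") as fh:
        json.dump(side, fh, indent=1)
    return path


def read_sweep_csv(path: str | Path) -> SweepSet:
    """Read a sweep CSV (+ sidecar) back into a :class:`SweepSet`.

    A missing sidecar degrades gracefully (warning; a generic single-segment
    protocol is reconstructed from the time axis and capacitance is absent).
    Ragged or malformed rows raise :class:`SweepParseError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        cols = header.split(",")
        if not cols or cols[0] != "time_ms":
            raise SweepParseError(f"{path}:1: expected 'time_ms' first column")
        n = len(cols) - 1
        if n < 1:
            raise SweepParseError(f"{path}:1: no sweep columns")
        t_rows: list[float] = []
        data: list[list[float]] = [[] for _ in range(n)]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != n + 1:
                raise SweepParseError(
                    f"{path}:{lineno}: expected {n + 1} cells, got {len(cells)}")
            try:
                t_rows.append(float(cells[0]))
                for k, c in enumerate(cells[1:]):
                    if c != "":
                        data[k].append(float(c))
            except ValueError as exc:
                raise SweepParseError(f"{path}:{lineno}: {exc}") from exc
    t_full = np.asarray(t_rows)

    side_file = sidecar_path(path)
    if side_file.exists():
        with open(side_file) as fh:
            side = json.load(fh)
        protocol = VoltageProtocol.from_dict(side["protocol"])
        cap = side.get("capacitance_pf")
        condition = side.get("condition")
        seed = side.get("seed")
        meta = side.get("meta", {})
    else:
        warnings.warn(f"no sidecar JSON next to {path}; metadata degraded",
                      stacklevel=2)
        dt = float(t_full[1] - t_full[0]) if t_full.size > 1 else 1.0
        dur = float(t_full[-1]) if t_full.size > 1 else 1.0
        protocol = VoltageProtocol(
            kind="custom", holding=np.nan,
            sweeps=[((np.nan, dur),)] * n,
            sweep_values=[float(k) for k in range(n)],
            sweep_param="sweep_index", dt=dt)
        cap = condition = seed = None
        meta = {}

    times, traces, commands = [], [], []
    for k in range(n):
        tr = np.asarray(data[k])
        times.append(t_full[: tr.size])
        sw = protocol.sweeps[k] if k < len(protocol.sweeps) else protocol.sweeps[-1]
        v = np.full(tr.size, np.nan)
        t0 = 0.0
        for level, durseg in sw:
            v[(times[k] >= t0 - 1e-12) & (times[k] <= t0 + durseg + 1e-12)] = level
            t0 += durseg
        commands.append(v)
        traces.append(tr)
    return SweepSet(protocol=protocol, times=times, traces=traces,
                    commands=commands, capacitance_pf=cap,
                    condition=condition, seed=seed, meta=meta)
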
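"""Minimal plotting helpers (matplotlib Agg-friendly, return the Axes)."""

from __future__ import annotations

import numpy as np

from .analysis import BoltzmannFit
from .protocols import SweepSet


def plot_sweeps(ss: SweepSet, ax=None, **kwargs):
    """Overlay all current traces of a sweep set."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for t, i in zip(ss.times, ss.traces):
        ax.plot(t, i, lw=0.8, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("current (pA)")
    return ax


def plot_boltzmann(v, y, fit: BoltzmannFit, ax=None, label=None):
    """Data points and fitted Boltzmann on a dense voltage axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(v, y, "o", ms=4, label=label)
    vv = np.linspace(min(v), max(v), 300)
    ax.plot(vv, fit(vv), "-", lw=1)
    ax.set_xlabel("voltage (mV)")
    return ax


def plot_voltage_trace(t, v, ax=None, **kwargs):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(t, v, lw=0.7, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("membrane potential (mV)")
    return ax
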
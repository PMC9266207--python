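import numpy as np
import pytest

from nav16sim import (
    MacroscopicCurrentParams,
    NeuronConfig,
    StimulusProtocol,
    build_neuron,
    get_preset,
    iv_protocol,
    run_protocol,
    simulate_evoked,
    simulate_spontaneous,
)
from nav16sim import analysis as an
from nav16sim.protocols import iv_curve
from nav16sim.synth import SyntheticCellSpec, generate_cell

#: the six shipped conditions mapped to the neuron compositions they imply
COMPOSITIONS = {
    "WT": (("WT", 1.0),),
    "WT+CN21": (("WT+CN21", 1.0),),
    "R639C": (("WT", 0.5), ("R639C", 0.5)),
    "R639C+CN21": (("WT+CN21", 0.5), ("R639C+CN21", 0.5)),
    "R850Q": (("WT", 0.5), ("R850Q", 0.5)),
    "R850Q+CN21": (("WT+CN21", 0.5), ("R850Q+CN21", 0.5)),
}

EVOKED_AMPS = (0.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def wt():
    return get_preset("WT")


@pytest.fixture(scope="session")
def mp():
    return MacroscopicCurrentParams(gbar=50.0)


@pytest.fixture(scope="session")
def wt_iv_sweeps(wt, mp):
    """Clean WT current-voltage family from the fluoride-protocol holding."""
    return run_protocol(iv_protocol(-100.0), wt, mp)


@pytest.fixture(scope="session")
def firing_stats():
    """Spontaneous and evoked firing for all six channel conditions.

    Expensive (a few dozen membrane simulations); shared session-wide.
    """
    stats = {}
    for name, comp in COMPOSITIONS.items():
        model = build_neuron(NeuronConfig(composition=comp))
        spont = simulate_spontaneous(model)
        evoked = simulate_evoked(model, StimulusProtocol(amplitudes=EVOKED_AMPS))
        stats[name] = {
            "spontaneous_hz": spont.frequency_hz,
            "n_spont_spikes": len(spont.spike_times_ms),
            "evoked_hz": dict(zip(EVOKED_AMPS,
                                  evoked.evoked["frequency_hz"])),
        }
    return stats


@pytest.fixture(scope="session")
def cohort_v50_recovery(wt, mp):
    """Mean activation midpoint recovered from a 10-cell noisy cohort.

    Noise SD is 2% of the WT peak transient current; seeds are fixed, so the
    result is reproducible.  Returns (noiseless V50, cohort-mean V50).
    """
    proto = iv_protocol(-100.0)
    clean = run_protocol(proto, wt, mp)
    sigma = 0.02 * float(np.abs(iv_curve(clean).peak_pA).max())
    truth = an.analyze_iv(clean)["activation_fit"].v50
    v50s = []
    for seed in range(10):
        spec = SyntheticCellSpec(condition="WT", gbar_ns=mp.gbar,
                                 capacitance_pf=12.0, noise_sigma_pa=sigma,
                                 seed=seed)
        ss, _ = generate_cell(spec, proto)
        v50s.append(an.analyze_iv(ss)["activation_fit"].v50)
    return truth, float(np.mean(v50s))
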
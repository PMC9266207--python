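# nav16sim

Kinetic modelling and in-silico electrophysiology of the neuronal voltage-gated
sodium channel Nav1.6 (*SCN8A*), for studying how CaMKII modulation reshapes
wild-type and epilepsy-mutant channel function and neuronal excitability.

The package is aimed at channel biophysicists and computational
neuroscientists who want a self-contained, scriptable pipeline that goes from
a kinetic parameter table to whole-cell-style measurements and single-neuron
firing statistics — with a synthetic-data generator so every analysis step is
testable against known ground truth.

## What it implements

**Channel model.** A 13-state Markov scheme of the resurgent-sodium type:
closed states C1–C5 with 4α/3α/2α/α activation steps (backward β…4β), an open
state O (C5→O rate γ, O→C5 rate δ), an open-blocked state OB (entry rate ε,
fixed at 0 here so resurgent current is absent), and inactivated states I1–I6
coupled vertically through an allosteric ladder built from
`alfac = (Oon/Con)^¼` and `btfac = (Ooff/Coff)^¼`. Voltage dependence is
exponential, e.g. `α(V) = α₀·exp(V/kα)` with kα = 20 mV. Six parameter
conditions ship as presets: `WT`, `R639C`, `R850Q`, each with and without
CaMKII inhibition (`+CN21`), differing in relative current density and a
small set of rates.

**Voltage clamp.** The three standard characterization protocols — I–V step
family (−80…+60 mV, 50 ms), steady-state inactivation (500 ms prepulses
−130…+40 mV, 20 ms test pulse at 0 mV) and paired-pulse recovery from fast
inactivation — run against any condition via exact per-segment
matrix-exponential propagation.

**Analysis.** Chord conductance `G = I/(V − V_rev)`, Boltzmann fits
`G/G_max = 1/(1+exp((V50−V)/k))` for activation and availability,
biexponential decay of the transient current (fit starting 1 ms into the
step), single-exponential recovery, persistent current (mean over the last
5 ms of the step), capacitance-normalized current density, and the
percent-change / midpoint-shift arithmetic used to compare conditions.

**Synthetic recordings.** Whole-cell-like cohorts with lognormal cell
capacitance and conductance, optional linear leak and additive Gaussian
noise, written as CSV + JSON with full ground truth for parameter-recovery
testing.

**Neuron model.** A single-compartment Purkinje-style pacemaker
(`C dV/dt = −ΣI_ion + I_stim`) carrying one or two Markov Nav1.6 populations
(50/50 for heterozygous expression), a fast delayed-rectifier K⁺ current, an
SK-like slow AHP K⁺ current and an ohmic leak; spontaneous and evoked firing
are quantified by threshold-crossing spike detection.

## Worked example

```python
import nav16sim as nv

# 1. simulate a clean I-V family for wild type and fit activation
mp = nv.MacroscopicCurrentParams(gbar=50.0, E_Na=68.0)   # nS, mV
ss = nv.run_protocol(nv.iv_protocol(holding=-100.0), nv.get_preset("WT"), mp)
res = nv.analyze_iv(ss)
print(round(res["v_rev"], 2), round(res["activation_fit"].v50, 2))
# 67.99 -31.62   (estimated reversal mV, activation midpoint mV)

# 2. compare conditions the way group data are compared
raw = nv.percent_change(-166.4, -115.4)     # reference vs test density, pA/pF
print(nv.round_percent(raw))
# 31   (percent reduction in current density)

# 3. heterozygous mutant excitability
wt = nv.build_neuron(nv.NeuronConfig(composition=(("WT", 1.0),)))
het = nv.build_neuron(nv.NeuronConfig(
    composition=(("WT", 0.5), ("R639C", 0.5))))
f_wt = nv.simulate_spontaneous(wt).frequency_hz
f_het = nv.simulate_spontaneous(het).frequency_hz
print(f_wt, f_het, round(100 * (f_het / f_wt - 1), 1))
# 23.0 38.5 67.4   (Hz, Hz, percent increase)
```

A command-line interface mirrors the library:

```bash
nav16sim simulate-clamp --condition WT+CN21 --protocol iv --holding -80 --out sweeps.csv
nav16sim generate --condition R639C --n-cells 10 --seed 42 --out cohort/
nav16sim analyze --in cohort/cell_000_iv.csv --out cell0.json
nav16sim simulate-neuron --genotype R850Q --camkii-inhibited --out run/
nav16sim report --reference ctrl.json --test inhibited.json
```

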
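# Methods

## Channel gating model

Sodium currents are generated by a 13-state Markov scheme of the
resurgent-sodium family: five closed states (C1–C5), one open state (O), one
open-blocked state (OB) and six inactivated states (I1–I6). Occupancies
evolve by the master equation `dp/dt = p·Q(V)` (row-vector convention; rows
of the generator sum to zero). Transitions:

* Closed tier: C1→C2…C4→C5 at 4α, 3α, 2α, α; backward β, 2β, 3β, 4β, with
  `α(V) = α₀·exp(V/kα)` and `β(V) = β₀·exp(−V/kβ)`, kα = kβ = 20 mV.
* Opening: C5→O at γ, O→C5 at δ (voltage independent); I5→I6 mirrors it.
* Open-channel block: O→OB at ε, OB→O at `ζ₀·exp(−V/kζ)`. All shipped
  conditions fix ε = 0, which removes resurgent current; OB is then
  unreachable and its occupancy is identically zero (a tested invariant).
* Inactivation ladder: Cn→In at `Con·alfac^(n−1)`, In→Cn at
  `Coff·btfac^(n−1)`, O→I6 at Oon, I6→O at Ooff, with the allosteric factors
  `alfac = (Oon/Con)^¼` and `btfac = (Ooff/Coff)^¼`. The inactivated tier
  repeats the closed-tier multiplicities with its own base rates:
  forward `(4…1)·α_i·alfac`, backward `(1…4)·β_i·btfac`. Giving the
  inactivated tier independent base rates (α_i, β_i) partially uncouples the
  voltage dependence of activation and inactivation; the same 20 mV e-fold
  constants are used on both tiers.

With the split factors, every closed/inactivated rectangle satisfies detailed
balance whenever the two tiers share rates (α·β_i = α_i·β), and the
C5–O–I6–I5 end loop balances identically because `Con·alfac⁴ = Oon` and
`Coff·btfac⁴ = Ooff`. An alternative convention folds both factors into a
single `a = alfac/btfac` applied to the vertical ladder; we rejected it
because it inflates closed-state inactivation at C5 by the factor Coff/Ooff
(100× for the wild type), which visibly distorts peak open probability and
the relative current amplitudes between conditions. The combined factor `a`
is still exposed on `RateConstants` as a derived property, recomputed from
the on/off rates on every access.

### Parameter conditions

Six presets describe wild-type and mutant channels with and without CaMKII
inhibition (`+CN21`). Each preset sets the relative current density
(`density_scale`, a pure multiplier on maximal conductance) and the rates
Coff, Oon, Ooff, α₀, β₀, α_i₀, β_i₀, γ₀; everything else takes the canonical
defaults `Con = 0.005 ms⁻¹`, `δ₀ = 40 ms⁻¹`, `ζ₀ = 0.03 ms⁻¹` (kζ = 25 mV) —
ζ is irrelevant while ε = 0 but kept for completeness. The sodium reversal
default is +68 mV (Nernst for 140/10 mM external/internal Na⁺ at 22 °C).
Users can supply their own condition tables as JSON.

Degenerate rate sets are permitted for testing: if `Con = 0` (no closed-state
inactivation) the ladder factors default to 1, and the closed tier reduces to
a four-subunit activation chain whose stationary law is
Binomial(4, α/(α+β)) — used as a closed-form oracle.

## Numerics

* **Steady state** at a holding potential solves `p·Q = 0, Σp = 1` by least
  squares on the normalization-augmented system and validates nonnegativity;
  it is cross-checked against a 10 s fixed-voltage relaxation to ≤ 1e−6.
* **Propagation** across piecewise-constant voltage segments uses the matrix
  exponential `p ← p·exp(Q·dt)` with dt = 0.025 ms by default. This is exact
  at the sample times for constant voltage, unconditionally stable and
  conserves probability to machine precision, so refining dt only densifies
  the sampling grid.
* **Peak search** excludes the first 0.05 ms after a step edge so the
  instantaneous ohmic jump cannot win; the persistent current is the mean
  over the final 5 ms of the step.
* Simulated clamp sweeps are artifact-free (no leak, capacitive transient or
  series resistance); the synthetic-recordings generator adds artifacts
  where wanted.

## Fitting conventions

* Activation: `G/G_max = 1/(1+exp((V50−V)/k))` with k > 0; availability uses
  the same form with k < 0 (reported |k| is convention independent). Fits are
  bounded least squares (tolerances 1e−12, ≤ 10⁴ evaluations) initialized at
  the interpolated half-maximum crossing with k = ±5 mV.
* The reversal potential is interpolated from the zero crossing of the
  ascending I–V limb; when the protocol stops just short of reversal the last
  ascending points are extrapolated linearly, but never more than 25 mV past
  the last step — flat or deeply inward relations raise an error instead.
* Decay: two exponentials plus offset, fit from 1.0 ms after the step onset
  to the step end; time constants are ordered so τ_fast ≤ τ_slow.
* Recovery: `f(t) = f_∞ − A·exp(−t/τ)` against gap duration. Recovered
  fractions are not exactly monotone: very long gaps relax availability to
  the −80 mV steady state, slightly (< 1%) below the transient maximum.
* Steady-state inactivation is normalized to the largest test-pulse current
  across prepulses.
* Percent changes compare magnitudes of signed inward quantities,
  `100·(|ref| − |test|)/|ref|`, reported raw and rounded half-away-from-zero
  to integer percent; midpoint shifts are `V50(a) − V50(b)`, positive when
  `a` is depolarized relative to `b`.

## Synthetic recordings

Each synthetic cell draws capacitance (lognormal, median 12 pF, log-SD 0.25)
and maximal conductance (lognormal, median 50 nS, log-SD 0.30) — typical
ND7/23-style whole-cell values; with the wild-type preset they give peak
current densities around −200 pA/pF at the 0 mV step. Optional linear leak
`g_leak·(V − E_leak)` and i.i.d. Gaussian current noise are added on top of
the clean simulation. Outputs are a pure function of (spec, protocol, seed);
cohort seeds spawn per-cell seeds through `numpy.random.SeedSequence`.

The generator emulates idealized voltage-clamp acquisitions only: no series
resistance or space-clamp error, no capacitive transients, no P/N subtraction
residue, no channel rundown or liquid-junction offset, and cell-to-cell
variability enters only through capacitance/conductance scaling, not through
kinetic heterogeneity. Passing recovery tests therefore demonstrate that the
analysis is correct for data matching its idealized assumptions, not that it
is robust to every artifact of real recordings.

## Neuron model

A single compartment (1 µF/cm²) integrates

    C dV/dt = −(I_Na + I_DR + I_SK + I_leak [+ I_h + I_BK]) + I_stim

with the Markov Nav1.6 current summed over its composition — e.g.
[(WT, 0.5), (R639C, 0.5)] for heterozygous expression — each population
contributing `fraction · density_scale · g_Na`. CaMKII-inhibited neurons
switch both halves to their `+CN21` parameter sets.

The auxiliary complement is deliberately minimal:

* fast delayed rectifier, `g_K·n⁴`, `n_∞ = 1/(1+exp(−(V+30)/9))`,
  `τ_n = 0.2 + 3·exp(−((V+45)/35)²)` ms;
* SK-like slow AHP current, `g_SK·z`, `z_∞ = 1/(1+exp(−(V+45)/4))`,
  τ_z = 50 ms — a spike-count integrator that governs repetitive rates the
  way SK does in Purkinje pacemaking;
* ohmic leak; optional h-type and BK-like currents behind config flags
  (off by default).

Defaults (g_Na = 16, g_K = 10, g_SK = 0.2, g_leak = 0.12 mS/cm²,
E_leak = −62, E_K = −88, E_Na = +68 mV) were calibrated once so that the
100% wild-type neuron is a stable spontaneous pacemaker at 23 Hz whose
pacemaking is sodium-driven (it falls silent when sodium conductance is
strongly reduced, mirroring the TTX sensitivity of Purkinje pacemaking).
All condition comparisons are relative, which the calibration preserves.

Integration is fixed-step (dt = 0.005 ms): channel occupancies advance with
matrix-exponential propagators precomputed on a 0.1 mV voltage grid
(nearest-neighbour lookup), V and the HH gates use exponential-Euler
updates. The scheme conserves probability to machine precision and halving
dt changes the spontaneous rate by far less than 2% (tested). Spikes are
upward crossings of −20 mV with a 1 ms lockout; spontaneous rates discard a
1 s settle and count spikes over a 2 s window; evoked rates use 1 s current
steps after a 1 s baseline. These window lengths resolve rate differences to
0.5 Hz, adequate for the tens-of-Hz rates involved.

## Known limitations

* Resurgent current is out of scope (ε = 0 everywhere), as are stochastic
  single-channel gating and temperature scaling.
* The model reproduces relative, not absolute, voltage-clamp biophysics: the
  simulated wild-type activation midpoint (≈ −32 mV) sits hyperpolarized of
  typical whole-cell estimates, while the condition differences (midpoint
  shifts, density ratios, availability ordering) match the experimental
  pattern. Conclusions should be drawn from between-condition comparisons.
* With this minimal auxiliary complement, the heterozygous R850Q+CN21 neuron
  pacemakes at a reduced rate rather than falling fully silent: the
  R850Q+CN21 channel's large open-state off-rate (Ooff = 0.018 ms⁻¹) gives
  it ~2.6× the wild-type persistent open probability, which keeps
  subthreshold drive above this model's pacemaking threshold. Operating
  points that do silence it push the wild-type neuron to its own pacemaking
  onset and roughly double the R639C/WT rate ratio, so they were not
  adopted. A richer Purkinje conductance set with a higher pacemaking
  threshold would likely restore the full silencing.
* The multicompartment cortical-pyramidal setting is out of scope; the
  single-compartment model covers the relative-excitability questions only.
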
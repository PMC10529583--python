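# pacgate

Simulation and curve-fitting toolkit for the polymodal gating of the
proton-activated chloride (PAC / ASOR) channel: proton gating, bifunctional
small-molecule modulation, and ion-flux voltage gating, exercised entirely
on synthetic whole-cell patch-clamp summary data.

## The model

The PAC channel carries three ligand sites: **site 0** binds protons,
**site 1** binds an activating small-molecule modulator, and **site 2** is an
open-channel block site for the same molecule. Site occupancy (2³ = 8
permutations) combined with the pore state (closed/open) gives 16 candidate
states; four experimentally derived constraints — site-1 binding alone cannot
open the pore, site-2 access requires the open (hence protonated) channel, a
site-2-bound channel is trapped closed, and the pore does not open without
protons — reduce these to 8 achievable states, labelled C0–C5, O1, O2.

Equilibrium behavior is an allosteric (MWC-style) statistical-weight scheme.
With h = 10^(n_H·(pK_H − pH)) and c₁ = [drug]/K₁:

    w(C0)=1        w(C1)=h        w(C2)=c1        w(C3)=h·c1·γ
    w(O1)=h·L      w(O2)=h·c1·γ·L·φ
    w(C4)=w(O1)·[drug]/K2          w(C5)=w(O2)·[drug]/K2'

Open probability is the weight share of O1+O2. Site-1 binding multiplies both
apparent proton affinity (γ) and opening (φ): the minimal scheme that shifts
pH50 to the alkaline direction with an exactly invariant slope factor, and
that produces the observed bell-shaped (activation-then-block) dose–response
at weak acidity and pure inhibition below pH 5.

Kinetics are a continuous-time Markov master equation dP/dt = P·Q over the
same graph, with rates built to satisfy detailed balance against the
equilibrium weights edge by edge, so the stationary law always matches the
equilibrium distribution. Voltage dependence is a phenomenological
Boltzmann ion-flux gate — Y = 1/(1 + exp((V½ − orientation·V)/K)) — whose
orientation follows the permeant species (anionic wild type: depolarization-
activated; cationic selectivity-filter mutants K319E/K319Q:
hyperpolarization-activated; K319H: both), multiplying a
Goldman–Hodgkin–Katz constant-field driving force. The fitting module
implements the Hill logistic, the pH–current equation with a basal-opening
term Y0, the Boltzmann G–V, monoexponential relaxations, log-linear
current–pH slopes, and Henderson–Hasselbalch ionization.

## Worked example

```python
import numpy as np
from pacgate import analysis, presets
from pacgate.equilibrium import dose_response, apparent_markers
from pacgate.states import enumerate_candidate_states, apply_constraints

space = apply_constraints(enumerate_candidate_states())
print("achievable states:", space.labels())

wt = presets.equilibrium_preset("wt")
grid = np.concatenate([[0.0], np.logspace(-2, 2, 100)])
m = apparent_markers(dose_response(wt, 5.6, grid))
print(f"pH 5.6: EC50 = {m.ec50:.2f} uM, IC50 = {m.ic50:.1f} uM, "
      f"peak = {m.peak_amplitude:.2f}x at {m.peak_conc:.1f} uM")

rec = analysis.pooled_activation_ec50(seed=1)
print(f"recovered EC50 = {rec.value:.3f} +/- {rec.se:.3f} uM "
      f"(generating truth {rec.truth} uM, n = {rec.n} cells)")

tau = analysis.washin_time_constant()
print(f"wash-in tau at pH 5.8, 5 uM: {tau.value:.2f} s (target {tau.truth} s)")
```

prints

```
achievable states: ['C0', 'C2', 'C1', 'O1', 'C4', 'C3', 'O2', 'C5']
pH 5.6: EC50 = 1.16 uM, IC50 = 24.6 uM, peak = 2.05x at 5.6 uM
recovered EC50 = 0.594 +/- 0.011 uM (generating truth 0.6 uM, n = 16 cells)
wash-in tau at pH 5.8, 5 uM: 4.50 s (target 4.5 s)
```

The first line is the canonical 8-state roster in deterministic order
(binary occupancy code, closed before open). The second shows the
bifunctional signature at pH 5.6: the calibrated wild-type preset is
activated with an apparent EC50 of ~1.2 µM, peaks at about twice the
untreated current, and is blocked with a ~21-fold weaker IC50. The third
line is an end-to-end parameter recovery: 16 noisy synthetic
concentration–response curves are generated from the published activation
potency at pH 5.34 and refitted, returning the generating EC50 within its
standard error. The last line shows the master-equation wash-in relaxing
with the time constant the rates were calibrated to.

A `pacgate` command-line tool wraps the same functionality
(`pacgate enumerate-states`, `pacgate simulate dose-response|ph-response|
timecourse|ramp`, `pacgate fit hill|ph|boltzmann|exp|slope`,
`pacgate generate <fixture>`, `pacgate calibrate`); every file-writing
command drops a JSON manifest with the inputs, seed and package version
next to its output.

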
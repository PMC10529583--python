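# Methods

This note documents the model, its parameters and their provenance, the
synthetic-data generator, the numerical choices, and the limits of what the
test suite demonstrates.

## State space

Three ligand sites (proton site 0; modulator activation site 1; modulator
open-channel-block site 2) × pore state give 16 candidate states. Four
constraints, each a pure predicate on a single state, reduce them to 8:

1. site 1 occupied alone cannot be open;
2. site 2 occupied requires site 0 occupied;
3. site 2 occupied traps the pore closed;
4. an open pore requires site 0 occupied.

Constraint 4 is encoded as absolute for the canonical (wild-type) space.
Constitutively opening variants (A321C, F196A, F196A/R237A, D289R) are
handled by an extra unprotonated-open weight L0 in the equilibrium module —
not by enlarging the canonical space — which keeps the 16 → 8 deduction
exactly reproducible. For L0 > 0 the weight set (and the kinetic graph)
gains four non-canonical states: unprotonated open O0, its site-1-bound
partner O0s1, and their blocked counterparts B0, B0s1. Constraint 2 is a
consequence of open-state access in the wild type; a basally open channel
is blockable at neutral pH, which is exactly the preincubation phenotype of
A321C, so the extended set relaxes it deliberately.

Transition edges connect states differing by one elementary event: one
site's binding/unbinding, or one pore transition. The site-2 event is
pore-coupled (open-channel block): blocker binding closes the pore and
unbinding reopens it as a single event, giving the O1↔C4 and O2↔C5 edges
and excluding closed-state blocker escape (no C1↔C4 edge). The graph is
connected, all 10 edges are reversible; the slow, only-partially-reversed
washout of inhibition is a rate property (small site-2 off-rate), not a
topology property. A possible concerted proton-binding-plus-opening edge
(C2→O2) is realized as the two-step path C2↔C3↔O2; nothing in the
macroscopic data distinguishes the two, and the two-step form keeps every
edge elementary.

## Equilibrium scheme

Protonation is a single effective Hill-weighted event,
h = 10^(n_H(pK_H − pH)), rather than explicit multi-site binding: only
macroscopic slope factors (~2) are available to constrain it, not per-site
pKa values. Site-1 binding multiplies proton affinity (γ) and opening
efficacy (φ); binding and gating contributions are experimentally
indistinguishable here, and this composite is the minimal scheme producing
an alkaline pH50 shift with an exactly invariant slope: at any fixed
modulator concentration the open probability is an exact logistic in h, so
the fitted slope equals n_H identically and only the midpoint moves.

Block weights scale as w(open)·[drug]/K2 (from O1) and ·[drug]/K2' (from
O2), making high-concentration block absorbing (response → 0 as
concentration → ∞). The site-1-bound basal-open state carries weight
L0·c1 with no φ factor: efficacy acts only through the proton-gating
pathway, so the modulator cannot activate a basally open channel at
neutral pH — it only blocks it — matching the monotone inhibition of
basal-open variants at pH 7.3 versus their bell-shaped modulation at
mildly acidic pH.

### Wild-type preset and calibration

The wild-type preset was produced by `pacgate.calibrate.calibrate_wt`:
bounded least squares matching the model's apparent potencies (ascending-
limb EC50, descending-limb IC50 of normalized dose–response curves, read
off a dense log grid by bisection) to the published values at pH
5.34–5.8 (activation) and pH 4.6–5.8 (inhibition), with a penalty driving
the ascending limb to extinction at pH ≤ 5.0, then rounded:

| parameter | value | units | meaning |
|---|---|---|---|
| pK_H | 5.08 | pH | effective proton half-occupancy |
| n_H | 2.5 | – | effective protonation Hill exponent |
| L | 3.8 | – | open/closed weight, protonated drug-free channel |
| K1 | 24 | µM | site-1 dissociation (closed, unprotonated reference) |
| γ | 3.3 | – | proton–site-1 coupling |
| φ | 5.5 | – | site-1 opening efficacy |
| K2 | 6.3 | µM | site-2 dissociation from O1 |
| K2' | 6.6 | µM | site-2 dissociation from O2 |

This preset gives bell-shaped dose–response at pH 5.34–5.8 (EC50
0.47/1.16/2.23 µM, falling with acidity as the γ-coupling predicts),
monotone inhibition at pH ≤ 5.0, an IC50/EC50 ratio ≈ 21 at pH 5.6, an
untreated pH50 of 5.35, and an alkaline shift to 5.66/5.79 under 5/10 µM
modulator with unchanged slope. K2' ≈ K2 emerged from the calibration; the
attenuated inhibition at weak acidity is carried mostly by the γφ-amplified
activation rather than by a weaker blocked-state affinity.

Variant presets: A321C (pK_H 5.9, L0 0.3 — basally open and
alkaline-shifted so that modulation is purely inhibitory at pH 7.3 and
bell-shaped at pH 6.2), F196A (γ = φ = 1, L0 0.447; activation site
destroyed, ~39% basal), F196A/R237A (γ = φ = 1, L0 0.135, pK_H 5.219 solved
from pH50 = pK_H + log10((1+L)/(1+L0))/n_H so the model curve has pH50 5.47
and basal opening 0.15), D289R (wild-type gating, L0 0.3). Numeric values
for these variants other than the double-mutant pH50/BOP are not published;
they are qualitative, synthetic choices and are marked as such in the
preset registry.

## Kinetics

Rates are constructed per edge class so that k_f/k_r equals the equilibrium
weight ratio on every edge, which enforces detailed balance on every cycle
and makes the stationary distribution of the generator identical to the
equilibrium distribution at any (pH, concentration) — verified numerically
to < 1e−12. Proton (500 s⁻¹ class) and pore (50 s⁻¹ class) transitions are
fast, so pH steps equilibrate essentially instantly on the seconds scale and
modulator binding is rate-limiting, as observed; no proton kinetics are
resolved experimentally, only the ≥100 s⁻¹ ordering matters and results are
insensitive to the exact fast scales.

The two modulator scales are calibrated to the published relaxation
constants: site-1 association to the wash-in time constant at pH 5.8 with
5 µM compound (4.5 s), site-2 association (hence the slow off-rate
kon₂·K2) to the compound-free recovery after inhibition at pH 4.6
(82.7 s). Because the published constants are themselves monoexponential
fits to current time courses, the calibration matches that same
observable — the fitted single-exponential τ of the simulated open
occupancy — seeding with closed-form pseudo-first-order estimates and
refining by a few secant steps (the relaxations are mildly
multi-exponential, so an eigenvalue-matched calibration would land ~8%
away from the fitted observable). Calibration is deterministic and takes
~1.5 s.

Integration uses the exact matrix exponential of the per-segment generator
at each sampling step (the generator is piecewise constant); an LSODA path
(rtol 1e−8, occupancies clipped at −1e−10 before renormalization, failure
beyond −1e−8 aborts with a diagnostic) is kept as a cross-check and agrees
to < 1e−6. Solution exchange is idealized as instantaneous at segment
boundaries; perfusion lag and chamber mixing (and the ~20% residual current
they produce in preincubation time courses) are deliberately not modelled.
The default initial condition equilibrates to the first segment and can be
overridden for carry-over protocols.

## Voltage gating and currents

Ion-flux gating is phenomenological: a Boltzmann gate in voltage whose axis
is sign-flipped by the conducting branch's orientation stands in for the
permeant ion's interaction with the selectivity filter; no mechanistic
equation is available for that interaction. The gate's half-activation
voltage interpolates linearly with the protonation fraction from
+198.7 mV (resting, with slope 31.7 mV — the measured wild-type values at
neutral pH) to 0 mV when fully protonated; the linear interpolation and the
0 mV endpoint are this package's choices, constrained only by the reported
threshold shift from ≈+100 mV to ≈0 mV under acidification. The chemical
and voltage gates combine as parallel pathways,
P = 1 − (1 − P_chem)(1 − g_V): a pure product would extinguish the large
depolarization-evoked currents at neutral pH where P_chem ≈ 0, so the
parallel form is the one consistent with both gates acting separately and
synergistically (synergy enters through V½(protonation)). An alkaline
attenuation factor (0.11 per pH unit above 7.3, chosen to reproduce the
shallow −0.22-per-pH-unit alkaline limb against the steep acidic limb)
scales the gate down under alkalization.

Open-pore current follows the GHK constant-field equation per species
(outward positive; analytic first-order limit below |zFV/RT| < 1e−6),
with bath/pipette chloride 154/141 mM and sodium 145/0 mM from the
recording solutions; temperature fixed at 296 K. Ramp simulation is
quasi-steady-state — the slow, time-dependent activation of the cationic
filter mutants during ramps is out of scope. Conductance extraction uses
G = I/(V − V_rev), excluding voltages within 5 mV of reversal except that
G(0 mV) is the average of the −20/+20 mV values, with G_max taken from the
Boltzmann fit because the conductance need not saturate in range.

## Fitting

All nonlinear fits are bounded least squares with three data-driven starts
(half-crossing midpoint heuristics; Hill exponents 0.5/1/2), tight
tolerances (1e−14), asymptotic standard errors from the Jacobian, and
explicit degeneracy flags (constant input, insignificant amplitude,
midpoint outside the sampled range → `extrapolated`). Potencies and time
constants are fitted on a log scale internally; their standard errors are
delta-method transformed. Hill fits default to free top and bottom, with a
fixed-bottom mode available. Bell-shaped data are fitted piecewise
(ascending Hill + descending Hill, split at the empirical maximum, as in
`apparent_markers`) rather than with a product model, because separate
EC50/IC50 values are what the experiments report. `fit_hill` offers a
relative-error mode (two-pass inverse-response weighting) that is the
appropriate estimator when noise is multiplicative, and is what the
pooled-recovery analyses use.

The pH–current equation is implemented as
Y = Y0 + (Y_steady − Y0)/(1 + 10^((pH − pH50)·nH)) with nH > 0, i.e. the
conventional form with the sign of nH chosen so that Y0 is the basal
opening proportion at neutral pH and Y_steady the acidic plateau, matching
how the fitted Y0 ("BOP") is defined and reported.

## Synthetic data

Generators emulate whole-cell patch-clamp summaries: a smooth generating
model per condition, lognormal per-cell amplitude variability (σ = 0.2
default), multiplicative per-point noise (CV 10% default) and an additive
baseline term (2% of max default). The defaults are not published values;
they were chosen once so that standard errors of the published size are
attainable at the printed cell counts. Replicate counts in the shipped
fixtures equal the printed n per condition, treating n as independent
cells (legends mix cells and repeated measures; the distinction is
immaterial for recovery tests). Datasets are long-format CSV with a
'#'-prefixed metadata header (generator parameters and seed), byte-
reproducible under a fixed seed via numpy's PCG64 generator. Only
summary-level points are generated — no kHz waveforms, no capacitance or
series-resistance artifacts, no leak. Passing recovery tests therefore
demonstrates estimator correctness and statistical calibration under the
assumed noise structure, not robustness to real recording artifacts.

## Problem sizes

The recovery analyses use the printed replicate counts (6–16 cells,
8–17 grid points), dose–response marker extraction a 2001-point dense log
grid, kinetics 30 s wash-in / 300 s washout segments at 0.1–0.5 s sampling,
and equilibrium property checks 120–200-point grids. The full test suite
runs in a few seconds; the acceptance script in ~3 s.

## Known limitations

* Site-1 occupancy saturates well above the apparent EC50 (the response is
  nonlinearly amplified), so activating pretreatment strongly attenuates
  but does not fully abolish the transient activation seen when stepping
  to a high blocker concentration; experimentally the transient disappears
  after 1 µM pretreatment.
* Whether site-1 affinity is itself pH-dependent is unresolved; here the
  falling apparent EC50 with acidity emerges entirely from the γ-coupling.
* The partial irreversibility of inhibition is modelled as a slow off-rate;
  a distinct absorbed state would be indistinguishable on these protocols.
* The voltage-gate/proton-gate coupling (linear V½ interpolation) and the
  basal-variant presets other than the double mutant are unconstrained by
  published numbers.
* No single-channel (Gillespie) trajectories, no noise analysis, no
  Nernst–Planck electrostatics, no global multi-pH simultaneous fitting,
  and no temperature dependence (fixed 296 K).
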
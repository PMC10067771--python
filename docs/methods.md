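# Methods

## Model overview

The cell is a branched compartmental model of a hippocampal CA1 pyramidal
neuron. A morphology (a real SWC reconstruction, or the package's
synthetic soma + tapered apical trunk + obliques + basal + axon cell) is
discretized with the d-lambda rule: each section receives the smallest odd
number of equal compartments keeping every compartment below
0.1·λ₁₀₀, with λ₁₀₀ the 100 Hz AC length constant from the local
diameter, Rm, Ra and Cm. Specific membrane resistivity and axial
resistivity fall sigmoidally with path distance x along the apical axis
(Rm 125→85 kΩ·cm², Ra 120→70 Ω·cm, half-distance 300 μm, slope 50 μm);
soma, basal dendrites and axon carry somatic values. Cm = 1 μF/cm²
everywhere. Because the printed parameter table lists two values for the
Ra slope (50 and 14 μm), the default pairs it with the Rm slope (50 μm)
and exposes it in `PassiveParams`.

Five voltage-gated conductances are expressed: fast Na and
delayed-rectifier K (uniform, 16 and 10 mS/cm²; 15.4 and 2 mS/cm² in the
theta/place-field configuration), A-type K rising linearly with x
(3.1 mS/cm² at the soma, 8-fold slope per 100 μm, proximal and distal
kinetic variants switching at 100 μm), and sigmoidally rising HCN
(25 μS/cm², 12-fold, d = 320 μm) and T-type Ca (80 μS/cm², 30-fold,
d = 350 μm). The HCN half-activation voltage shifts from −82 mV (x ≤ 100)
linearly to −90 mV (x ≥ 300). The axon is passive except the initial
segment (30 × 1 μm by default), which carries five-fold somatic Na (plus
somatic KDR so that axonal spikes repolarize). Dendritic Na carries an
extra slow-inactivation gate with a depolarized residual of 0.7. Rate
functions for all gates are closed forms with coefficients in
`CHANNEL_KINETICS`, following the canonical published CA1 schemes for
each channel family, with q10 factors referenced to 34 °C. CaT and the
synaptic receptors use the Goldman–Hodgkin–Katz constant-field form
rather than ohmic driving forces.

## Synapses and calcium

A synapse co-localizes AMPA and NMDA receptors on one compartment (at
most one synapse per compartment). Gating is the normalized double
exponential s(t) = a(e^{−t/τd} − e^{−t/τr}) (AMPA 2/10 ms, NMDA 5/50 ms;
a makes a single event peak at exactly 1; events superpose linearly).
Receptor currents are GHK fluxes with P_Ca : P_Na : P_K = 10.6 : 1 : 1
for NMDA (gated by the magnesium unblock 1/(1 + ([Mg]/3.57)e^{−0.062v}))
and 1 : 1 Na : K for AMPA, scaled by the weight w. The NMDA : AMPA
permeability ratio is 1.5 throughout. Permeabilities are densities over
the host compartment's membrane, which makes the calcium shell equation
dimensionally natural.

Calcium entering through NMDA receptors and CaT channels feeds a 0.1 μm
submembrane shell that relaxes to 100 nM with τ = 30 ms:

    d[Ca]/dt = −φ · 10000 · I_Ca / (3.6 · dpt · F) + ([Ca]∞ − [Ca]) / τ.

φ is the *free-calcium fraction*: the portion of entering calcium that
escapes buffering and is visible to the plasticity machinery. With φ = 1
(the default for the shell primitive itself) physiological GHK current
densities (μA/cm²) drive the shell tens of μM high — two orders above the
learning rule's thresholds — so every synapse saturates to LTP within
seconds and no homeostatic signal can modulate the outcome. The model
presets therefore set φ = 0.008, chosen once so that 4–12 Hz induction
lands per-synapse free calcium across the LTD/LTP window: the first
induction epoch then produces the expected texture (mean final weight
≈ 0.5, most synapses potentiated, a few depressed, none saturated
immediately).

## Plasticity and coupling

Weights follow the calcium-control rule dw/dt = (Ω − w)/τ with
τ([Ca]) = P1 + P2/(P3 + [Ca]^P4) (P1 = 1 s, P2 = 0.1 s, P3 = P2·10⁻⁴,
P4 = 3; ≈ 3 h at rest, ~1 s at saturating calcium) and Ω the double
sigmoid with α1 = 0.35, α2 = 0.55, β1 = β2 = 80 (calcium in μM — the
scale on which those thresholds are defined). w starts at 0.25. Weight
updates integrate exactly (exponential pursuit) every 10 solver steps
(0.25 ms), far below the rule's fastest time constant.

Every 100 ms the somatic maximal h conductance updates as
g′ = g(1 + ΔW·slope), ΔW the fractional change of the summed plastic
weights over the interval (the percent convention is a config flag; the
dimensionless-slope fractional form is the default because it produces
interior RMSE minima at slopes of the same order as the published optima
— ours lands at 4–5 depending on the measurement grid, versus 3.5 at full
scale). The whole spatial gradient rescales through
the somatic value. Between protocol iterations, evolved weights are
consolidated into permeabilities (P_AMPA ← P_AMPA · w/w_init, w reset,
NMDA following through the fixed ratio), so both receptor classes carry
the positive feedback loop across iterations.

## Numerics

Backward-Euler integration at dt = 25 μs on the branched cable, solved by
Hines elimination (compartments ordered parent-before-child). Gating uses
exact exponential relaxation with steady states and step factors
interpolated from 0.05 mV tables built from the closed-form kinetics.
Ohmic channel currents are implicit through their conductances; CaT and
the divalent NMDA component are explicit at the previous voltage; the
monovalent synaptic GHK current enters implicitly through its chord
conductance about its zero crossing (v_T·ln((Na_o+K_o)/(Na_i+K_i)) ≈
−2.3 mV), which keeps multi-fold potentiated synapses unconditionally
stable. Divergence (|V| > 500 mV or NaN) aborts with the offending
compartment and time. Spikes are upward crossings of −20 mV with a 2 ms
refractory period. Runs are bit-reproducible given a model, stimulus set
and configuration.

Every protocol window is preceded by a 200 ms settle at the holding
potential. The stated holding (−65 mV for Poisson protocols, −66 mV for
the place field) is enforced the way an experimenter would: during
settling the soma is voltage-clamped at the holding potential, and the
steady clamp current then continues as a constant somatic bias for the
protocol window. This anchoring matters scientifically: the h reversal
(−30 mV) lies above rest, so without it an h-conductance increase
depolarizes the resting potential and *raises* synaptically driven
firing, inverting the homeostatic sign; with the operating point anchored,
h increases act through shunt and sag and right-shift the input/output
profile, reproducing the expected direction.

## Protocols and presets

The reduced preset — the configuration exercised by the tests and the
acceptance script — keeps every biophysical constant (dt, kinetics,
gradients, plasticity parameters, NAR, theta parameters) and shrinks only
the problem size: synthetic morphology (~60 compartments), 28 synapses
(one per apical compartment in 12.5–286.7 μm), stimulus grid 2–20 Hz in
steps of 2 with 3 trials, slope grid 0–8 in steps of 1. Because the
synapse count is ~10× below full scale, the dendritic-democracy target is
2.0 mV per unitary EPSP (0.2 mV at full scale) so the summed drive spans
the same firing range; induction runs 5 s (weights move on the rule's
1–2 s time constants at LTP-range calcium; the place-field figures show
full LTP developing within a 5 s stimulation window). The place-field
preset uses 15 base + 6 place synapses (≈1/10 of 151/61, same 2.5 : 1
ratio), 10 s runs with the place window at 3–8 s, theta period 125 ms,
σ = T/8, one event per cycle per synapse on average, a somatic ramp
calibrated to ≈4 mV peak depolarization (rise over 80 % of the window),
and 300 ms-SD Gaussian rate smoothing.

Protocol randomness derives from named seed sequences of one master seed:
per-synapse induction frequencies (uniform 4–12 Hz), induction Poisson
trains (drawn once, reused across iterations and across
coupled/uncoupled arms), measurement trains (depending only on seed and
grid, so profiles of a perturbed model are trial-paired with baseline,
and RMSE measures profile shift rather than trial noise).

## What the reduced model shows — and what it cannot

Reproduced at desk scale: the baseline type-I input/output profile
(silent below ~10 Hz stimulus); the first-epoch left shift under pure
synaptic plasticity followed, over repeated iterations, by
depolarization-block collapse at high stimulus frequencies; the
inverted-bell RMSE-versus-slope curve with an interior optimum; the
decrease of that optimal slope with rising baseline synaptic scale or
baseline h conductance; the decline of mutual information across
iterations driven by rising noise entropy with approximately conserved
response entropy; and the theta-driven place field with sparse out-field
firing and in-field collapse under uncoupled plasticity.

Known limitations, consequences of desk scale rather than of the
mechanism: the reduced cell is electrotonically compact (DC length
constants exceed every neurite), so the within-induction negative
feedback of the h conductance onto synaptic calcium is weak — coupled
induction restores the input/output profile through the measured
transfer function, not by measurably suppressing weight growth. Two
downstream effects follow. First, at late iterations the uncoupled
trajectory can transiently re-enter partial firing (28 giant synapses
leave inter-event gaps for sodium recovery; 303 small ones would not), so
the coupled arm, while far better early (≈3 vs 20 Hz RMSE at the first
iteration), does not necessarily beat it at literally every iteration.
Second, an established in-field depolarization block cannot be reversed
by raising a conductance whose reversal (−30 mV) lies above the blocked
envelope, so the place-field rescue by coupling — which at full scale
operates by suppressing weight growth — may not reproduce; the package
runs and reports that comparison honestly rather than tuning toward it.
These are documented scale artifacts, not adjustable outcomes.

Real-data features the synthetic substrate does not emulate: detailed
branching statistics of reconstructed neurons, spines, inhomogeneous
synapse densities, inhibition, and regenerative dendritic events
(explicitly out of scope).
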
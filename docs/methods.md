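# Methods

## Model

The bacterial flagellar motor is reduced to two rigid rotating rings with
one angular coordinate each: the MotA pentamer ring of a single stator
unit (θ_S) and the FliG ring of the rotor (θ_R). Both are overdamped —
inertia is irrelevant at nanometre scales — and evolve under Langevin
dynamics with independent thermal noises satisfying the
fluctuation–dissipation relation ⟨η(t)η(t′)⟩ = 2k_BTξδ(t−t′). The rotor is
passive: the only torque on it is −∂V_R/∂θ_R from the MotA–FliG contact.
The stator is active: it feels the reaction −∂V_R/∂θ_S and the
proton-powered MotA–MotB torque −∂V_S/∂θ_S.

Ring geometry is fixed by stoichiometry and never varied: stator period
Δθ_S = 2π/5 (five MotA subunits), rotor period Δθ_R = 2π/26 (26 FliG
subunits assumed), gear ratio k = Δθ_R/Δθ_S = 5/26. Because V_R must be
periodic in both angles it depends only on the scaled relative angle
φ = θ_R − kθ_S; we use a symmetric triangular wave of amplitude U_R —
the least-committal piecewise-linear periodic shape (asymmetric shapes,
relevant to directional switching, are out of scope; the shape is easy to
swap). An exact consequence of this construction is the gear reaction
identity τ_S,coupling = −k·τ_R, which the tests check to machine
precision.

### The stator ratchet

Each MotB monomer contributes one *anchored* well
`single_well(θ_S − n_i·Δθ_S − δ_i)` with δ_1 = 0, δ_2 = Δθ_S/2 (the 5:2
stoichiometry puts the two proton channels in antiphase). The well shape
is piecewise linear: a steep back-flow barrier of height `U_barrier` over
`barrier_width` behind the plateau, a flat plateau of height U_S over
`plateau_fraction` of the period, a linear power-stroke ramp descending to
the minimum, and a confining wall (same slope as the barrier) rising past
the minimum.

The forward wall deserves a note, because a natural-looking alternative —
continuing the potential flat beyond the minimum until the next chemical
step — breaks the motor. With a half-period plateau the partner well's
ramp begins exactly at this well's minimum, so a flat continuation lets
the partner drag the ring through the stepping window with order-one miss
probability; one miss leaves that MotB's landscape permanently behind
(its anchor can never catch up), collapsing the cycle to one proton per
period and destroying rotor traction. The wall makes the ring *wait* at
the minimum until its chemical step fires, which is also what the
mechanochemistry demands: stepping is a transition from low to high
potential energy, strict two-protons-per-stroke stoichiometry, and a
stator duty cycle that includes dwells at the minima. After re-anchoring,
the same wall is the back-flow barrier of the fresh plateau.

At kinks of the piecewise-linear potentials the gradient is taken from
the left (the side approached under forward rotation); the single
exception is an exact minimum of V_R, where symmetry dictates zero. These
conventions act on measure-zero sets and only matter for reproducibility
— with one visible consequence: the standard initial condition sits
exactly on the plateau-start kink, so the very first integration step
receives one barrier-slope kick (the deterministic-limit tests measure
from the first stored sample onward).

### Chemistry

The proton discharge–recharge chain C⁺→C⁻→P⁻→P⁺ of each MotB is collapsed
into a single effective rate k_m(θ_S): a top-hat equal to `k0` within
`window_width` of the well minimum and zero elsewhere. A firing advances
the anchor by one period and counts one proton; there are no backward
steps. Steps are attempted with first-order probability k_m·dt, and
parameter validation enforces dt·k0 ≤ 0.1 so the linearization is valid.
Coarse conformational labels (P⁺ early plateau, I⁺ intermediate, C⁺
stepping window) annotate trajectories and let tests verify the cycle
order P⁺→I⁺→C⁺→(step)→P⁺.

## Parameters

| parameter | default | meaning |
|---|---|---|
| U_S | 15 k_BT | plateau-to-minimum drop of each MotA–MotB well |
| U_R | 15 k_BT | amplitude of the MotA–FliG coupling |
| U_barrier | 30 k_BT | back-flow barrier (and wall) height |
| barrier_width | 0.1·Δθ_S | barrier rise width |
| plateau_fraction | 1/2 | flat fraction of the stator period |
| k0 | 200 τ⁻¹ | stepping rate inside the window |
| window_width | 0.05·Δθ_S | stepping-window half-width |
| ξ_S | 0.1 | stator drag (held small and fixed) |
| ξ_R | 0.1 | rotor drag — *the* load, swept in experiments |
| k_BT | 1 | energy unit |
| dt | 5·10⁻⁶ τ | Euler–Maruyama step |

The absolute energy and rate values are modelling choices (no measured
values are available for them); they are set once to produce the two
qualitative regimes cleanly and are not tuned per analysis. The deciding
constraint is thermal register-hopping: the rotor can thermally hop one
coupling period (one FliG subunit) at a rate ∝ exp(−U_R/k_BT). At
U_R ≈ 5 k_BT such hops occur on simulation timescales even at low load,
which would blur the no-slip regime; at 15 k_BT they are negligible while
genuine load-driven slippage still sets in around ξ_R ≈ 5. With U_R = U_S
and a half-period plateau, the maximal coupling back-torque on the stator
(k·2U_R/Δθ_R) exactly equals the ramp drive (2U_S/Δθ_S) — the
"comparable" regime sits on this natural balance point. `U_barrier` is
kept at twice the scale of the driving potentials so that neither thermal
fluctuations nor coupling back-push (which reaches k·2U_R/Δθ_R) can cross
the barrier; the `tight_coupling` preset (U_S = 5, U_R = 50, U_barrier =
20) keeps the same margin against its much stronger coupling.

## Numerics

Integration is Euler–Maruyama; after each mechanical update the chemical
step is attempted (the ordering is fixed for reproducibility; at valid dt
the ordering bias is below Monte-Carlo error). The inner loop is compiled
with numba and consumes pre-drawn noise blocks of fixed size, so a given
(parameters, seed) pair yields bit-identical trajectories regardless of
duration; a test holds the compiled loop bit-identical to a pure-Python
step built on the public potentials/chemistry API.

Parameter validation enforces a conservative drift-stability heuristic
dt ≤ 0.1·min(ξ)·Δθ_R²/(k_BT + max potential drop). The default
dt = 5·10⁻⁶ comes from the convergence requirement that halving dt move
the mean rotor speed by well under 2% (at 10⁻⁵ the bias is ≈4%,
dominated by wall-contact overshoot). Angles are stored unwrapped;
wrapping happens only inside potential evaluation.

Load sweeps reuse replicate seeds across loads (seed + replicate index) —
common random numbers, which sharpens monotonicity comparisons; each
trajectory records its own seed.

## Observables

Speeds are end-to-end slopes after discarding a 10% burn-in, with block
SEMs (10 contiguous blocks). Torque is ξ_R·⟨dθ_R/dt⟩ (the bead-drag
convention); the time-average of −∂V_R/∂θ_R is computed as an independent
cross-check and agrees within Monte-Carlo error. The torque–speed-curve
concavity diagnostic compares interior points with the chord joining the
lowest- and highest-speed points, with a 2-standard-error slack: near the
free-running plateau several loads share the same speed within error, so
the strict comparison would flip with the seed. Speeds are reported raw;
normalizing by the zero-load speed is left to the caller since the
natural reference is itself a measured quantity.

φ analyses use unwrapped φ referenced to its initial value, so slippage
(the stator leaving the rotor behind) shows as mass drifting below zero.
Motion classification coarse-grains the trajectory into windows of one
mean power-stroke duration (by default inferred from the trajectory's own
stator speed) and labels each window type I (rotor follows at the gear
ratio within a 25% relative tolerance), type III (stator advances ≥
Δθ_S/4 while the rotor moves ≤ 0.05 rad), or type II (everything else).
The thresholds are exposed parameters; the classification is inherently
coarse and is used for relative, load-to-load comparisons.

Proton accounting divides total translocations by net stator rotation in
periods (→ 2) and by net rotor rotation in revolutions (→ 52 under tight
coupling). Both carry an O(1/N) bias from the partial strokes at the ends
of a finite run, so "exactly 2" is approached, not hit, at any finite
duration; tests assert 1%.

## Validation oracles

Independent references, coded against the defining formulas rather than
the production modules: (i) a Boltzmann quadrature on the accessible
(θ_S, φ) well with chemistry frozen — the confining walls make this well
bounded — marginalized onto the wrapped φ, against which the simulator's
equilibrium distribution matches with Kolmogorov–Smirnov distance < 0.02;
(ii) a tiny-step (dt/100) noiseless Euler slide down V_S via
finite-differenced forces, matching the production integrator to < 10⁻⁴
rad mid-slide; (iii) closed forms for free diffusion (MSD = 2k_BT·t/ξ),
the binomial statistics of the stepping rule, and the Gaussian marginal of
a substituted harmonic well.

## What the simulations do and do not show

The generator's default conditions reproduce the structural regime
facts — gear-ratio coupling, 2 protons per stroke, downward-concave
torque–speed shape, no-slip tight coupling, load-increasing slippage for
comparable potentials — not any particular measured curve: absolute
speeds and torques are in model units, the potential amplitudes and
stepping rate are not experimentally constrained, and a single stator
unit is simulated (real motors recruit up to ~11, and stator assembly is
itself load-dependent). CW/CCW switching, PMF dependence of k_m, and
C-ring conformational mechanics are outside the model. Test problem
sizes (typically 1–6·10⁶ steps per run, ≈50–600 power strokes) are chosen
so every statistical assertion sits several standard errors from its
threshold.

## Known limitations

* The first-order stepping rule slightly shortens dwell times relative to
  exponential waiting (bias O(k0·dt) ≤ 1e-3 at defaults).
* Near-stall behaviour depends on the triangular V_R's constant force
  magnitude; smooth potentials would round the stall plateau.
* The classification thresholds are heuristic; absolute type fractions
  should not be over-interpreted.
* Euler–Maruyama handles the potential kinks by one-sided gradients;
  observables converge at first order in dt, hence the conservative
  default step.
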
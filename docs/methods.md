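# Methods

This note records the models implemented in `dendrocable`, their
assumptions, the numerical choices behind them, and what the synthetic
test conditions do and do not establish.

## Morphology representation and discretization

A reconstruction is a rooted tree of 3D points with radii (SWC
semantics: consecutive points bound conical frusta). Sections are the
maximal unbranched stretches; boundaries fall at the root, at
bifurcation points, and at domain changes, and the branch point belongs
to its *parent* section, so sections partition the points. For
geometry, each non-root section is anchored at its first point's parent
so the connection gap counts toward section length; summed section
lengths therefore equal summed inter-point distances exactly. When the
anchor lies in a different domain (a dendrite leaving the soma), the
anchor's radius is replaced by the section's own first radius so
dendrites do not inherit the somatic calibre; a repeated junction point
(same coordinate, own radius) overrides the anchor radius, which is the
conventional way to author uniform daughter branches in SWC.

Two soma dialects are normalized: a single-point soma becomes a sphere
(L = diam, area 4πr², one segment, no internal axial resistance); a
multi-point soma is an ordinary cylindrical-frustum section.

Segments tile each section in `nseg` equal arcs with centers at
`(2i−1)/(2·nseg)`; odd `nseg` guarantees a midpoint recording site, and
an even request is an error rather than silently rounded. The d_lambda
rule uses `λ_f = 10⁵·√(d/(4π·f·Ra·cm))` µm (d in µm, Ra in Ω·cm, cm in
µF/cm², f = 100 Hz by default) and
`nseg = floor((L/(d_lambda·λ_f) + 0.9)/2)·2 + 1`, with the
length-weighted mean diameter standing in for `d` on tapered sections.
Segment diameters interpolate the radius profile linearly in arclength;
segment lateral areas are sums of frustum areas cut at both the
reconstruction knots and the segment boundaries, so per-section areas
are conserved to rounding.

## Channel kinetics

The NMODL reader supports HH-style density mechanisms: assignment
statements, `PROCEDURE`/`FUNCTION` bodies without control flow, one
`DERIVATIVE` block, `USEION`/`NONSPECIFIC_CURRENT`. `VERBATIM`,
`KINETIC` (Markov) schemes, conditionals and pointers raise explicit
unsupported-construct errors — a silent misparse is treated as worse
than a refusal.

Rather than binding steady states and time constants purely by symbol
names, the extractor resolves every assigned symbol into sympy
expressions and reads the kinetics off the state ODE: with
`dx/dt = a(V) + b(V)·x`, `τ = −1/b` and `x∞ = −a/b`. This is exact for
both `(x∞ − x)/τ` and `α(1−x) − βx` authoring styles, including helper
symbols defined in procedures; a right-hand side nonlinear in the state
is rejected with the candidate symbols listed. The open-probability
structure (state powers) comes from the polynomial degree of the
BREAKPOINT current in each state symbol, and `gbar`/reversal are read
off the ohmic factorization `I = gbar·p·(V − E)`.

Rate expressions of the form `A·(v−θ)/(1−e^{−(v−θ)/k})` have removable
singularities. Evaluation guards them two ways: non-finite results, and
points where a denominator falls below 10⁻⁶ of its additive-term scale
(where naive evaluation can return a wrong *finite* value through
catastrophic cancellation). Both fall back to a two-sided numeric
limit; symbolic limits proved unreliable on float-coefficient
exponential rationals.

Temperature enters only through symbols the mechanism itself defines
(`celsius`, typically via a q10 factor); mechanisms without one are
temperature-inert. Curves are evaluated at the mechanism's definition
temperature unless overridden.

### Standardization

Each gating variable is refit to the five-parameter transition-state
form (v_half mV, σ mV, K ms⁻¹, δ ∈ (0,1), τ₀ ms ≥ 0). Note the rate
pair is `α = K·e^{δ(V−v_half)/σ}` and `β = K·e^{−(1−δ)(V−v_half)/σ}` —
the unique sign convention under which α/(α+β) collapses to the
steady-state sigmoid; with both rates increasing in V the time constant
could not be bell-shaped and the system would be internally
inconsistent.

The fit is two-stage least squares on a −100..100 mV grid (1 mV step):
stage 1 fits both curves jointly with residuals normalized by each
curve's range; stage 2 refits (v_half, σ) against the steady state
alone, freezing the τ-shape parameters (K, δ, τ₀). The freeze set is an
interpretation: refitting only the sigmoid parameters preserves voltage
dynamics while letting τ accuracy degrade, which is the stated intent
of the second stage. K is fit in log space; σ's sign is fixed by the
curve's monotonic direction; tolerances 10⁻¹²; at most 10⁴ evaluations.
On noiseless curves generated from the model itself all five parameters
are recovered to ≲10⁻⁶ relative; on genuinely non-sigmoid curves (the
classic n∞, for example) the steady-state RMSE floor is the best
achievable logistic approximation (≈0.04 for the toy delayed
rectifier), and a non-monotone steady state produces a warning rather
than an error. Rendered standardized MOD files use a fixed block order,
one DERIVATIVE block, and parameters named
`v_half_<state>`, `sigma_<state>`, `k_<state>`, `delta_<state>`,
`tau_0_<state>`; re-parsing them reproduces the closed forms to 10⁻⁹.

## Distributions

Segment groups select by domain membership plus one optional criterion:
diameter (µm), absolute path distance to the root (µm), or relative
distance within the domain. Relative distance normalizes per domain
*and per root stem* — each stem's subtree is normalized by its own
maximal path length — which matches the intuition of "relative distance
within a domain" when a domain has several stems; a global-per-domain
normalization was the alternative reading. Groups are ordered layers:
the last matching group supplies the value, evaluated at the segment
center's path distance. Mechanism parameters on segments no group
covers default to zero conductance (mechanism effectively absent);
passives fall back to config-level globals, and a missing passive is a
validation error because it would silently corrupt the circuit. The
per-segment table records which group supplied every value.

## Cable simulation

Each segment is one compartment: capacitance `cm·area`, ionic currents
`gbar·area·p·(V−E)`, axial conductances from the exact frustum integral
`∫dl/(πr²)` between adjacent segment centers (half-resistances meet at
section boundaries; a spherical soma contributes none). Internal units
are mV, ms, nA, µS, nF.

Time stepping is a theta-scheme on the linearized current balance:
gating states first advance by the exact exponential solution of their
ODE at the pre-step voltage, then the voltage system — symmetric,
tree-structured — is solved exactly by one child-to-parent elimination
sweep and one parent-to-child substitution sweep. Backward Euler
(θ = 1) is the default for robustness; Crank–Nicolson (θ = 0.5) is
second-order and used where solver accuracy itself is being measured.
External step currents enter as their exact average over each time
step, so a step edge injects the correct charge regardless of its phase
relative to the grid; without this the onset error is first-order for
every θ. Measured convergence on the passive RC benchmark: error
halves per dt-halving at θ = 1 and quarters at θ = 0.5, with a maximum
relative error of 0.05% at dt = 0.025 ms even for backward Euler.
Gating curves are tabulated once per mechanism on a 0.05 mV grid over
−120..100 mV and interpolated linearly during integration; voltages
outside clamp to the table edges.

Synapses are dual-exponential conductances normalized so the peak
equals gmax, implemented by the standard rise/decay impulse-pair state
update (exact between events). Defaults: AMPA (e = 0 mV, τ 0.1/2.5 ms),
NMDA (0 mV, 2/30 ms), GABA_A (−70 mV, 0.5/8 ms), gmax 0.5 nS; the
compound AMPA+NMDA synapse is two components sharing spike times with a
configurable NMDA:AMPA conductance ratio. The NMDA voltage dependence
is the Jahr–Stevens magnesium block `1/(1 + η[Mg]e^{−γV})` with
[Mg] = 1 mM, η = 0.28 mM⁻¹, γ = 0.062 mV⁻¹ (half-unblock near
−20.5 mV); all parameters overridable. The NMDA factor is evaluated at
the pre-step voltage, consistent with the gating freeze.

Presynaptic trains follow the NetStim-compatible noise convention: each
interval is `(1−noise)` of the mean plus an exponential remainder of
mean `noise·mean`, so noise = 0 is exactly regular and noise = 1 is
Poisson (ISI CV = 1). Placement over a segment selection is uniform per
unit membrane length (length-weighted segment choice, uniform offset) —
the physically uniform reading of "uniform within the selected
segments". All randomness flows through seeded numpy generators.

An optional free-running equilibration window can precede t = 0 (the
default protocol leaves it off; traces never include it).

## Validation protocols

All analyses are pure functions of traces plus stimulus metadata.
Voltage "at onset" is the sample just before the step edge;
`V_offset` is the mean of the last 5% of the step window (excluding the
offset sample itself) for noise robustness. The membrane time constant
is the slowest component of a double-exponential fit starting 1 ms
after onset (log-linear tail initialization); components carrying less
than 5% of the fitted amplitude are ignored because a second component
is unidentifiable on a near-single-exponential transient. Spike
amplitude is measured from each spike's preceding local minimum (robust
for bursts); half-width interpolates the two half-amplitude crossings;
peak detection defaults to a 0 mV threshold and 1 ms minimum
separation. Rheobase is found by bisection to a stated resolution
(0.001 nA default) after verifying the bracket spans the threshold.
f-I rates divide spike counts by the stimulus duration. On the toy
excitable point neuron the f-I curve is non-decreasing up to ≈0.7 nA
and then enters depolarization block — expected HH behaviour at this
compartment size, which is why the monotonicity check is scoped below
block.

## Morphology reduction

For a selected section's inclusive subtree, sealed-end cable algebra
composes input impedances leaf-to-root (parallel admittances at branch
points, each section treated as a uniform cylinder at its
length-weighted mean diameter) and accumulates voltage attenuation
root-to-tip; the transfer path follows the maximal-attenuation
("electrotonically most distal") tip, first in tree order on ties. The
equivalent cylinder preserving (|Z00|, |Z0L|) has the closed-form DC
solution `L̂ = arccosh(Z00/Z0L)`, `R∞ = Z0L·sinh(L̂)`,
`d = ((2/π)√(RmRa)/R∞)^{2/3}`, `L = L̂·λ(d)`; at nonzero frequency the
DC solution seeds a two-equation least-squares refinement on the
magnitudes. DC is the default frequency — it keeps the acceptance
algebra analytic — with the frequency exposed as an option. Reduction
operates on passive properties; active conductances are reattached
afterwards by the mapping step.

The replacement cylinder attaches at the original parent point along
the original first-edge direction, and the reduced morphology is
resegmented by the d_lambda rule at 0.1λ. Each original segment maps to
the cylinder coordinate equal to its fraction of cumulative electrotonic
distance along its own maximal root-to-tip path; reduced segments
average their contributors' values, and empty bins interpolate linearly
from populated neighbours. Averaging does not conserve total
conductance (`Σ gbar·area`) — the deviation is a property of the
method, not an error, and callers can compute it from the map. Synapses
are deliberately not remapped: populations are expected to be placed on
the reduced morphology.

Refitting maps the averaged values against distance with candidate
models {constant, linear, cubic polynomial, step, exponential,
sigmoidal}; the step model is fit by exhaustive two-edge search over
midpoints. Selection minimizes MSE with parameter count as tie-break
among candidates within 5% of the best — so exact linear data picks
the line over the cubic.

## Synthetic study conditions

All test inputs are generated: ball-and-stick, binary-tree, Y-shaped
and single-cylinder morphologies; textbook HH-style Na (m³h, written in
rate-constant style), delayed-rectifier K (n⁴, written in inf/tau style
with q10 = 3 declared at 6.3 °C) and leak mechanisms, chosen so both
NMODL authoring styles, the temperature path and the singular rate
forms are all exercised; and analytic traces (exponentials, triangular
spikes, a sag profile) whose ground truth is known by construction.

The dendritic-nonlinearity demonstration uses a passive ball-and-stick
with a thin distal branch (300 µm × 0.8 µm, Rm = 10 kΩ·cm², rest
−70 mV) and one compound synapse at 90% of the branch with unitary AMPA
gmax 0.05 nS and NMDA:AMPA ratio 4 — values in the range used for
NMDA-spike studies in thin dendrites, where the local input impedance
lets the magnesium unblock regenerate. Under these conditions the
actual/expected EPSP ratio exceeds 1.3 near 30 synchronous unitary
inputs and returns below 1 when the NMDA conductance is zeroed.

Passing these tests shows the machinery is internally correct against
closed forms and its own contracts. The synthetic morphologies have
none of the tortuosity, taper irregularity or reconstruction noise of
real SWC archives; the toy channels have none of the kinetic complexity
of published mechanism libraries (no calcium dependence, no Markov
schemes — the latter rejected by design); and no claim is made that the
demonstration parameter values reproduce any particular experimental
measurement.

## Problem sizes

The default test and acceptance runs use single compartments to ~30
compartment cables, 20 random gating-parameter draws, 10⁴-sample
placement statistics, and 100 s equivalent spike trains — sizes at
which every closed-form comparison is already tight while the full
suite completes in about a minute.

## Known limitations

No extracellular fields, calcium dynamics, plasticity, or networks.
The NMODL subset excludes Markov schemes and ligand-gated mechanisms.
Only voltage is recordable from the trace interface. Reduction assumes
uniform passive properties per subtree and treats tapered sections as
uniform cylinders at their mean diameter for impedance purposes. The
ball-and-stick equivalent of a reduced cell preserves somatic input
resistance and transfer impedance, not every higher-frequency property.
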
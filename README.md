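# dendrocable

Morphology-aware biophysical modelling of single neurons: reconstruction
tree graphs, ion-channel kinetics standardization, distance-based
conductance distributions, a multicompartment cable simulator with
synapses, electrophysiological validation protocols, and
impedance-preserving dendrite reduction — in one coherent, scriptable
Python package for computational neuroscientists who build and refine
compartmental models.

## What it does

**Morphology.** An SWC reconstruction is represented at three linked
levels: the *point tree* (3D points with radii), the *section tree*
(unbranched stretches between bifurcations), and the *segment tree*
(each section cut into `nseg` equal arcs; segment centers at
`(2i−1)/(2·nseg)`). Each segment is one RC compartment. Segment counts
can follow the d_lambda rule: every segment at most a fraction
`d_lambda` of the AC length constant `λ_f = 10⁵·√(d/(4πf·Ra·cm))` µm at
f = 100 Hz.

**Channels.** A hand-written parser reads an HH-style subset of NMODL
(`.mod`) mechanism files and extracts, symbolically, each gating
variable's steady state `x∞(V)` and time constant `τₓ(V)` from its ODE
`dx/dt = (x∞ − x)/τₓ` — covering both the `inf`/`tau` and the
`α`/`β` rate-constant authoring styles, q10 temperature corrections,
and the removable singularities of `v/(1−e^(−v/k))` rate forms.
Channels can then be *standardized*: refit to a five-parameter
transition-state form per gating variable,

    x∞(V) = 1/(1 + exp(−(V − v_half)/σ))
    τₓ(V) = 1/(α + β) + τ₀,   α = K·e^(δ(V−v_half)/σ),  β = K·e^(−(1−δ)(V−v_half)/σ)

(so that α/(α+β) ≡ x∞), and re-exported as clean MOD files.

**Distributions.** Channel densities and passive parameters are
assigned through *segment groups* (criteria on diameter, absolute or
relative path distance) carrying analytic *distribution functions* of
distance (constant, linear, exponential, sigmoidal, polynomial, step).
Groups layer: the top-most matching group wins. Configurations
round-trip through a versioned JSON format and port across
morphologies that share domain names.

**Simulation.** The cable equation `C dV/dt = −ΣI_ion − ΣI_syn + I_ext
+ I_axial` is integrated implicitly (backward Euler, or Crank–Nicolson
via `theta=0.5`) with exact tree-ordered Gaussian elimination and
exponential gating updates — unconditionally stable for passive
systems. Synapses are peak-normalized dual-exponential conductances
(AMPA, NMDA with Jahr–Stevens magnesium block, GABA_A, compound
AMPA+NMDA), driven by regular-to-Poisson spike trains and placed
uniformly per unit length.

**Validation protocols.** Input resistance, membrane time constant
(slowest of a double-exponential fit), spike detection with amplitude
and half-width, rheobase by bisection, f-I curves, voltage attenuation
vs cable theory, dendritic nonlinearity (expected vs actual EPSP), and
sag ratio.

**Reduction.** Any section's inclusive subtree can be replaced by the
unique sealed-end cylinder that preserves the subtree's input impedance
|Z00| and the transfer impedance |Z0L| from the electrotonically most
distal tip, at a configurable frequency (DC by default). Channel
densities are remapped by electrotonic-position averaging and refit
with compact analytic distributions.

## Worked example

An excitable single-compartment model from the built-in toy channel set
(Na `m³h`, K `n⁴`, leak — generated, not downloaded):

```python
from dendrocable.fixtures import make_point_neuron, make_hh_config
from dendrocable.model import Model
from dendrocable.protocols import detect_spikes

model = Model(make_point_neuron(20.0), make_hh_config(), nseg=1)
trace = model.run_step(0.1, delay=20, duration=100, tstop=140)["v@0"]
table = detect_spikes(trace, stim_duration=100.0)
print(len(table), table.rate)
print(table.times[0], table.peaks[0], table.amplitudes[0], table.half_widths[0])
```

prints

```
7 70.0
22.48 39.4 104.4 1.48
```

— a 0.1 nA, 100 ms step drives 7 action potentials (70 Hz); the first
peaks 2.5 ms after onset at +39.4 mV with a 104.4 mV amplitude and a
1.48 ms half-width.

The same model answers from the shell:

```bash
dendrocable fixtures make ball_and_stick --out model_dir
dendrocable morph stats model_dir/morphology/ball_and_stick.swc
dendrocable chan standardize model_dir/biophys/mod/tkdr.mod --out std_kdr.mod
dendrocable validate model_dir/morphology/ball_and_stick.swc \
    model_dir/biophys/config.json --protocol rin
```

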
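"""Compartmental cable simulation.

Each segment of a discretized morphology is one RC compartment obeying
current balance: ``C dV/dt = -sum_i I_ion,i - sum_j I_syn,j + I_ext +
I_axial``.  Voltages are advanced by an implicit theta-scheme (backward
Euler by default, Crank–Nicolson with ``theta=0.5``) solved by
tree-ordered Gaussian elimination (two sweeps over the branched tree,
unconditionally stable for passive systems); gating states follow the
exact exponential solution of their linear ODE at frozen voltage.

Units: mV, ms, nA, µS, nF; densities S/cm² and µF/cm² are converted via
segment areas (µm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import SegmentTree

__all__ = [
    "CableSystem",
    "StepCurrent",
    "Synapse",
    "SpikeSource",
    "Trace",
    "MechanismInstance",
    "build_circuit",
    "advance",
    "run",
    "dual_exp_conductance",
    "nmda_gate",
    "spike_train",
    "place_synapses",
    "make_synapse",
    "SYNAPSE_DEFAULTS",
]


# ---------------------------------------------------------------------------
# Synaptic conductances and input statistics
# ---------------------------------------------------------------------------

def _dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalization so the dual-exponential peaks exactly at gmax."""
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def dual_exp_conductance(t_since_spike, gmax: float, tau_rise: float, tau_decay: float):
    """g(t) = gmax · N · (e^(−t/τ_d) − e^(−t/τ_r)), peak-normalized to gmax."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t = np.asarray(t_since_spike, dtype=float)
    norm = _dual_exp_norm(tau_rise, tau_decay)
    g = gmax * norm * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))
    g = np.where(t >= 0, g, 0.0)
    return float(g) if np.ndim(t_since_spike) == 0 else g


def nmda_gate(V, mg: float = 1.0, eta: float = 0.28, gamma: float = 0.062):
    """Voltage-dependent magnesium unblock of the NMDA receptor.

    1/(1 + η·[Mg]·e^(−γV)) with [Mg] in mM, η in 1/mM, γ in 1/mV;
    defaults give half-unblock at V = ln(η·[Mg])/γ ≈ −20.5 mV.
    """
    return 1.0 / (1.0 + eta * mg * np.exp(-gamma * np.asarray(V, float)))


@dataclass
class SpikeSource:
    """Regular-to-Poisson presynaptic spike generator.

    noise=0 gives a regular train at the given rate; noise=1 a Poisson
    process; intermediate values mix a fixed fraction (1−noise) of the
    mean interval with an exponentially distributed remainder.
    """

    rate: float          # Hz
    noise: float = 0.0   # in [0, 1]
    onset: float = 0.0   # ms
    duration: float = 0.0  # ms
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must lie in [0, 1]")


def spike_train(src: SpikeSource, rng: np.random.Generator | None = None) -> np.ndarray:
    """Spike times (ms) in [onset, onset+duration)."""
    if src.rate == 0 or src.duration <= 0:
        return np.array([])
    if rng is None:
        rng = np.random.default_rng(src.seed)
    mean = 1000.0 / src.rate  # ms
    end = src.onset + src.duration
    times = []
    t = src.onset
    while t < end:
        times.append(t)
        if src.noise == 0:
            isi = mean
        else:
            isi = (1.0 - src.noise) * mean + rng.exponential(src.noise * mean)
        t += isi
    return np.array(times)


def place_synapses(n: int, segments, rng: np.random.Generator | int | None = None):
    """Sample n synapse locations uniformly per unit length over segments.

    Returns a list of (segment, x) with x the relative offset within the
    segment; segments are chosen with probability proportional to length.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    segments = list(segments)
    if n == 0:
        return []
    if not segments:
        raise ValueError("cannot place synapses on an empty segment set")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lengths = np.array([s.length for s in segments], dtype=float)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(segments), size=n, p=probs)
    offsets = rng.random(n)
    return [(segments[i], float(x)) for i, x in zip(picks, offsets)]


SYNAPSE_DEFAULTS = {
    # type: (e mV, tau_rise ms, tau_decay ms, voltage_gated)
    "AMPA": (0.0, 0.1, 2.5, False),
    "NMDA": (0.0, 2.0, 30.0, True),
    "GABA_A": (-70.0, 0.5, 8.0, False),
}


@dataclass
class Synapse:
    """A dual-exponential conductance synapse on one compartment."""

    comp: int            # compartment index
    gmax: float          # µS
    e: float             # mV
    tau_rise: float      # ms
    tau_decay: float     # ms
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))
    voltage_gated: bool = False  # NMDA-style magnesium block
    mg: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))


def make_synapse(
    kind: str,
    comp: int,
    gmax: float = 5e-4,
    spike_times=(),
    nmda_ratio: float = 1.0,
    **overrides,
) -> list[Synapse]:
    """Build synapse(s) of a named type; AMPA_NMDA yields two components."""
    if kind == "AMPA_NMDA":
        return make_synapse("AMPA", comp, gmax, spike_times, **overrides) + (
            make_synapse("NMDA", comp, gmax * nmda_ratio, spike_times, **overrides)
            if nmda_ratio > 0
            else []
        )
    if kind not in SYNAPSE_DEFAULTS:
        raise ValueError(f"unknown synapse type {kind!r}")
    e, tr, td, vg = SYNAPSE_DEFAULTS[kind]
    return [
        Synapse(
            comp=comp,
            gmax=gmax,
            e=overrides.get("e", e),
            tau_rise=overrides.get("tau_rise", tr),
            tau_decay=overrides.get("tau_decay", td),
            spike_times=np.asarray(spike_times, dtype=float),
            voltage_gated=vg,
            mg=overrides.get("mg", 1.0),
        )
    ]


# ---------------------------------------------------------------------------
# Stimuli, recordings, traces
# ---------------------------------------------------------------------------

@dataclass
class StepCurrent:
    """Step current clamp: amplitude (nA) over [delay, delay+duration)."""

    comp: int
    amplitude: float  # nA
    delay: float = 0.0      # ms
    duration: float = 0.0   # ms

    def __post_init__(self) -> None:
        if self.delay < 0 or self.duration < 0:
            raise ValueError("delay and duration must be non-negative")

    def current(self, t: float) -> float:
        return self.amplitude if self.delay <= t < self.delay + self.duration else 0.0

    def mean_current(self, t0: float, t1: float) -> float:
        """Exact average current over (t0, t1] — charge-conserving for
        steps that switch inside an integration step."""
        lo = max(t0, self.delay)
        hi = min(t1, self.delay + self.duration)
        if hi <= lo or t1 <= t0:
            return 0.0
        return self.amplitude * (hi - lo) / (t1 - t0)


@dataclass
class Trace:
    """Recorded time series on a uniform time grid."""

    name: str
    location: str
    t: np.ndarray   # ms
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# Mechanisms and circuit assembly
# ---------------------------------------------------------------------------

class MechanismInstance:
    """One channel type inserted on a set of compartments.

    Gating curves are tabulated once on a fine voltage grid (0.05 mV,
    −120..100 mV) and evaluated by linear interpolation during the run;
    voltages outside the table clamp to its edges.
    """

    _TABLE_V = np.arange(-120.0, 100.0 + 0.05, 0.05)

    def __init__(self, name, channel, comps, gbar_density, areas, E,
                 temperature=None, tabulate=True):
        self.name = name
        self.channel = channel
        self.comps = np.asarray(comps, dtype=int)
        # absolute conductance µS = S/cm² · µm² · 1e-2
        self.gbar = np.asarray(gbar_density, float) * np.asarray(areas, float) * 1e-2
        self.E = float(E)
        self.powers = list(channel.states)  # [(state, power)]
        fns = channel.gating_functions(temperature)
        if tabulate and self.powers:
            tv = self._TABLE_V
            self._inf = {
                s: _TableFn(tv, np.asarray(fns[s][0](tv), float))
                for s, _ in self.powers
            }
            self._tau = {
                s: _TableFn(tv, np.asarray(fns[s][1](tv), float))
                for s, _ in self.powers
            }
        else:
            self._inf = {s: fns[s][0] for s, _ in self.powers}
            self._tau = {s: fns[s][1] for s, _ in self.powers}
        self.state: dict[str, np.ndarray] = {}

    def init_states(self, V: np.ndarray) -> None:
        Vc = V[self.comps]
        for s, _p in self.powers:
            self.state[s] = np.asarray(self._inf[s](Vc), float)

    def update_states(self, V: np.ndarray, dt: float) -> None:
        """Exact exponential update of dx/dt=(inf−x)/tau at frozen V."""
        Vc = V[self.comps]
        for s, _p in self.powers:
            inf = np.asarray(self._inf[s](Vc), float)
            tau = np.asarray(self._tau[s](Vc), float)
            self.state[s] = inf + (self.state[s] - inf) * np.exp(-dt / tau)

    def conductance(self) -> np.ndarray:
        """Instantaneous conductance (µS) per target compartment."""
        g = self.gbar.copy()
        for s, p in self.powers:
            g = g * self.state[s] ** p
        return g


class _TableFn:
    """Linear-interpolation lookup of a tabulated voltage curve."""

    __slots__ = ("v", "y")

    def __init__(self, v: np.ndarray, y: np.ndarray):
        self.v = v
        self.y = y

    def __call__(self, V):
        return np.interp(V, self.v, self.y)


class CableSystem:
    """Assembled compartmental circuit state."""

    def __init__(self, stree: SegmentTree, C, g_axial, parent, mechanisms):
        self.stree = stree
        self.C = np.asarray(C, float)            # nF
        self.g_axial = np.asarray(g_axial, float)  # µS, coupling i -> parent[i]
        self.parent = np.asarray(parent)         # -1 for root
        self.mechanisms: list[MechanismInstance] = mechanisms
        self.n = len(self.C)
        self.V = np.full(self.n, -65.0)
        self.t = 0.0

    def initialize(self, v_init: float = -65.0) -> None:
        self.V = np.full(self.n, float(v_init))
        self.t = 0.0
        for m in self.mechanisms:
            m.init_states(self.V)


def _axial_half_resistances(stree: SegmentTree, Ra: np.ndarray):
    """(R_prox, R_dist) in Ω from each compartment's center to its
    proximal / distal boundary, from frustum geometry."""
    R_prox = np.zeros(len(stree))
    R_dist = np.zeros(len(stree))
    for seg in stree:
        sec = seg.section
        if sec.is_spherical:
            continue  # point-like soma: no internal axial drop
        n = sec.nseg
        i_local = stree.section_segments[sec.idx].index(seg.idx)
        lo, hi = i_local / n, (i_local + 1) / n
        R_prox[seg.idx] = _arc_axial_res(sec, lo, seg.x) * Ra[seg.idx]
        R_dist[seg.idx] = _arc_axial_res(sec, seg.x, hi) * Ra[seg.idx]
    return R_prox, R_dist


def _arc_axial_res(sec, lo: float, hi: float) -> float:
    """∫ dl/(π r²) over a relative-arclength slice, per unit Ra (1/cm)."""
    L = sec.length
    a, b = lo * L, hi * L
    knots = [a] + [t for t in sec._arc if a < t < b] + [b]
    total = 0.0
    for t0, t1 in zip(knots[:-1], knots[1:]):
        r0 = float(np.interp(t0, sec._arc, sec._radii))
        r1 = float(np.interp(t1, sec._arc, sec._radii))
        if t1 > t0:
            # linear taper: ∫ dl/(π r²) = h/(π r0 r1)
            total += (t1 - t0) / (math.pi * r0 * r1)
    return total * 1e4  # µm units -> Ω per (Ω·cm of Ra)


def build_circuit(
    stree: SegmentTree,
    params,
    channels: dict[str, object] | None = None,
    reversals: dict[str, float] | None = None,
    temperature: float | None = None,
) -> CableSystem:
    """Assemble the compartmental circuit from a segment tree + parameters.

    ``params`` is a :class:`~dendrocable.distributions.ParamTable` (or any
    object with a ``values`` dict) holding per-segment ``cm`` (µF/cm²),
    ``Ra`` (Ω·cm) and ``gbar_<mech>`` (S/cm²) arrays; ``channels`` maps
    mechanism names to channel objects (states + gating_functions).
    """
    values = params.values if hasattr(params, "values") else params
    n = len(stree)
    for key in ("cm", "Ra"):
        if key not in values:
            raise ValueError(f"missing passive parameter {key!r}")
        if np.any(~np.isfinite(values[key])) or np.any(values[key] <= 0):
            bad = int(np.flatnonzero(~(values[key] > 0))[0])
            raise ValueError(f"non-positive {key} at segment {bad}")
    areas = np.array([s.area for s in stree])            # µm²
    C = values["cm"] * areas * 1e-5                       # nF
    Ra = np.asarray(values["Ra"], float)
    R_prox, R_dist = _axial_half_resistances(stree, Ra)
    parent = np.array([-1 if s.parent is None else s.parent for s in stree])
    g_axial = np.zeros(n)
    for i in range(n):
        p = parent[i]
        if p < 0:
            continue
        R = R_prox[i] + R_dist[p]
        g_axial[i] = 1e6 / R if R > 0 else 1e9  # µS; rigid link if zero
    mechanisms = []
    reversals = reversals or {}
    for name, chan in (channels or {}).items():
        key = f"gbar_{name}"
        if key not in values:
            continue
        dens = np.asarray(values[key], float)
        comps = np.flatnonzero(dens > 0)
        if comps.size == 0:
            continue
        if chan.ion is not None and chan.ion in reversals:
            E = reversals[chan.ion]
        elif getattr(chan, "E_name", None) in reversals:
            E = reversals[chan.E_name]
        else:
            E = chan.reversal()
        mechanisms.append(
            MechanismInstance(
                name, chan, comps, dens[comps], areas[comps], E, temperature
            )
        )
    return CableSystem(stree, C, g_axial, parent, mechanisms)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

class _SynapseState:
    """Per-run dual-exponential state (rise/decay impulse pair)."""

    def __init__(self, syn: Synapse):
        self.syn = syn
        self.A = 0.0
        self.B = 0.0
        self.norm = _dual_exp_norm(syn.tau_rise, syn.tau_decay)
        self._next = 0

    def step(self, t_new: float, dt: float) -> None:
        self.A *= math.exp(-dt / self.syn.tau_rise)
        self.B *= math.exp(-dt / self.syn.tau_decay)
        times = self.syn.spike_times
        while self._next < len(times) and times[self._next] <= t_new:
            # partial decay from the spike time to the end of the step
            rem = t_new - times[self._next]
            self.A += math.exp(-rem / self.syn.tau_rise)
            self.B += math.exp(-rem / self.syn.tau_decay)
            self._next += 1

    def conductance(self, V_comp: float) -> float:
        g = self.syn.gmax * self.norm * (self.B - self.A)
        if self.syn.voltage_gated:
            g *= float(nmda_gate(V_comp, mg=self.syn.mg))
        return max(g, 0.0)


def advance(
    sys: CableSystem,
    dt: float,
    stimuli: list[StepCurrent] = (),
    syn_states: list[_SynapseState] = (),
    theta: float = 1.0,
) -> None:
    """One implicit step of the current-balance equation.

    theta=1 is backward Euler; theta=0.5 Crank–Nicolson.  Gating states
    advance first by their exact exponential update at the pre-step
    voltage; the resulting linear system is solved exactly by one
    downward and one upward sweep in tree order.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V_old = sys.V
    t_new = sys.t + dt

    for m in sys.mechanisms:
        m.update_states(V_old, dt)

    n = sys.n
    g_total = np.zeros(n)
    ge_total = np.zeros(n)  # Σ g·E  (µS·mV = nA)
    for m in sys.mechanisms:
        g = m.conductance()
        np.add.at(g_total, m.comps, g)
        np.add.at(ge_total, m.comps, g * m.E)
    for ss in syn_states:
        ss.step(t_new, dt)
        g = ss.conductance(V_old[ss.syn.comp])
        g_total[ss.syn.comp] += g
        ge_total[ss.syn.comp] += g * ss.syn.e

    # external current enters as its exact average over the step, so a
    # discontinuous step injects the correct charge regardless of phase
    I_ext = np.zeros(n)
    for stim in stimuli:
        I_ext[stim.comp] += stim.mean_current(sys.t, t_new)

    # linear membrane operator F(V) = -G V + b
    b = ge_total + I_ext
    diag = sys.C / dt + theta * g_total
    off = np.zeros(n)
    GV_old = g_total * V_old
    parent = sys.parent
    gax = sys.g_axial
    for i in range(1, n):
        p = parent[i]
        if p < 0:
            continue
        off[i] = -theta * gax[i]
        diag[i] += theta * gax[i]
        diag[p] += theta * gax[i]
        dv = V_old[i] - V_old[p]
        GV_old[i] += gax[i] * dv
        GV_old[p] -= gax[i] * dv
    rhs = (sys.C / dt) * V_old - (1.0 - theta) * GV_old + b
    # the (1-theta) explicit part of the non-axial membrane current
    # G V_old above already includes conductive terms; b is fully implicit

    # Hines elimination: children before parents
    diag = diag.copy()
    rhs = rhs.copy()
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p < 0:
            continue
        f = off[i] / diag[i]
        diag[p] -= f * off[i]
        rhs[p] -= f * rhs[i]
    V_new = np.empty(n)
    V_new[0] = rhs[0] / diag[0]
    for i in range(1, n):
        p = parent[i]
        V_new[i] = (rhs[i] - off[i] * V_new[p]) / diag[i] if p >= 0 else rhs[i] / diag[i]
    if not np.all(np.isfinite(V_new)):
        raise FloatingPointError(f"non-finite voltage at t = {t_new:g} ms")
    sys.V = V_new
    sys.t = t_new


def run(
    system: CableSystem,
    stimuli: list[StepCurrent] = (),
    synapses: list[Synapse] = (),
    recordings: list[tuple[str, int]] = (("v", 0),),
    tstop: float = 100.0,
    dt: float = 0.025,
    v_init: float = -65.0,
    theta: float = 1.0,
    t_equil: float = 0.0,
) -> dict[str, Trace]:
    """Integrate and record.

    ``recordings`` are (variable, compartment) pairs; only 'v' is
    recorded.  An optional free-running equilibration window of
    ``t_equil`` ms precedes t=0 and is excluded from the traces.
    """
    if tstop <= 0:
        raise ValueError("tstop must be positive")
    system.initialize(v_init)
    syn_states = [_SynapseState(s) for s in synapses]
    if t_equil > 0:
        nequil = int(round(t_equil / dt))
        for _ in range(nequil):
            advance(system, dt, (), (), theta)
        system.t = 0.0
    nsteps = int(round(tstop / dt))
    t_grid = np.arange(nsteps + 1) * dt
    out = {f"{var}@{comp}": np.empty(nsteps + 1) for var, comp in recordings}
    for var, comp in recordings:
        out[f"{var}@{comp}"][0] = system.V[comp]
    for k in range(1, nsteps + 1):
        advance(system, dt, stimuli, syn_states, theta)
        for var, comp in recordings:
            out[f"{var}@{comp}"][k] = system.V[comp]
    return {
        key: Trace(name=key.split("@")[0], location=key.split("@")[1], t=t_grid,
                   values=vals)
        for key, vals in out.items()
    }
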
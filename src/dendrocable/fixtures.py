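"""Synthetic inputs for testing and demonstration.

Everything other modules need — morphologies, channel MOD files,
biophysics configurations, synthetic traces with known ground truth —
is generated here programmatically, so the package is fully testable
without any downloaded reconstruction or mechanism files.

All generators are deterministic: identical arguments (and seed, where
one applies) produce identical bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import BiophysConfig, DistributionFunction, SegmentGroup
from .simulator import Trace

__all__ = [
    "make_ball_and_stick",
    "make_binary_tree",
    "make_single_cylinder",
    "make_point_neuron",
    "make_y_tree",
    "make_toy_channels",
    "make_passive_config",
    "make_hh_config",
    "make_synthetic_trace",
]


# ---------------------------------------------------------------------------
# Morphologies (SWC text)
# ---------------------------------------------------------------------------

def _swc(lines: list[tuple[int, int, float, float, float, float, int]]) -> str:
    body = "\n".join(
        f"{i} {c} {x:g} {y:g} {z:g} {r:g} {p}" for i, c, x, y, z, r, p in lines
    )
    return body + "\n"


def make_ball_and_stick(
    stick_length: float = 200.0,
    stick_diam: float = 2.0,
    soma_diam: float = 20.0,
    n_stick_points: int = 11,
    domain_code: int = 4,
) -> str:
    """Spherical soma plus one uniform cylindrical (apical) dendrite.

    The first stick point coincides with the soma center so the stick
    section's length equals ``stick_length`` exactly.
    """
    if stick_length <= 0 or stick_diam <= 0 or soma_diam <= 0:
        raise ValueError("geometry must be positive")
    lines = [(1, 1, 0.0, 0.0, 0.0, soma_diam / 2, -1)]
    r = stick_diam / 2
    for k in range(n_stick_points):
        x = stick_length * k / (n_stick_points - 1)
        lines.append((2 + k, domain_code, x, 0.0, 0.0, r, 1 + k))
    return _swc(lines)


def make_binary_tree(
    depth: int = 3,
    branch_length: float = 50.0,
    root_diam: float = 2.0,
    taper: float = 0.7,
    soma_diam: float = 20.0,
) -> str:
    """Soma plus a symmetric binary tree of 2^depth − 1 basal sections.

    Each branch carries two own points (midpoint and endpoint) so every
    section holds ≥2 points; diameters shrink by ``taper`` per level.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lines = [(1, 1, 0.0, 0.0, 0.0, soma_diam / 2, -1)]
    counter = [1]

    def add_branch(parent_id, x0, y0, angle, level):
        if level >= depth:
            return
        d = root_diam * taper**level
        L = branch_length
        x1, y1 = x0 + L * math.cos(angle), y0 + L * math.sin(angle)
        xm, ym = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        mid_id = counter[0] + 1
        end_id = counter[0] + 2
        counter[0] += 2
        lines.append((mid_id, 3, xm, ym, 0.0, d / 2, parent_id))
        lines.append((end_id, 3, x1, y1, 0.0, d / 2, mid_id))
        spread = math.pi / (2 ** (level + 2))
        add_branch(end_id, x1, y1, angle + spread, level + 1)
        add_branch(end_id, x1, y1, angle - spread, level + 1)

    add_branch(1, 0.0, 0.0, 0.0, 0)
    return _swc(lines)


def make_single_cylinder(
    length: float = 1000.0, diam: float = 2.0, n_points: int = 21, domain_code: int = 4
) -> str:
    """An unbranched uniform cable with no soma (sealed-end cylinder)."""
    if length <= 0 or diam <= 0:
        raise ValueError("geometry must be positive")
    r = diam / 2
    lines = []
    for k in range(n_points):
        x = length * k / (n_points - 1)
        lines.append((k + 1, domain_code, x, 0.0, 0.0, r, k if k else -1))
    return _swc(lines)


def make_point_neuron(soma_diam: float = 20.0) -> str:
    """A single-point spherical soma (an isopotential patch)."""
    if soma_diam <= 0:
        raise ValueError("geometry must be positive")
    return _swc([(1, 1, 0.0, 0.0, 0.0, soma_diam / 2, -1)])


def make_y_tree(
    stem_length: float = 100.0,
    branch_length: float = 150.0,
    stem_diam: float = 2.0,
    branch_diam: float = 1.4,
    soma_diam: float = 20.0,
) -> str:
    """Soma, one apical stem, and two symmetric daughter branches."""
    lines = [(1, 1, 0.0, 0.0, 0.0, soma_diam / 2, -1)]
    rs = stem_diam / 2
    rb = branch_diam / 2
    # stem: 3 points along +x, first at the soma center
    for k, frac in enumerate((0.0, 0.5, 1.0)):
        lines.append((2 + k, 4, stem_length * frac, 0.0, 0.0, rs, 1 + k))
    ang = math.pi / 6
    nid = 5
    for sgn in (+1, -1):
        parent = 4  # stem end
        # first branch point repeats the junction coordinate with the
        # branch calibre, so each branch is a uniform cylinder
        for frac in (0.0, 0.5, 1.0):
            x = stem_length + branch_length * frac * math.cos(sgn * ang)
            y = branch_length * frac * math.sin(sgn * ang)
            lines.append((nid, 4, x, y, 0.0, rb, parent))
            parent = nid
            nid += 1
    return _swc(lines)


# ---------------------------------------------------------------------------
# Toy channels (NMODL text)
# ---------------------------------------------------------------------------

_NA_MOD = """\
TITLE toy transient sodium channel (m3h gating, rate-constant style)

NEURON {
    SUFFIX tna
    USEION na READ ena WRITE ina
    RANGE gbar
}

PARAMETER {
    gbar = 0.12 (S/cm2)
    ena = 50 (mV)
}

STATE { m h }

ASSIGNED {
    v (mV)
    ina (mA/cm2)
}

BREAKPOINT {
    SOLVE states METHOD cnexp
    ina = gbar*m*m*m*h*(v - ena)
}

INITIAL {
    m = alpham(v)/(alpham(v) + betam(v))
    h = alphah(v)/(alphah(v) + betah(v))
}

DERIVATIVE states {
    m' = alpham(v)*(1 - m) - betam(v)*m
    h' = alphah(v)*(1 - h) - betah(v)*h
}

FUNCTION alpham(v (mV)) (/ms) {
    alpham = 0.1*(v + 40)/(1 - exp(-(v + 40)/10))
}

FUNCTION betam(v (mV)) (/ms) {
    betam = 4*exp(-(v + 65)/18)
}

FUNCTION alphah(v (mV)) (/ms) {
    alphah = 0.07*exp(-(v + 65)/20)
}

FUNCTION betah(v (mV)) (/ms) {
    betah = 1/(1 + exp(-(v + 35)/10))
}
"""

_KDR_MOD = """\
TITLE toy delayed-rectifier potassium channel (n4 gating, inf/tau style)

NEURON {
    SUFFIX tkdr
    USEION k READ ek WRITE ik
    RANGE gbar
    GLOBAL ninf, ntau
}

PARAMETER {
    gbar = 0.036 (S/cm2)
    ek = -77 (mV)
    q10 = 3
    celsius = 6.3 (degC)
}

STATE { n }

ASSIGNED {
    v (mV)
    ik (mA/cm2)
    ninf
    ntau (ms)
}

BREAKPOINT {
    SOLVE states METHOD cnexp
    ik = gbar*n^4*(v - ek)
}

INITIAL {
    rates(v)
    n = ninf
}

DERIVATIVE states {
    rates(v)
    n' = (ninf - n)/ntau
}

PROCEDURE rates(v (mV)) {
    LOCAL a, b, tadj
    a = 0.01*(v + 55)/(1 - exp(-(v + 55)/10))
    b = 0.125*exp(-(v + 65)/80)
    tadj = q10^((celsius - 6.3)/10)
    ninf = a/(a + b)
    ntau = 1/(tadj*(a + b))
}
"""

_LEAK_MOD = """\
TITLE toy passive leak conductance

NEURON {
    SUFFIX tleak
    NONSPECIFIC_CURRENT i
    RANGE gbar, e
}

PARAMETER {
    gbar = 0.0003 (S/cm2)
    e = -54.3 (mV)
}

ASSIGNED {
    v (mV)
    i (mA/cm2)
}

BREAKPOINT {
    i = gbar*(v - e)
}
"""


def make_toy_channels() -> dict[str, str]:
    """Three MOD files: Na (m³h, α/β style), Kdr (n⁴, inf/τ style with
    a q10 temperature correction), and a leak conductance."""
    return {"tna": _NA_MOD, "tkdr": _KDR_MOD, "tleak": _LEAK_MOD}


# ---------------------------------------------------------------------------
# Biophysics configurations
# ---------------------------------------------------------------------------

def make_passive_config(
    g_leak: float = 1e-4,
    e_leak: float = -65.0,
    cm: float = 1.0,
    Ra: float = 150.0,
    domains: list[str] | None = None,
) -> BiophysConfig:
    """Uniform passive membrane (leak only) over the given domains."""
    domains = domains or ["soma", "apical", "basal"]
    return BiophysConfig(
        domains={d: ["tleak"] for d in domains},
        groups=[SegmentGroup(name="all")],
        parameters={
            "cm": (None, {"all": DistributionFunction.constant(cm)}),
            "Ra": (None, {"all": DistributionFunction.constant(Ra)}),
            "gbar_tleak": ("tleak", {"all": DistributionFunction.constant(g_leak)}),
        },
        globals={"cm": cm, "Ra": Ra, "v_init": e_leak},
        reversals={"e": e_leak},
    )


def make_hh_config(
    gna: float = 0.12,
    gk: float = 0.036,
    g_leak: float = 3e-4,
    cm: float = 1.0,
    Ra: float = 150.0,
    domains: list[str] | None = None,
) -> BiophysConfig:
    """Uniform excitable membrane: toy Na + Kdr + leak everywhere."""
    domains = domains or ["soma", "apical", "basal"]
    return BiophysConfig(
        domains={d: ["tna", "tkdr", "tleak"] for d in domains},
        groups=[SegmentGroup(name="all")],
        parameters={
            "cm": (None, {"all": DistributionFunction.constant(cm)}),
            "Ra": (None, {"all": DistributionFunction.constant(Ra)}),
            "gbar_tna": ("tna", {"all": DistributionFunction.constant(gna)}),
            "gbar_tkdr": ("tkdr", {"all": DistributionFunction.constant(gk)}),
            "gbar_tleak": ("tleak", {"all": DistributionFunction.constant(g_leak)}),
        },
        globals={"cm": cm, "Ra": Ra, "v_init": -65.0},
        reversals={"na": 50.0, "k": -77.0},
    )


# ---------------------------------------------------------------------------
# Synthetic traces with known ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrace:
    trace: Trace
    truth: dict


def make_synthetic_trace(kind: str, seed: int = 0, **params) -> SyntheticTrace:
    """Generate an analysis-ready trace with its ground-truth outputs.

    Kinds: ``exp`` (single-exponential step response), ``double_exp``
    (two components), ``triangle_spikes`` (piecewise-linear spikes),
    ``sag`` (hyperpolarizing step with rebound).
    """
    dt = params.get("dt", 0.025)
    if kind == "exp":
        tau = params.get("tau", 20.0)
        onset = params.get("onset", 20.0)
        v0, dv = params.get("v0", -65.0), params.get("dv", -10.0)
        tstop = onset + 10 * tau
        t = np.arange(0.0, tstop + dt, dt)
        v = np.full_like(t, v0)
        m = t >= onset
        v[m] = v0 + dv * (1 - np.exp(-(t[m] - onset) / tau))
        truth = {"tau": tau, "onset": onset, "v_inf": v0 + dv}
    elif kind == "double_exp":
        tau1 = params.get("tau_fast", 5.0)
        tau2 = params.get("tau_slow", 30.0)
        a1, a2 = params.get("a_fast", -3.0), params.get("a_slow", -7.0)
        onset = params.get("onset", 20.0)
        v0 = params.get("v0", -65.0)
        tstop = onset + 10 * tau2
        t = np.arange(0.0, tstop + dt, dt)
        v = np.full_like(t, v0)
        m = t >= onset
        td = t[m] - onset
        v[m] = (
            v0 + a1 + a2
            - a1 * np.exp(-td / tau1)
            - a2 * np.exp(-td / tau2)
        )
        truth = {"tau_slow": tau2, "tau_fast": tau1, "onset": onset}
    elif kind == "triangle_spikes":
        n = params.get("n", 3)
        isi = params.get("isi", 50.0)
        baseline = params.get("baseline", -70.0)
        peak = params.get("peak", 30.0)
        rise = params.get("rise", 1.0)
        fall = params.get("fall", 2.0)
        first = params.get("first", 20.0)
        tstop = first + n * isi + 20.0
        t = np.arange(0.0, tstop + dt, dt)
        v = np.full_like(t, baseline)
        for k in range(n):
            tp = first + k * isi
            up = (t >= tp - rise) & (t <= tp)
            dn = (t > tp) & (t <= tp + fall)
            v[up] = baseline + (peak - baseline) * (t[up] - (tp - rise)) / rise
            v[dn] = peak + (baseline - peak) * (t[dn] - tp) / fall
        # half-amplitude width of an asymmetric triangle
        truth = {
            "n": n,
            "isi": isi,
            "amplitude": peak - baseline,
            "half_width": (rise + fall) / 2,
            "peak_times": [first + k * isi for k in range(n)],
        }
    elif kind == "sag":
        v_onset = params.get("v_onset", -70.0)
        v_min = params.get("v_min", -80.0)
        v_offset = params.get("v_offset", -75.0)
        onset, offset = params.get("onset", 50.0), params.get("offset", 250.0)
        t_min = onset + params.get("t_to_min", 30.0)
        tstop = offset + 50.0
        t = np.arange(0.0, tstop + dt, dt)
        v = np.full_like(t, v_onset)
        drop = (t >= onset) & (t <= t_min)
        v[drop] = v_onset + (v_min - v_onset) * (t[drop] - onset) / (t_min - onset)
        # recovery completes before the step ends so the end-of-step
        # level (mean of the last 5%) equals v_offset exactly
        t_flat = offset - 0.2 * (offset - t_min)
        rise = (t > t_min) & (t <= t_flat)
        v[rise] = v_min + (v_offset - v_min) * (t[rise] - t_min) / (t_flat - t_min)
        v[t > t_flat] = v_offset
        b = v_onset - v_min
        truth = {
            "sag_ratio": (v_offset - v_min) / b if b else np.nan,
            "onset": onset,
            "offset": offset,
        }
    else:
        raise ValueError(f"unknown synthetic trace kind {kind!r}")
    return SyntheticTrace(
        trace=Trace(name="v", location="synthetic", t=t, values=v), truth=truth
    )
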
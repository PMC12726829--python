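"""Ion-channel kinetics: parsing, evaluation, and standardization.

A channel is a set of gating variables ``x`` with first-order dynamics
``dx/dt = (x_inf(V) - x)/tau_x(V)`` and an open probability
``p = prod x_i^{p_i}``; the current density is ``I = gbar * p * (V - E)``.

Standardization refits arbitrary channel kinetics to a transition-state
form with five parameters per gating variable:

* ``x_inf(V) = 1/(1 + exp(-(V - v_half)/sigma))``
* ``tau_x(V) = 1/(alpha + beta) + tau_0`` with
  ``alpha = K exp(delta (V - v_half)/sigma)`` and
  ``beta  = K exp(-(1 - delta)(V - v_half)/sigma)``

so that ``alpha/(alpha + beta)`` equals ``x_inf`` identically.  v_half
(mV) is the half-activation voltage, sigma (mV) the inverse slope, K
(1/ms) the maximum rate, delta the skew of the time-constant curve, and
tau_0 (ms) the rate-limiting minimum time constant.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.optimize import least_squares

from .nmodl import ModAST, ModParseError, parse_mod

__all__ = [
    "GatingParams",
    "ChannelSpec",
    "StandardChannel",
    "KineticCurves",
    "StandardizedGate",
    "steady_state",
    "time_constant",
    "rate_alpha",
    "rate_beta",
    "channel_current",
    "spec_from_ast",
    "load_channel",
    "evaluate_kinetics",
    "fit_standard",
    "render_standard_mod",
]

_V = sp.Symbol("v")
_CELSIUS = sp.Symbol("celsius")

DEFAULT_GRID = np.arange(-100.0, 100.0 + 0.5, 1.0)

# fallback reversal potentials (mV) when the MOD file leaves them to the ion
DEFAULT_REVERSALS = {"na": 50.0, "k": -77.0, "ca": 140.0}


# ---------------------------------------------------------------------------
# The 5-parameter standardized gate
# ---------------------------------------------------------------------------

@dataclass
class GatingParams:
    """Five-parameter transition-state kinetics of one gating variable."""

    v_half: float  # mV
    sigma: float   # mV, sign sets activation (+) vs inactivation (-)
    K: float       # 1/ms
    delta: float   # unitless in (0, 1)
    tau_0: float   # ms, >= 0

    def __post_init__(self) -> None:
        if self.sigma == 0:
            raise ValueError("sigma must be nonzero")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0 < self.delta < 1):
            raise ValueError("delta must lie in (0, 1)")
        if self.tau_0 < 0:
            raise ValueError("tau_0 must be non-negative")

    def steady_state(self, V):
        return steady_state(self, V)

    def time_constant(self, V):
        return time_constant(self, V)


def steady_state(gp: GatingParams, V):
    """x_inf(V) = 1/(1 + exp(-(V - v_half)/sigma))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - gp.v_half) / gp.sigma))


def rate_alpha(gp: GatingParams, V):
    return gp.K * np.exp(gp.delta * (np.asarray(V, float) - gp.v_half) / gp.sigma)


def rate_beta(gp: GatingParams, V):
    return gp.K * np.exp(
        -(1.0 - gp.delta) * (np.asarray(V, float) - gp.v_half) / gp.sigma
    )


def time_constant(gp: GatingParams, V):
    """tau(V) = 1/(alpha + beta) + tau_0; alpha/(alpha+beta) == x_inf."""
    return 1.0 / (rate_alpha(gp, V) + rate_beta(gp, V)) + gp.tau_0


def channel_current(gbar, p, V, E):
    """Ohmic channel current density: I = gbar * p * (V - E)."""
    return gbar * p * (np.asarray(V, float) - E)


# ---------------------------------------------------------------------------
# Channel specifications
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """A parsed channel: gating structure plus symbolic kinetics.

    ``inf``/``tau`` map each state name to a sympy expression in the
    membrane potential ``v`` (mV) and, if the mechanism is
    temperature-corrected, ``celsius`` (°C).
    """

    name: str
    ion: str | None            # None for nonspecific (leak) currents
    gbar_name: str
    gbar: float                # S/cm²
    E_name: str | None
    E: float | None            # mV; None if left to the simulator's ion table
    states: list[tuple[str, int]]
    inf: dict[str, sp.Expr] = field(default_factory=dict)
    tau: dict[str, sp.Expr] = field(default_factory=dict)
    temp_def: float | None = None  # °C the mechanism was defined at

    @property
    def state_names(self) -> list[str]:
        return [s for s, _ in self.states]

    def reversal(self) -> float:
        if self.E is not None:
            return self.E
        if self.ion in DEFAULT_REVERSALS:
            return DEFAULT_REVERSALS[self.ion]
        raise ValueError(f"no reversal potential known for channel {self.name}")

    def gating_functions(self, temperature: float | None = None):
        """Per-state (inf, tau) numpy callables at a given temperature."""
        temp = temperature if temperature is not None else self.temp_def
        out = {}
        for s in self.state_names:
            out[s] = (
                _make_callable(self.inf[s], temp),
                _make_callable(self.tau[s], temp),
            )
        return out

    def open_probability(self, state_values: dict[str, float]) -> float:
        p = 1.0
        for s, power in self.states:
            p *= state_values[s] ** power
        return p


def _make_callable(expr: sp.Expr, temperature: float | None):
    """Lambdify with removable-singularity handling via symbolic limits."""
    if temperature is not None:
        expr = expr.subs(_CELSIUS, temperature)
    if _CELSIUS in expr.free_symbols:
        raise ValueError(
            "expression is temperature-dependent but no temperature given"
        )
    fn = sp.lambdify(_V, expr, modules="numpy")
    # removable-singularity guard: points where a denominator nearly
    # cancels (|den| < 1e-6 of its additive-term scale) are evaluated by
    # a numeric limit — naive evaluation can return a wrong finite value
    num_e, den_e = sp.fraction(sp.together(expr))
    den_terms = sp.Add.make_args(sp.expand(den_e))
    fn_den = sp.lambdify(_V, den_e, modules="numpy")
    fn_den_scale = sp.lambdify(
        _V, sp.Add(*[sp.Abs(t) for t in den_terms]), modules="numpy"
    )
    limit_cache: dict[float, float] = {}

    def numeric_limit(v0: float) -> float:
        # two-sided evaluation next to a removable singularity; symbolic
        # limits are unreliable on large float-coefficient rationals
        for eps in (1e-6, 1e-5, 1e-4, 1e-3):
            with np.errstate(all="ignore"):
                lo = float(np.asarray(fn(np.array([v0 - eps])), float)[0])
                hi = float(np.asarray(fn(np.array([v0 + eps])), float)[0])
            if np.isfinite(lo) and np.isfinite(hi):
                scale = max(abs(lo), abs(hi), 1e-30)
                if abs(hi - lo) / scale < 1e-3:
                    return 0.5 * (lo + hi)
        raise ValueError(f"cannot evaluate expression limit at v = {v0}")

    def wrapped(V):
        V = np.asarray(V, dtype=float)
        scalar = V.ndim == 0
        Va = np.atleast_1d(V)
        with np.errstate(all="ignore"):
            out = np.asarray(fn(Va), dtype=float)
            den = np.asarray(fn_den(Va), dtype=float)
            den_scale = np.asarray(fn_den_scale(Va), dtype=float)
        if out.shape != Va.shape:
            out = np.full_like(Va, float(out))
        den = np.broadcast_to(den, Va.shape)
        den_scale = np.broadcast_to(den_scale, Va.shape)
        bad = ~np.isfinite(out)
        with np.errstate(invalid="ignore"):
            bad |= np.abs(den) < 1e-6 * den_scale
        if bad.any():
            for i in np.flatnonzero(bad):
                v0 = float(Va[i])
                if v0 not in limit_cache:
                    limit_cache[v0] = numeric_limit(v0)
                out[i] = limit_cache[v0]
        return float(out[0]) if scalar else out

    return wrapped


@dataclass
class StandardChannel:
    """A channel in the standardized 5-parameter form."""

    name: str
    ion: str | None
    gbar: float
    E: float
    states: list[tuple[str, int]]
    params: dict[str, GatingParams] = field(default_factory=dict)
    gbar_name: str = "gbar"

    @property
    def state_names(self) -> list[str]:
        return [s for s, _ in self.states]

    def reversal(self) -> float:
        return self.E

    def gating_functions(self, temperature: float | None = None):
        out = {}
        for s in self.state_names:
            gp = self.params[s]
            out[s] = (
                (lambda V, gp=gp: steady_state(gp, V)),
                (lambda V, gp=gp: time_constant(gp, V)),
            )
        return out


# ---------------------------------------------------------------------------
# AST -> ChannelSpec
# ---------------------------------------------------------------------------

_SYMPY_FUNCS = {
    "exp": sp.exp,
    "log": sp.log,
    "log10": lambda x: sp.log(x, 10),
    "fabs": sp.Abs,
    "sqrt": sp.sqrt,
    "pow": sp.Pow,
}


def _to_sympy(text: str, inliners: dict) -> sp.Expr:
    text = text.replace("^", "**")
    local = dict(_SYMPY_FUNCS)
    local.update(inliners)
    try:
        return sp.sympify(text, locals=local)
    except (sp.SympifyError, TypeError, SyntaxError) as exc:
        raise ModParseError(f"cannot interpret expression {text!r}: {exc}") from exc


def _resolve(expr: sp.Expr, env: dict[sp.Symbol, sp.Expr], max_iter: int = 50):
    for _ in range(max_iter):
        nxt = expr.xreplace(env)
        if nxt == expr:
            return expr
        expr = nxt
    raise ModParseError("circular symbol definitions in MOD file")


def _build_function_inliners(ast: ModAST) -> dict:
    """Turn FUNCTION blocks into sympy-inlinable python callables."""
    inliners: dict = {}

    def make(fname: str):
        fdef = ast.functions[fname]

        def call(*args):
            if len(args) != len(fdef.args):
                raise ModParseError(
                    f"function {fname} called with {len(args)} args"
                )
            env = {sp.Symbol(a): sp.sympify(x) for a, x in zip(fdef.args, args)}
            for st in fdef.statements:
                if st.is_derivative:
                    raise ModParseError(f"derivative inside FUNCTION {fname}")
                rhs = _to_sympy(st.rhs, inliners).xreplace(env)
                env[sp.Symbol(st.lhs)] = rhs
            try:
                return env[sp.Symbol(fname)]
            except KeyError:
                raise ModParseError(f"FUNCTION {fname} never assigns its value")

        return call

    for fname in ast.functions:
        inliners[fname] = make(fname)
    return inliners


def spec_from_ast(ast: ModAST) -> ChannelSpec:
    """Extract the gating structure and kinetics from a parsed MOD file.

    Steady states and time constants are derived symbolically from each
    state's ODE: with the right-hand side linear in x (``a + b x``),
    ``tau = -1/b`` and ``inf = -a/b``.  This covers both the
    ``(x_inf - x)/x_tau`` and the ``alpha (1 - x) - beta x`` authoring
    styles, including helper symbols defined in PROCEDURE blocks.
    """
    inliners = _build_function_inliners(ast)
    params_env = {
        sp.Symbol(n): sp.Float(val)
        for n, (val, _u) in ast.parameters.items()
        if val is not None and n not in ("v", "celsius")
    }

    # run PROCEDURE bodies to collect assigned helper symbols
    assigned_env: dict[sp.Symbol, sp.Expr] = {}

    def run_procedure(pd, arg_exprs=None):
        env_local = dict(assigned_env)
        if arg_exprs is None:
            arg_exprs = [sp.Symbol(a) for a in pd.args]
        for a, x in zip(pd.args, arg_exprs):
            env_local[sp.Symbol(a)] = sp.sympify(x)
        for st in pd.statements:
            if st.is_derivative:
                continue
            rhs = _to_sympy(st.rhs, inliners)
            rhs = _resolve(rhs, {**env_local, **params_env})
            env_local[sp.Symbol(st.lhs)] = rhs
            if st.lhs not in pd.args and st.lhs not in pd.locals:
                assigned_env[sp.Symbol(st.lhs)] = rhs

    called = []
    for c in (ast.derivative.calls if ast.derivative else []) + ast.breakpoint_calls:
        m = re.match(r"^(\w+)\s*\(", c)
        if m and m.group(1) in ast.procedures:
            called.append(m.group(1))
    for name in called:
        run_procedure(ast.procedures[name])
    for name, pd in ast.procedures.items():
        if name not in called:
            run_procedure(pd)

    # per-state kinetics from the ODE
    inf: dict[str, sp.Expr] = {}
    tau: dict[str, sp.Expr] = {}
    resolve_env = {**assigned_env, **params_env}
    if ast.derivative is not None:
        for st in ast.derivative.statements:
            if not st.is_derivative:
                # inline assignments inside DERIVATIVE update the env
                rhs = _resolve(_to_sympy(st.rhs, inliners), resolve_env)
                resolve_env[sp.Symbol(st.lhs)] = rhs
                continue
            x = sp.Symbol(st.lhs)
            rhs = _resolve(_to_sympy(st.rhs, inliners), resolve_env)
            # rhs must be linear in x: rhs = a + b*x, tau = -1/b, inf = -a/b
            b = sp.diff(rhs, x)
            if x in b.free_symbols:
                b = sp.cancel(b)
            if x in b.free_symbols or b == 0:
                candidates = [s for s in ast.assigned if st.lhs.lower() in s.lower()]
                raise ModParseError(
                    f"cannot identify first-order kinetics for state {st.lhs!r};"
                    f" candidate symbols: {candidates}"
                )
            a = rhs.subs(x, 0)
            # cancel() keeps the algebra compact; full simplify()/expand()
            # can blow up on inlined rational-exponential rate functions
            tau[st.lhs] = sp.together(-1 / b)
            inf[st.lhs] = sp.cancel(sp.together(-a / b))

    # current expression from BREAKPOINT (parameters kept symbolic)
    bp_env: dict[sp.Symbol, sp.Expr] = dict(assigned_env)
    current_syms: list[str] = list(ast.nonspecific)
    for ion, rw in ast.ions.items():
        current_syms.extend(w for w in rw["write"] if w.startswith("i"))
    current_expr = sp.Integer(0)
    for st in ast.breakpoint:
        rhs = _resolve(_to_sympy(st.rhs, inliners), bp_env)
        bp_env[sp.Symbol(st.lhs)] = rhs
        if st.lhs in current_syms:
            current_expr = current_expr + rhs
    if current_expr == 0:
        raise ModParseError("BREAKPOINT assigns no membrane current")

    state_syms = [sp.Symbol(s) for s in ast.states]
    powers = []
    p_expr = sp.Integer(1)
    for s, xsym in zip(ast.states, state_syms):
        deg = sp.degree(sp.expand(current_expr), xsym)
        deg = int(deg) if deg is not None else 0
        if deg < 1:
            raise ModParseError(f"state {s!r} does not appear in the current")
        powers.append((s, deg))
        p_expr *= xsym**deg

    # I = gbar * p * (v - E): divide out p and read gbar and E off
    q = sp.simplify(sp.cancel(current_expr / p_expr))
    c1 = sp.diff(q, _V)
    if c1 == 0:
        raise ModParseError("current does not depend on v (not ohmic)")
    E_expr = sp.simplify(_V - q / c1)
    gbar_sym_candidates = [
        s for s in c1.free_symbols if s.name in ast.parameters
    ]
    if len(gbar_sym_candidates) == 1:
        gbar_name = gbar_sym_candidates[0].name
        gbar_val = ast.parameter_value(gbar_name, 0.0)
    else:
        gbar_name = "gbar"
        gbar_val = float(c1.xreplace(params_env)) if not c1.free_symbols else 0.0

    ion = next(iter(ast.ions), None)
    E_name = None
    E_val: float | None = None
    free_E = [s for s in E_expr.free_symbols if s is not _V]
    if len(free_E) == 1:
        E_name = free_E[0].name
        E_val = ast.parameter_value(E_name, None)
    elif not free_E:
        E_val = float(E_expr)

    temp_def = ast.parameter_value("celsius", None)
    return ChannelSpec(
        name=ast.suffix,
        ion=ion,
        gbar_name=gbar_name,
        gbar=float(gbar_val if gbar_val is not None else 0.0),
        E_name=E_name,
        E=E_val,
        states=powers,
        inf=inf,
        tau=tau,
        temp_def=temp_def,
    )


def load_channel(text: str) -> ChannelSpec:
    """Parse NMODL source straight into a :class:`ChannelSpec`."""
    return spec_from_ast(parse_mod(text))


# ---------------------------------------------------------------------------
# Kinetic curves and standardization
# ---------------------------------------------------------------------------

@dataclass
class KineticCurves:
    """Steady-state and time-constant curves on a voltage grid."""

    v: np.ndarray                    # mV, strictly increasing
    inf: dict[str, np.ndarray]       # unitless, in [0, 1]
    tau: dict[str, np.ndarray]       # ms, > 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.v) <= 0):
            raise ValueError("voltage grid must be strictly increasing")


def evaluate_kinetics(
    spec, grid: np.ndarray | None = None, temperature: float | None = None
) -> KineticCurves:
    """Evaluate a channel's gating curves on a voltage grid (mV)."""
    v = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, float)
    inf, tau = {}, {}
    for s, (f_inf, f_tau) in spec.gating_functions(temperature).items():
        inf[s] = np.asarray(f_inf(v), float)
        tau[s] = np.asarray(f_tau(v), float)
    return KineticCurves(v=v, inf=inf, tau=tau)


@dataclass
class StandardizedGate:
    params: GatingParams
    inf_rmse: float
    tau_rmse: float
    warnings: list[str] = field(default_factory=list)


def _fit_gate(v: np.ndarray, inf: np.ndarray, tau: np.ndarray) -> StandardizedGate:
    warnings: list[str] = []
    dinf = np.diff(inf)
    if not (np.all(dinf >= -1e-9) or np.all(dinf <= 1e-9)):
        warnings.append("steady-state curve is non-monotone; fit quality reduced")
    increasing = inf[-1] >= inf[0]

    # initial guesses from curve geometry
    half = 0.5 * (inf.min() + inf.max())
    idx = int(np.argmin(np.abs(inf - half)))
    vh0 = float(v[idx])
    slope = float(np.max(np.abs(np.gradient(inf, v))))
    sig0 = 1.0 / (4.0 * max(slope, 1e-6))
    if not increasing:
        sig0 = -sig0
    tau0_0 = max(0.0, 0.5 * float(tau.min()))
    tau_vh = float(np.interp(vh0, v, tau))
    K0 = 1.0 / (2.0 * max(tau_vh - tau0_0, 1e-6))

    r_inf = max(float(np.ptp(inf)), 1e-12)
    r_tau = max(float(np.ptp(tau)), 1e-3 * float(np.max(tau)), 1e-12)

    def model(theta):
        vh, sig, logK, delta, tau0 = theta
        gp = GatingParams(vh, sig, math.exp(logK), delta, tau0)
        return steady_state(gp, v), time_constant(gp, v)

    def resid_joint(theta):
        m_inf, m_tau = model(theta)
        return np.concatenate(
            [(m_inf - inf) / r_inf, (m_tau - tau) / r_tau]
        )

    if increasing:
        sig_lo, sig_hi = 1e-2, np.inf
    else:
        sig_lo, sig_hi = -np.inf, -1e-2
    bounds = (
        [-np.inf, sig_lo, -30.0, 1e-3, 0.0],
        [np.inf, sig_hi, 30.0, 1.0 - 1e-3, np.inf],
    )
    x0 = [vh0, sig0, math.log(max(K0, 1e-12)), 0.5, tau0_0]
    x0 = np.clip(x0, bounds[0], bounds[1])
    stage1 = least_squares(
        resid_joint, x0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=10_000,
    )

    # stage 2: refit (v_half, sigma) on the steady state alone, freezing
    # the time-constant shape (K, delta, tau_0)
    vh1, sig1, logK1, delta1, tau01 = stage1.x

    def resid_inf(theta2):
        vh, sig = theta2
        gp = GatingParams(vh, sig, math.exp(logK1), delta1, tau01)
        return (steady_state(gp, v) - inf) / r_inf

    stage2 = least_squares(
        resid_inf, [vh1, sig1], bounds=([-np.inf, sig_lo], [np.inf, sig_hi]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
    )
    vh2, sig2 = stage2.x
    gp = GatingParams(float(vh2), float(sig2), math.exp(logK1), float(delta1),
                      float(tau01))
    inf_rmse = float(np.sqrt(np.mean((steady_state(gp, v) - inf) ** 2)))
    tau_rmse = float(np.sqrt(np.mean((time_constant(gp, v) - tau) ** 2)))
    return StandardizedGate(gp, inf_rmse, tau_rmse, warnings)


def fit_standard(curves: KineticCurves) -> dict[str, StandardizedGate]:
    """Two-stage fit of the 5-parameter form to each state's curves.

    Stage 1 jointly fits the steady-state and time-constant curves
    (residuals normalized by each curve's range); stage 2 refits
    (v_half, sigma) against the steady state alone, trading
    time-constant accuracy for preserved voltage dynamics.
    """
    return {
        s: _fit_gate(curves.v, curves.inf[s], curves.tau[s])
        for s in curves.inf
    }


def standardize(spec: ChannelSpec, grid: np.ndarray | None = None) -> StandardChannel:
    """Full pipeline: evaluate curves at the definition temperature and fit."""
    curves = evaluate_kinetics(spec, grid=grid)
    fits = fit_standard(curves)
    return StandardChannel(
        name=f"std{spec.name}",
        ion=spec.ion,
        gbar=spec.gbar,
        E=spec.reversal(),
        states=list(spec.states),
        params={s: f.params for s, f in fits.items()},
        gbar_name=spec.gbar_name,
    )


# ---------------------------------------------------------------------------
# Standardized MOD rendering
# ---------------------------------------------------------------------------

def render_standard_mod(chan: StandardChannel) -> str:
    """Render a standardized channel as NMODL source.

    The output re-parses with :func:`parse_mod` and reproduces the
    closed-form kinetics exactly; each state contributes exactly five
    parameters (v_half, sigma, k, delta, tau_0).
    """
    states = chan.state_names
    ion = chan.ion
    if ion:
        current = f"i{ion}"
        use_ion = f"    USEION {ion} READ e{ion} WRITE i{ion}\n"
        e_sym = f"e{ion}"
        e_param = ""
        e_assigned = f"    {e_sym} (mV)\n"
    else:
        current = "i"
        use_ion = f"    NONSPECIFIC_CURRENT i\n"
        e_sym = "e"
        e_param = f"    e = {chan.E:g} (mV)\n"
        e_assigned = ""

    param_lines = [f"    {chan.gbar_name} = {chan.gbar:g} (S/cm2)"]
    for s in states:
        gp = chan.params[s]
        param_lines += [
            f"    v_half_{s} = {gp.v_half:.12g} (mV)",
            f"    sigma_{s} = {gp.sigma:.12g} (mV)",
            f"    k_{s} = {gp.K:.12g} (/ms)",
            f"    delta_{s} = {gp.delta:.12g}",
            f"    tau_0_{s} = {gp.tau_0:.12g} (ms)",
        ]

    p_term = "".join(
        f"*{s}^{p}" if p > 1 else f"*{s}" for s, p in chan.states
    )

    lines = [
        f"TITLE standardized ion channel {chan.name}",
        "",
        "NEURON {",
        f"    SUFFIX {chan.name}",
        use_ion.rstrip("\n"),
        f"    RANGE {chan.gbar_name}, {current}",
        "}",
        "",
        "UNITS {",
        "    (mV) = (millivolt)",
        "    (mA) = (milliamp)",
        "    (S) = (siemens)",
        "}",
        "",
        "PARAMETER {",
        *param_lines,
        e_param.rstrip("\n") if e_param else None,
        "}",
        "",
    ]
    lines = [l for l in lines if l is not None]

    if states:
        lines += [
            "STATE { " + " ".join(states) + " }",
            "",
        ]
    assigned = ["    v (mV)", f"    {current} (mA/cm2)"]
    if e_assigned:
        assigned.append(e_assigned.rstrip("\n"))
    for s in states:
        assigned += [f"    inf_{s}", f"    tau_{s} (ms)"]
    lines += ["ASSIGNED {", *assigned, "}", ""]

    lines += ["BREAKPOINT {"]
    if states:
        lines.append("    SOLVE states METHOD cnexp")
    lines.append(f"    {current} = {chan.gbar_name}{p_term}*(v - {e_sym})")
    lines += ["}", ""]

    if states:
        lines += ["INITIAL {", "    rates(v)"]
        lines += [f"    {s} = inf_{s}" for s in states]
        lines += ["}", ""]
        lines += ["DERIVATIVE states {", "    rates(v)"]
        lines += [f"    {s}' = (inf_{s} - {s})/tau_{s}" for s in states]
        lines += ["}", ""]
        rates = ["PROCEDURE rates(v (mV)) {"]
        rates.append(
            "    LOCAL " + ", ".join(
                t for s in states for t in (f"alpha_{s}", f"beta_{s}")
            )
        )
        for s in states:
            rates += [
                f"    alpha_{s} = k_{s}*exp(delta_{s}*(v - v_half_{s})/sigma_{s})",
                f"    beta_{s} = k_{s}*exp(-(1 - delta_{s})*(v - v_half_{s})/sigma_{s})",
                f"    inf_{s} = 1/(1 + exp(-(v - v_half_{s})/sigma_{s}))",
                f"    tau_{s} = 1/(alpha_{s} + beta_{s}) + tau_0_{s}",
            ]
        rates.append("}")
        lines += rates
    return "\n".join(lines) + "\n"
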
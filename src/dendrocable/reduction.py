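"""Impedance-preserving morphology reduction.

A selected inclusive subtree (a section plus all its descendants) is
replaced by the unique sealed-end cylinder with the same passive
membrane properties that preserves two impedances at a chosen angular
frequency: the input impedance |Z00| at the subtree's proximal end
(disconnected from the rest of the cell) and the transfer impedance
|Z0L| from the electrotonically most distal tip to that end.  Channel
densities are then remapped by averaging original segment values into
reduced segments at matching relative electrotonic position, and the
resulting spatial profiles are refit with analytic distribution
functions (fewest coefficients within an MSE tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .distributions import DistributionFunction, evaluate_distribution
from .morphology import (
    PointNode,
    PointTree,
    Section,
    SectionTree,
    SegmentTree,
    build_segments,
    split_to_sections,
)

__all__ = [
    "PassiveProps",
    "ImpedancePair",
    "EquivalentCylinder",
    "ReductionMap",
    "ReducedModel",
    "subtree_impedances",
    "equivalent_cylinder",
    "reduce_subtree",
    "reduce_all_stems",
    "map_channel_values",
    "fit_reduced_distribution",
]


@dataclass
class PassiveProps:
    """Uniform passive cable properties."""

    Rm: float  # Ω·cm²
    Cm: float = 1.0   # µF/cm²
    Ra: float = 150.0  # Ω·cm

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return self.Rm * self.Cm * 1e-3


@dataclass
class ImpedancePair:
    """|Z00| (input, proximal end) and |Z0L| (transfer, tip→end) in MΩ."""

    Z00: float
    Z0L: float
    omega: float = 0.0  # rad/ms

    def __post_init__(self) -> None:
        if self.Z0L > self.Z00 * (1 + 1e-12):
            raise ValueError("|Z0L| cannot exceed |Z00|")


@dataclass
class EquivalentCylinder:
    diam: float   # µm
    length: float  # µm
    Rm: float
    Cm: float
    Ra: float


@dataclass
class ReductionMap:
    """Original→reduced segment correspondence.

    ``coordinate`` maps each original (subtree) segment index to its
    relative electrotonic position in [0, 1]; ``bins`` lists, per
    reduced segment, the contributing original segment indices.
    """

    coordinate: dict[int, float] = field(default_factory=dict)
    bins: list[list[int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cable algebra
# ---------------------------------------------------------------------------

def _cable_constants(diam_um: float, p: PassiveProps, omega: float):
    """(characteristic impedance Ω, complex electrotonic length per µm)."""
    if diam_um <= 0:
        raise ValueError("zero-diameter section in impedance computation")
    d = diam_um * 1e-4  # cm
    lam = math.sqrt(p.Rm * d / (4.0 * p.Ra))  # cm, DC space constant
    r_inf = (2.0 / math.pi) * math.sqrt(p.Rm * p.Ra) * d ** -1.5  # Ω
    q = np.sqrt(1.0 + 1j * omega * p.tau_m)  # omega in rad/ms, tau in ms
    z_c = r_inf / q
    per_um = q / (lam * 1e4)  # complex electrotonic length per µm
    return z_c, per_um


def _sec_mean_diam(sec: Section) -> float:
    arcs, radii = sec._arc, sec._radii
    if arcs[-1] == 0:
        return float(2 * radii[0])
    mids = 0.5 * (radii[:-1] + radii[1:])
    return float(2 * np.sum(mids * np.diff(arcs)) / arcs[-1])


def _zin_section(z_c, lhat, z_load):
    """Input impedance of a cable with distal load (∞ = sealed)."""
    th = np.tanh(lhat)
    if z_load is None or np.isinf(z_load):
        return z_c / th
    return z_c * (z_load + z_c * th) / (z_c + z_load * th)


def _attenuation(z_c, lhat, z_load):
    """V(distal)/V(proximal) for a cable with distal load."""
    if z_load is None or np.isinf(z_load):
        return 1.0 / np.cosh(lhat)
    return 1.0 / (np.cosh(lhat) + (z_c / z_load) * np.sinh(lhat))


def subtree_impedances(
    sectree: SectionTree,
    root_section: int,
    passives: PassiveProps,
    omega: float = 0.0,
) -> ImpedancePair:
    """Impedances of an inclusive subtree with sealed terminals.

    Composed leaf→root recursively; the transfer path runs to the
    electrotonically most distal tip (maximal attenuation; first in
    tree order on ties).
    """
    secs = sectree.sections

    zin_cache: dict[int, complex] = {}
    load_cache: dict[int, complex | None] = {}

    def zin(si: int) -> complex:
        if si in zin_cache:
            return zin_cache[si]
        sec = secs[si]
        kids = sec.children
        if kids:
            y = sum(1.0 / zin(k) for k in kids)
            z_load = 1.0 / y
        else:
            z_load = None  # sealed
        load_cache[si] = z_load
        z_c, per_um = _cable_constants(_sec_mean_diam(sec), passives, omega)
        lhat = per_um * sec.length
        zin_cache[si] = _zin_section(z_c, lhat, z_load)
        return zin_cache[si]

    z00 = zin(root_section)

    # most attenuated tip
    best: tuple[float, complex] | None = None
    stack: list[tuple[int, complex]] = [(root_section, 1.0 + 0j)]
    order: list[tuple[int, complex]] = []
    while stack:
        si, att = stack.pop(0)
        sec = secs[si]
        z_c, per_um = _cable_constants(_sec_mean_diam(sec), passives, omega)
        att = att * _attenuation(z_c, per_um * sec.length, load_cache[si])
        if not sec.children:
            if best is None or abs(att) < best[0] * (1 - 1e-12):
                best = (abs(att), att)
        else:
            for k in sec.children:
                order.append((k, att))
            stack = [(k, att) for k in sec.children] + stack
    assert best is not None
    z0l = z00 * best[1]
    return ImpedancePair(Z00=abs(z00) * 1e-6, Z0L=abs(z0l) * 1e-6, omega=omega)


def _cylinder_pair(d_um: float, L_um: float, p: PassiveProps, omega: float):
    z_c, per_um = _cable_constants(d_um, p, omega)
    lhat = per_um * L_um
    z00 = z_c / np.tanh(lhat)
    z0l = z00 / np.cosh(lhat)
    return abs(z00) * 1e-6, abs(z0l) * 1e-6  # MΩ


def equivalent_cylinder(
    pair: ImpedancePair, passives: PassiveProps
) -> EquivalentCylinder:
    """The sealed-end cylinder reproducing an impedance pair.

    At ω=0 the solution is closed-form; at ω>0 it initializes from the
    DC solution and refines (d, L) by least squares on the magnitudes.
    """
    z00 = pair.Z00 * 1e6  # Ω
    z0l = pair.Z0L * 1e6
    if z0l > z00:
        raise ValueError("|Z0L| > |Z00| is physically impossible")
    ratio = z00 / max(z0l, 1e-300)
    if ratio <= 1 + 1e-12:
        raise ValueError("|Z0L| == |Z00|: degenerate (zero-length) cylinder")
    lhat = math.acosh(ratio)
    r_inf = z0l * math.sinh(lhat)
    d_cm = ((2.0 / math.pi) * math.sqrt(passives.Rm * passives.Ra) / r_inf) ** (2.0 / 3.0)
    lam_cm = math.sqrt(passives.Rm * d_cm / (4.0 * passives.Ra))
    d_um = d_cm * 1e4
    L_um = lhat * lam_cm * 1e4
    if pair.omega != 0.0:
        def resid(x):
            z1, z2 = _cylinder_pair(math.exp(x[0]), math.exp(x[1]), passives, pair.omega)
            return [math.log(z1 / pair.Z00), math.log(z2 / pair.Z0L)]

        sol = least_squares(
            resid, [math.log(d_um), math.log(L_um)], xtol=1e-14, ftol=1e-14
        )
        d_um, L_um = math.exp(sol.x[0]), math.exp(sol.x[1])
    return EquivalentCylinder(
        diam=d_um, length=L_um, Rm=passives.Rm, Cm=passives.Cm, Ra=passives.Ra
    )


# ---------------------------------------------------------------------------
# Subtree replacement
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    ptree: PointTree
    sectree: SectionTree
    stree: SegmentTree
    cylinder: EquivalentCylinder
    rmap: ReductionMap
    reduced_section: int        # section index of the cylinder in the new tree
    pair: ImpedancePair


def _subtree_sections(sectree: SectionTree, root_section: int) -> list[int]:
    out, stack = [], [root_section]
    while stack:
        i = stack.pop()
        out.append(i)
        stack.extend(sectree.sections[i].children)
    return out


def _electrotonic_coordinate(
    stree: SegmentTree, subtree_secs: list[int], passives: PassiveProps
) -> dict[int, float]:
    """Per original segment: fraction of electrotonic distance along its
    maximal root→tip path (position of the center / full path length)."""
    sectree = stree.sectree
    sub = set(subtree_secs)
    root_sec = subtree_secs[0]
    # electrotonic length per section and distance from subtree root to
    # each section's proximal end
    elec_len: dict[int, float] = {}
    for si in subtree_secs:
        sec = sectree.sections[si]
        _zc, per_um = _cable_constants(_sec_mean_diam(sec), passives, 0.0)
        elec_len[si] = float(np.real(per_um)) * sec.length
    start: dict[int, float] = {root_sec: 0.0}
    stack = [root_sec]
    while stack:
        si = stack.pop()
        for k in sectree.sections[si].children:
            if k in sub:
                start[k] = start[si] + elec_len[si]
                stack.append(k)
    # max downstream electrotonic extension per section
    down: dict[int, float] = {}
    for si in sorted(subtree_secs, key=lambda s: -start[s]):
        kids = [k for k in sectree.sections[si].children if k in sub]
        down[si] = elec_len[si] + (max(down[k] for k in kids) if kids else 0.0)
    coord: dict[int, float] = {}
    for si in subtree_secs:
        total = start[si] + down[si]
        for gi in stree.section_segments[si]:
            seg = stree.segments[gi]
            pos = start[si] + seg.x * elec_len[si]
            coord[gi] = pos / total if total > 0 else 0.0
    return coord


def reduce_subtree(
    stree: SegmentTree,
    section: int,
    passives: PassiveProps,
    omega: float = 0.0,
    d_lambda: float = 0.1,
) -> ReducedModel:
    """Replace a section's inclusive subtree with its equivalent cylinder.

    The subtree is disconnected, its impedance pair computed, the
    exclusive subtree removed, and the selected section's geometry
    updated to the cylinder before reconnecting.  The reduced morphology
    is resegmented at a spatial resolution of ``d_lambda``·λ (0.1λ by
    default).  Synapses are not remapped.
    """
    sectree = stree.sectree
    sec = sectree.sections[section]
    if sec.parent is None or sec.domain == "soma":
        raise ValueError("cannot reduce the soma/root section")
    pair = subtree_impedances(sectree, section, passives, omega)
    cyl = equivalent_cylinder(pair, passives)
    coord = _electrotonic_coordinate(
        stree, _subtree_sections(sectree, section), passives
    )

    # rebuild the point tree with the subtree replaced by a 2-point cylinder
    ptree = sectree.ptree
    doomed = set()
    for si in _subtree_sections(sectree, section):
        doomed.update(sectree.sections[si].point_ids)
    first = ptree.nodes[sec.point_ids[0]]
    anchor = ptree.nodes[first.parent]
    direction = first.coords() - anchor.coords()
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    new_nodes = []
    keep_map = {}
    for nd in ptree.nodes:
        if nd.idx in doomed:
            continue
        keep_map[nd.idx] = len(new_nodes)
        new_nodes.append(
            PointNode(
                len(new_nodes), nd.domain, nd.x, nd.y, nd.z, nd.radius,
                None if nd.parent is None else keep_map[nd.parent],
            )
        )
    r = cyl.diam / 2.0
    base = anchor.coords()
    p0 = base  # cylinder starts at the attachment point
    p1 = base + direction * cyl.length
    i0 = len(new_nodes)
    new_nodes.append(
        PointNode(i0, sec.domain, *p0, r, keep_map[anchor.idx])
    )
    new_nodes.append(PointNode(i0 + 1, sec.domain, *p1, r, i0))
    new_ptree = PointTree(new_nodes)
    new_sectree = split_to_sections(new_ptree)
    new_stree = build_segments(
        new_sectree, d_lambda=d_lambda, Ra=passives.Ra, cm=passives.Cm
    )
    # locate the cylinder section in the new tree
    reduced_section = new_sectree.point_section[
        new_ptree.nodes[-1].idx
    ]
    nred = len(new_stree.section_segments[reduced_section])
    bins: list[list[int]] = [[] for _ in range(nred)]
    for gi, frac in coord.items():
        b = min(int(frac * nred), nred - 1)
        bins[b].append(gi)
    return ReducedModel(
        ptree=new_ptree,
        sectree=new_sectree,
        stree=new_stree,
        cylinder=cyl,
        rmap=ReductionMap(coordinate=coord, bins=bins),
        reduced_section=reduced_section,
        pair=pair,
    )


def reduce_all_stems(
    stree: SegmentTree, passives: PassiveProps, omega: float = 0.0,
    d_lambda: float = 0.1,
) -> list[ReducedModel]:
    """Reduce every branching stem (child of the soma) to one cylinder.

    Returns the successive intermediate models; the last one is the
    fully reduced, ball-and-stick-like morphology (every stem a single
    unbranched cylinder).  Stems that are already single leaf sections
    are left untouched.
    """
    models: list[ReducedModel] = []
    current = stree
    while True:
        sectree = current.sectree
        todo = [
            c
            for c in sectree.root.children
            if sectree.sections[c].domain != "soma" and sectree.sections[c].children
        ]
        if not todo:
            break
        model = reduce_subtree(current, todo[0], passives, omega, d_lambda)
        models.append(model)
        current = model.stree
    return models


def map_channel_values(
    rmap: ReductionMap, original: dict[int, float], n_reduced: int | None = None
) -> np.ndarray:
    """Average original per-segment values into reduced segments.

    Reduced segments with no contributing original segment interpolate
    linearly from their nearest populated neighbours.
    """
    n = n_reduced if n_reduced is not None else len(rmap.bins)
    vals = np.full(n, np.nan)
    for b, members in enumerate(rmap.bins[:n]):
        contributing = [original[g] for g in members if g in original]
        if contributing:
            vals[b] = float(np.mean(contributing))
    if np.all(np.isnan(vals)):
        raise ValueError("no original values map onto the reduced segments")
    filled = np.flatnonzero(~np.isnan(vals))
    vals = np.interp(np.arange(n), filled, vals[filled])
    return vals


# ---------------------------------------------------------------------------
# Distribution refitting
# ---------------------------------------------------------------------------

def _fit_step(d: np.ndarray, y: np.ndarray):
    """Best two-edge step function by exhaustive edge search."""
    order = np.argsort(d)
    d, y = d[order], y[order]
    n = len(d)
    best = None
    edges = np.concatenate([[d[0] - 1], 0.5 * (d[:-1] + d[1:]), [d[-1] + 1]])
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            inside = (d >= edges[i]) & (d <= edges[j])
            if not inside.any() or inside.all():
                v_in = float(np.mean(y[inside])) if inside.any() else 0.0
                v_out = float(np.mean(y)) if inside.all() else float(np.mean(y[~inside]))
            else:
                v_in = float(np.mean(y[inside]))
                v_out = float(np.mean(y[~inside]))
            pred = np.where(inside, v_in, v_out)
            sse = float(np.sum((y - pred) ** 2))
            if best is None or sse < best[0]:
                best = (sse, v_in, v_out, float(edges[i]), float(edges[j]))
    sse, v_in, v_out, e0, e1 = best
    return sse / n, DistributionFunction(
        "step", {"v_in": v_in, "v_out": v_out, "d_start": e0, "d_end": e1}
    )


def fit_reduced_distribution(
    distances, values, rel_tol: float = 0.05
) -> tuple[DistributionFunction, float]:
    """Best analytic distribution by MSE, complexity as tie-break.

    Candidates: constant, linear, polynomial (≤3), step, exponential,
    sigmoidal.  Among candidates within ``rel_tol`` of the best MSE (or
    within an absolute floor for exact fits), the fewest-parameter model
    wins.  Returns (distribution, MSE).
    """
    d = np.asarray(distances, float)
    y = np.asarray(values, float)
    if len(d) < 2:
        raise ValueError("need at least two points")
    scale = max(float(np.ptp(y)), abs(float(np.mean(y))), 1e-12)
    candidates: list[tuple[float, int, int, DistributionFunction]] = []

    def add(mse, nparams, fn):
        candidates.append((float(mse), nparams, len(candidates), fn))

    add(np.mean((y - y.mean()) ** 2), 1, DistributionFunction.constant(float(y.mean())))
    co = np.polyfit(d, y, 1)
    add(
        np.mean((np.polyval(co, d) - y) ** 2), 2,
        DistributionFunction("linear", {"slope": float(co[0]), "intercept": float(co[1])}),
    )
    if len(d) > 4:
        co3 = np.polyfit(d, y, 3)
        add(
            np.mean((np.polyval(co3, d) - y) ** 2), 4,
            DistributionFunction(
                "polynomial", {"coeffs": [float(c) for c in co3[::-1]]}
            ),
        )
    mse_step, fn_step = _fit_step(d, y)
    add(mse_step, 4, fn_step)

    span = max(float(np.ptp(d)), 1e-9)
    for kind, x0, nparams in (
        ("exponential", [float(np.ptp(y)) or scale, 1.0 / span, float(y.min())], 3),
        (
            "sigmoidal",
            [float(np.ptp(y)) or scale, float(np.median(d)), span / 10, float(y.min())],
            4,
        ),
    ):
        names = {"exponential": ("amplitude", "rate", "offset"),
                 "sigmoidal": ("amplitude", "d_half", "scale", "offset")}[kind]

        def resid(theta, kind=kind, names=names):
            fn = DistributionFunction(kind, dict(zip(names, theta)))
            return (evaluate_distribution(fn, d) - y) / scale

        try:
            sol = least_squares(resid, x0, max_nfev=2000)
            fn = DistributionFunction(kind, dict(zip(names, [float(v) for v in sol.x])))
            add(np.mean((evaluate_distribution(fn, d) - y) ** 2), nparams, fn)
        except Exception:
            continue

    best_mse = min(c[0] for c in candidates)
    floor = (rel_tol * scale) ** 2 * 1e-6
    admissible = [c for c in candidates if c[0] <= best_mse * (1 + rel_tol) + floor]
    admissible.sort(key=lambda c: (c[1], c[2]))
    mse, _np_, _i, fn = admissible[0]
    return fn, float(mse)
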
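"""Distance-based parameter distributions over segment groups.

Biophysical parameters (channel densities, passives) are assigned to
segments through *segment groups* — criterion-defined, possibly
overlapping selections — each carrying a *distribution function* of
path distance from the root.  Groups act as layers: for a segment in
several groups, the last (top-most) group in the configured order wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .morphology import Segment, SegmentTree

__all__ = [
    "SegmentGroup",
    "DistributionFunction",
    "BiophysConfig",
    "ParamTable",
    "select_segments",
    "evaluate_distribution",
    "apply_biophys",
    "read_biophys_json",
    "write_biophys_json",
]

FORMAT_VERSION = "1.0"


class BiophysSchemaError(ValueError):
    """Invalid biophysics configuration (with the offending JSON path)."""


@dataclass
class SegmentGroup:
    """A criterion-defined selection of segments.

    criterion is one of ``diameter`` (µm), ``absolute_distance`` (µm from
    the root) or ``relative_distance`` (fraction of the domain's maximal
    path length, per root stem), or None to select whole domains.
    """

    name: str
    domains: list[str] | None = None  # None = all domains
    criterion: str | None = None
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.criterion not in (
            None, "diameter", "absolute_distance", "relative_distance",
        ):
            raise BiophysSchemaError(f"unknown criterion {self.criterion!r}")
        if self.lower > self.upper:
            raise BiophysSchemaError(f"group {self.name}: bounds out of order")
        if self.criterion == "relative_distance":
            lo = max(self.lower, 0.0)
            hi = min(self.upper, 1.0)
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise BiophysSchemaError(
                    f"group {self.name}: relative bounds must lie in [0, 1]"
                )


def select_segments(group: SegmentGroup, stree: SegmentTree) -> list[Segment]:
    """Segments in the group's domains whose criterion value is in bounds."""
    tree_domains = {seg.domain for seg in stree}
    if group.domains is not None:
        unknown = set(group.domains) - tree_domains
        if unknown:
            raise ValueError(f"group {group.name}: unknown domain(s) {sorted(unknown)}")
    out = []
    for seg in stree:
        if group.domains is not None and seg.domain not in group.domains:
            continue
        if group.criterion is None:
            out.append(seg)
            continue
        if group.criterion == "diameter":
            val = seg.diam
        elif group.criterion == "absolute_distance":
            val = stree.path_distance(seg)
        else:  # relative_distance
            val = stree.relative_distance(seg)
        if group.lower <= val <= group.upper:
            out.append(seg)
    return out


_DIST_COEFFS = {
    "constant": ("value",),
    "linear": ("slope", "intercept"),
    "exponential": ("amplitude", "rate", "offset"),       # a*exp(b*d)+c
    "sigmoidal": ("amplitude", "d_half", "scale", "offset"),
    "polynomial": ("coeffs",),                             # a0 + a1 d + ...
    "step": ("v_in", "v_out", "d_start", "d_end"),
}


@dataclass
class DistributionFunction:
    """Analytic parameter value as a function of path distance (µm)."""

    kind: str
    coeffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _DIST_COEFFS:
            raise BiophysSchemaError(f"unknown distribution kind {self.kind!r}")
        missing = set(_DIST_COEFFS[self.kind]) - set(self.coeffs)
        if missing:
            raise BiophysSchemaError(
                f"{self.kind} distribution missing coefficients {sorted(missing)}"
            )

    def __call__(self, distance):
        return evaluate_distribution(self, distance)

    @classmethod
    def constant(cls, value: float) -> "DistributionFunction":
        return cls("constant", {"value": value})


def evaluate_distribution(fn: DistributionFunction, distance):
    """Evaluate a distribution function at a path distance (µm)."""
    d = np.asarray(distance, dtype=float)
    c = fn.coeffs
    if fn.kind == "constant":
        out = np.full_like(d, float(c["value"]))
    elif fn.kind == "linear":
        out = c["slope"] * d + c["intercept"]
    elif fn.kind == "exponential":
        out = c["amplitude"] * np.exp(c["rate"] * d) + c["offset"]
    elif fn.kind == "sigmoidal":
        with np.errstate(over="ignore"):  # saturates cleanly at 0/amplitude
            out = (
                c["amplitude"] / (1.0 + np.exp(-(d - c["d_half"]) / c["scale"]))
                + c["offset"]
            )
    elif fn.kind == "polynomial":
        out = np.polyval(list(reversed(list(c["coeffs"]))), d)
    elif fn.kind == "step":
        inside = (d >= c["d_start"]) & (d <= c["d_end"])
        out = np.where(inside, c["v_in"], c["v_out"])
    else:  # pragma: no cover - guarded in __post_init__
        raise BiophysSchemaError(f"unknown distribution kind {fn.kind!r}")
    return float(out) if np.ndim(distance) == 0 else out


@dataclass
class BiophysConfig:
    """Domains, groups, and per-parameter distribution layers.

    ``parameters`` maps a parameter name to ``(mechanism, {group:
    distribution})``; mechanism None marks a passive/global parameter
    active everywhere.  ``globals`` carries cm (µF/cm²), Ra (Ω·cm) and
    simulation defaults; ``reversals`` the equilibrium potentials (mV).
    """

    domains: dict[str, list[str]] = field(default_factory=dict)
    groups: list[SegmentGroup] = field(default_factory=list)
    parameters: dict[str, tuple[str | None, dict[str, DistributionFunction]]] = field(
        default_factory=dict
    )
    globals: dict[str, float] = field(
        default_factory=lambda: {"cm": 1.0, "Ra": 150.0, "v_init": -65.0}
    )
    reversals: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        group_names = {g.name for g in self.groups}
        mechs = {m for ms in self.domains.values() for m in ms}
        for pname, (mech, dists) in self.parameters.items():
            for gname in dists:
                if gname not in group_names:
                    raise BiophysSchemaError(
                        f"parameters.{pname}: undefined group {gname!r}"
                    )
            if mech is not None and mech not in mechs:
                raise BiophysSchemaError(
                    f"parameters.{pname}: mechanism {mech!r} not inserted in any domain"
                )

    def mechanism_domains(self, mech: str) -> set[str]:
        return {d for d, ms in self.domains.items() if mech in ms}


@dataclass
class ParamTable:
    """Per-segment parameter values with full provenance."""

    stree: SegmentTree
    values: dict[str, np.ndarray]
    source: dict[str, list[str | None]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pname, vals in self.values.items():
            for seg, v, src in zip(self.stree, vals, self.source[pname]):
                rows.append(
                    {
                        "section": seg.section.idx,
                        "x": seg.x,
                        "domain": seg.domain,
                        "parameter": pname,
                        "value": v,
                        "source_group": src,
                    }
                )
        return pd.DataFrame(rows)


def apply_biophys(
    cfg: BiophysConfig, stree: SegmentTree, defaults: dict[str, float] | None = None
) -> ParamTable:
    """Resolve the layered configuration to per-segment values.

    For each parameter and segment the value comes from the top-most
    (last-listed) matching group, evaluated at the segment's center path
    distance.  Mechanism-scoped parameters are active only in domains
    where the mechanism is inserted; uncovered mechanism parameters
    default to 0 (mechanism effectively absent), passives to the
    config-level globals.
    """
    cfg.validate()
    defaults = dict(defaults or {})
    n = len(stree)
    distances = np.array([stree.path_distance(s) for s in stree])
    membership: dict[str, np.ndarray] = {}
    for g in cfg.groups:
        mask = np.zeros(n, dtype=bool)
        for seg in select_segments(g, stree):
            mask[seg.idx] = True
        membership[g.name] = mask

    values: dict[str, np.ndarray] = {}
    source: dict[str, list[str | None]] = {}
    for pname, (mech, dists) in cfg.parameters.items():
        default = defaults.get(pname, cfg.globals.get(pname, 0.0))
        vals = np.full(n, float(default))
        src: list[str | None] = [None] * n
        if mech is not None:
            dom = cfg.mechanism_domains(mech)
            active = np.array([seg.domain in dom for seg in stree])
        else:
            active = np.ones(n, dtype=bool)
        for g in cfg.groups:  # later groups overwrite: last = top-most
            if g.name not in dists:
                continue
            mask = membership[g.name] & active
            if mask.any():
                vals[mask] = evaluate_distribution(dists[g.name], distances[mask])
                for i in np.flatnonzero(mask):
                    src[i] = g.name
        vals[~active] = 0.0 if mech is not None else default
        values[pname] = vals
        source[pname] = src
    return ParamTable(stree=stree, values=values, source=source)


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def _group_to_dict(g: SegmentGroup) -> dict:
    out: dict = {"name": g.name, "domains": g.domains, "criterion": g.criterion}
    if np.isfinite(g.lower):
        out["lower"] = g.lower
    if np.isfinite(g.upper):
        out["upper"] = g.upper
    return out


def write_biophys_json(cfg: BiophysConfig) -> str:
    """Serialize to the canonical (sorted, indented) JSON dialect."""
    doc = {
        "format_version": FORMAT_VERSION,
        "domains": cfg.domains,
        "globals": cfg.globals,
        "reversals": cfg.reversals,
        "groups": [_group_to_dict(g) for g in cfg.groups],
        "parameters": {
            pname: {
                "mechanism": mech,
                "distributions": {
                    gname: {"kind": fn.kind, **fn.coeffs}
                    for gname, fn in dists.items()
                },
            }
            for pname, (mech, dists) in cfg.parameters.items()
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def read_biophys_json(text: str) -> BiophysConfig:
    doc = json.loads(text)
    for key in ("domains", "groups", "parameters"):
        if key not in doc:
            raise BiophysSchemaError(f"missing top-level section {key!r} at $.{key}")
    groups = []
    for i, g in enumerate(doc["groups"]):
        try:
            groups.append(
                SegmentGroup(
                    name=g["name"],
                    domains=g.get("domains"),
                    criterion=g.get("criterion"),
                    lower=g.get("lower", -np.inf),
                    upper=g.get("upper", np.inf),
                )
            )
        except KeyError as exc:
            raise BiophysSchemaError(f"$.groups[{i}]: missing {exc}") from exc
    parameters = {}
    for pname, pdoc in doc["parameters"].items():
        dists = {}
        for gname, ddoc in pdoc.get("distributions", {}).items():
            ddoc = dict(ddoc)
            kind = ddoc.pop("kind", None)
            if kind is None:
                raise BiophysSchemaError(
                    f"$.parameters.{pname}.distributions.{gname}: missing kind"
                )
            try:
                dists[gname] = DistributionFunction(kind, ddoc)
            except BiophysSchemaError as exc:
                raise BiophysSchemaError(
                    f"$.parameters.{pname}.distributions.{gname}: {exc}"
                ) from exc
        parameters[pname] = (pdoc.get("mechanism"), dists)
    cfg = BiophysConfig(
        domains=doc["domains"],
        groups=groups,
        parameters=parameters,
        globals=doc.get("globals", {"cm": 1.0, "Ra": 150.0, "v_init": -65.0}),
        reversals=doc.get("reversals", {}),
    )
    cfg.validate()
    return cfg
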
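"""Reader and parser for a subset of the NMODL mechanism language.

Supported: HH-style voltage-gated and leak density mechanisms — the
NEURON, UNITS, PARAMETER, ASSIGNED, STATE, BREAKPOINT, INITIAL,
DERIVATIVE, PROCEDURE and FUNCTION blocks, with plain assignment
statements and first-order state equations ``x' = ...``.

Deliberately unsupported (raise :class:`UnsupportedConstructError`):
VERBATIM blocks, KINETIC (Markov) schemes, conditionals, pointers and
net-event handling.  Channels outside the subset must be preprocessed
by hand before conversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["ModAST", "parse_mod", "ModParseError", "UnsupportedConstructError"]


class ModParseError(ValueError):
    pass


class UnsupportedConstructError(ModParseError):
    pass


_UNSUPPORTED_BLOCKS = (
    "VERBATIM",
    "KINETIC",
    "NET_RECEIVE",
    "LINEAR",
    "NONLINEAR",
    "DISCRETE",
)


@dataclass
class Assignment:
    lhs: str
    rhs: str
    is_derivative: bool = False  # lhs was written x'


@dataclass
class ProcedureDef:
    name: str
    args: list[str]
    locals: list[str]
    statements: list[Assignment]
    calls: list[str] = field(default_factory=list)


@dataclass
class ModAST:
    """Per-block parse results of one MOD file."""

    title: str | None = None
    suffix: str | None = None
    ions: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    nonspecific: list[str] = field(default_factory=list)
    range_vars: list[str] = field(default_factory=list)
    global_vars: list[str] = field(default_factory=list)
    parameters: dict[str, tuple[float | None, str | None]] = field(default_factory=dict)
    assigned: dict[str, str | None] = field(default_factory=dict)
    states: list[str] = field(default_factory=list)
    solve: tuple[str, str] | None = None  # (block name, method)
    breakpoint: list[Assignment] = field(default_factory=list)
    breakpoint_calls: list[str] = field(default_factory=list)
    initial: list[Assignment] = field(default_factory=list)
    initial_calls: list[str] = field(default_factory=list)
    derivative: ProcedureDef | None = None
    procedures: dict[str, ProcedureDef] = field(default_factory=dict)
    functions: dict[str, ProcedureDef] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def parameter_value(self, name: str, default: float | None = None) -> float | None:
        val = self.parameters.get(name, (default, None))[0]
        return default if val is None else val


# ---------------------------------------------------------------------------
# Reader: comment stripping and block splitting
# ---------------------------------------------------------------------------

def _strip_comments(text: str) -> str:
    text = re.sub(r"COMMENT.*?ENDCOMMENT", "", text, flags=re.S)
    # '?' and ':' start line comments in NMODL
    lines = []
    for line in text.splitlines():
        for marker in (":", "?"):
            pos = line.find(marker)
            if pos >= 0:
                line = line[:pos]
        lines.append(line)
    return "\n".join(lines)


def _split_blocks(text: str) -> list[tuple[str, str, str]]:
    """Yield (keyword, header remainder, body) for each braced block."""
    blocks = []
    i, n = 0, len(text)
    while i < n:
        brace = text.find("{", i)
        if brace < 0:
            break
        header = text[i:brace].strip()
        depth = 1
        j = brace + 1
        while j < n and depth:
            if text[j] == "{":
                depth += 1
            elif text[j] == "}":
                depth -= 1
            j += 1
        if depth:
            raise ModParseError(f"unbalanced braces after {header!r}")
        body = text[brace + 1 : j - 1]
        parts = header.split(None, 1)
        keyword = parts[0] if parts else ""
        rest = parts[1] if len(parts) > 1 else ""
        blocks.append((keyword, rest, body))
        i = j
    return blocks


_IDENT = r"[A-Za-z_]\w*"


def _parse_statements(body: str, where: str) -> tuple[list[Assignment], list[str], list[str]]:
    """Parse assignment statements, procedure calls and LOCAL decls."""
    statements: list[Assignment] = []
    calls: list[str] = []
    locals_: list[str] = []
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("~"):
            raise UnsupportedConstructError(
                f"kinetic scheme statement in {where}: {line!r}"
            )
        if re.match(r"(?i)^(IF|ELSE|WHILE|FOR)\b", line) or line in ("{", "}"):
            raise UnsupportedConstructError(
                f"control flow in {where} is outside the supported subset: {line!r}"
            )
        if re.match(r"(?i)^LOCAL\b", line):
            locals_.extend(s.strip() for s in line[5:].split(","))
            continue
        if re.match(r"(?i)^(TABLE|UNITSOFF|UNITSON)\b", line):
            continue
        m = re.match(rf"(?i)^SOLVE\s+({_IDENT})(?:\s+METHOD\s+({_IDENT}))?$", line)
        if m:
            statements.append(Assignment("SOLVE", m.group(2) or "cnexp"))
            calls.append(f"SOLVE {m.group(1)}")
            continue
        m = re.match(rf"^({_IDENT})'\s*=\s*(.+)$", line)
        if m:
            statements.append(Assignment(m.group(1), m.group(2).strip(), True))
            continue
        m = re.match(rf"^({_IDENT})\s*=\s*(.+)$", line)
        if m:
            rhs = m.group(2).strip()
            if rhs.startswith("="):
                raise ModParseError(f"cannot parse statement in {where}: {line!r}")
            statements.append(Assignment(m.group(1), rhs))
            continue
        m = re.match(rf"^({_IDENT})\s*\(([^)]*)\)$", line)
        if m:
            calls.append(line)
            continue
        raise ModParseError(f"cannot parse statement in {where}: {line!r}")
    return statements, calls, locals_


def _parse_neuron_block(body: str, ast: ModAST) -> None:
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        kw = line.split()[0].upper()
        if kw == "SUFFIX" or kw == "POINT_PROCESS":
            ast.suffix = line.split()[1]
        elif kw == "USEION":
            m = re.match(
                rf"(?i)USEION\s+({_IDENT})"
                rf"(?:\s+READ\s+([\w\s,]+?))?(?:\s+WRITE\s+([\w\s,]+?))?"
                rf"(?:\s+VALENCE\s+[-\d]+)?$",
                line,
            )
            if not m:
                raise ModParseError(f"cannot parse USEION line: {line!r}")
            ion = m.group(1)
            reads = [s.strip() for s in (m.group(2) or "").split(",") if s.strip()]
            writes = [s.strip() for s in (m.group(3) or "").split(",") if s.strip()]
            ast.ions[ion] = {"read": reads, "write": writes}
        elif kw == "NONSPECIFIC_CURRENT":
            ast.nonspecific.extend(
                s.strip() for s in line.split(None, 1)[1].split(",")
            )
        elif kw == "RANGE":
            ast.range_vars.extend(s.strip() for s in line.split(None, 1)[1].split(","))
        elif kw == "GLOBAL":
            ast.global_vars.extend(s.strip() for s in line.split(None, 1)[1].split(","))
        elif kw in ("THREADSAFE", "ELECTRODE_CURRENT"):
            continue
        elif kw == "POINTER":
            raise UnsupportedConstructError("POINTER variables are unsupported")
        else:
            raise ModParseError(f"unknown NEURON block statement: {line!r}")


_PARAM_RE = re.compile(
    rf"^({_IDENT})\s*(?:=\s*([-+0-9.eE]+))?\s*(?:\(([^)]*)\))?\s*(?:<[^>]*>)?$"
)


def _parse_parameter_block(body: str, ast: ModAST) -> None:
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _PARAM_RE.match(line)
        if not m:
            raise ModParseError(f"cannot parse PARAMETER line: {line!r}")
        value = float(m.group(2)) if m.group(2) is not None else None
        ast.parameters[m.group(1)] = (value, m.group(3))


def _parse_assigned_block(body: str, ast: ModAST) -> None:
    for raw in body.splitlines():
        line = raw.strip()
        if not line:
            continue
        m = re.match(rf"^({_IDENT})\s*(?:\(([^)]*)\))?$", line)
        if not m:
            raise ModParseError(f"cannot parse ASSIGNED line: {line!r}")
        ast.assigned[m.group(1)] = m.group(2)


def parse_mod(text: str) -> ModAST:
    """Parse NMODL source (supported subset) into a :class:`ModAST`."""
    text = _strip_comments(text)
    for kw in _UNSUPPORTED_BLOCKS:
        if re.search(rf"\b{kw}\b", text):
            raise UnsupportedConstructError(
                f"{kw} blocks are outside the supported NMODL subset"
            )
    ast = ModAST()
    m = re.search(r"^\s*TITLE\s+(.*)$", text, flags=re.M)
    if m:
        ast.title = m.group(1).strip()
        text = text.replace(m.group(0), "")
    # drop stray non-block lines (INDEPENDENT etc. would appear as headers)
    for keyword, rest, body in _split_blocks(text):
        kw = keyword.upper()
        if kw == "NEURON":
            _parse_neuron_block(body, ast)
        elif kw == "UNITS":
            for raw in body.splitlines():
                line = raw.strip()
                if line:
                    ast.units[line.split("=")[0].strip()] = line
        elif kw == "PARAMETER":
            _parse_parameter_block(body, ast)
        elif kw == "ASSIGNED":
            _parse_assigned_block(body, ast)
        elif kw == "STATE":
            for raw in re.split(r"[\s,]+", body.strip()):
                if raw:
                    m2 = re.match(rf"^({_IDENT})$", raw)
                    if not m2:
                        raise ModParseError(f"cannot parse STATE entry: {raw!r}")
                    ast.states.append(raw)
        elif kw == "BREAKPOINT":
            stmts, calls, _ = _parse_statements(body, "BREAKPOINT")
            for st in stmts:
                if st.lhs == "SOLVE":
                    continue
                ast.breakpoint.append(st)
            for c in calls:
                if c.startswith("SOLVE "):
                    ast.solve = (c.split()[1], "cnexp")
                else:
                    ast.breakpoint_calls.append(c)
        elif kw == "INITIAL":
            stmts, calls, _ = _parse_statements(body, "INITIAL")
            ast.initial = [s for s in stmts if s.lhs != "SOLVE"]
            ast.initial_calls = calls
        elif kw == "DERIVATIVE":
            stmts, calls, locs = _parse_statements(body, f"DERIVATIVE {rest}")
            ast.derivative = ProcedureDef(rest.strip(), [], locs, stmts, calls)
        elif kw in ("PROCEDURE", "FUNCTION"):
            m2 = re.match(rf"^({_IDENT})\s*\(([^)]*)\)", rest)
            if not m2:
                raise ModParseError(f"cannot parse {kw} header: {rest!r}")
            args = []
            for a in m2.group(2).split(","):
                a = a.strip()
                if a:
                    args.append(a.split("(")[0].strip())
            stmts, calls, locs = _parse_statements(body, f"{kw} {m2.group(1)}")
            pd = ProcedureDef(m2.group(1), args, locs, stmts, calls)
            if kw == "PROCEDURE":
                ast.procedures[pd.name] = pd
            else:
                ast.functions[pd.name] = pd
        elif kw in ("INDEPENDENT", "CONSTANT"):
            continue
        else:
            raise ModParseError(f"unknown block {keyword!r}")
    if ast.suffix is None:
        raise ModParseError("missing NEURON block with SUFFIX")
    for s in ast.states:
        has_ode = ast.derivative is not None and any(
            st.is_derivative and st.lhs == s for st in ast.derivative.statements
        )
        if not has_ode:
            raise ModParseError(f"state {s!r} has no derivative equation")
    return ast
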
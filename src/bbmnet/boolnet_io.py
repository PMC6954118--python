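"""Readers and writers for the BoolNet text format and companion CSVs.

The model file uses the BoolNet "targets, factors" convention with the
operator alphabet ``& | !`` plus the constants ``0``/``1``; every
composite sub-expression is parenthesised explicitly so any loader
agrees on the parse.  Companion files: a two-column symbol map
(``symbol,name``), an initial-values table (``symbol,value``), and
trajectory tables with one row per target and one column per time step.
"""

from __future__ import annotations

import csv
import io
import re
from pathlib import Path
from typing import Optional, TextIO, Union

from .compiler import BipartiteBooleanModel, Target
from .engine import SimulationResult, StateVector
from .expr import And, BoolExpr, FALSE, Not, Or, Ref, TRUE

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Expression rendering / parsing
# ---------------------------------------------------------------------------

def render_expr(e: BoolExpr) -> str:
    if e == TRUE:
        return "1"
    if e == FALSE:
        return "0"
    if isinstance(e, Ref):
        return e.name
    if isinstance(e, Not):
        inner = render_expr(e.child)
        if isinstance(e.child, Ref):
            return f"!{inner}"
        return f"!({inner})"
    if isinstance(e, And):
        return "(" + " & ".join(render_expr(c) for c in e.children) + ")"
    if isinstance(e, Or):
        return "(" + " | ".join(render_expr(c) for c in e.children) + ")"
    raise ValueError(f"cannot render {e!r}")


class BoolnetParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)
        self.line = line


_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[01()&|!])")


def parse_expr(text: str, line: Optional[int] = None) -> BoolExpr:
    """Recursive-descent parser for the ``& | !`` dialect
    (precedence ! > & > |)."""
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise BoolnetParseError(
                    f"bad token at {text[pos:].strip()[:10]!r}", line)
            break
        tokens.append(m.group(1))
        pos = m.end()
    i = 0

    def peek() -> Optional[str]:
        return tokens[i] if i < len(tokens) else None

    def take() -> str:
        nonlocal i
        tok = tokens[i]
        i += 1
        return tok

    def atom() -> BoolExpr:
        tok = peek()
        if tok is None:
            raise BoolnetParseError("unexpected end of expression", line)
        if tok == "(":
            take()
            e = disjunction()
            if peek() != ")":
                raise BoolnetParseError("missing ')'", line)
            take()
            return e
        if tok == "!":
            take()
            child = atom()
            if child == TRUE:
                return FALSE
            if child == FALSE:
                return TRUE
            return Not(child)
        if tok == "1":
            take()
            return TRUE
        if tok == "0":
            take()
            return FALSE
        if re.match(r"^[A-Za-z_]", tok):
            take()
            return Ref(tok)
        raise BoolnetParseError(f"unexpected token {tok!r}", line)

    def conjunction() -> BoolExpr:
        parts = [atom()]
        while peek() == "&":
            take()
            parts.append(atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def disjunction() -> BoolExpr:
        parts = [conjunction()]
        while peek() == "|":
            take()
            parts.append(conjunction())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    e = disjunction()
    if i != len(tokens):
        raise BoolnetParseError(f"trailing tokens {tokens[i:]!r}", line)
    return e


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def boolnet_text(model: BipartiteBooleanModel) -> str:
    lines = ["targets, factors"]
    for t in model.targets:
        lines.append(f"{t.symbol}, {render_expr(model.rules[t.symbol])}")
    return "\n".join(lines) + "\n"


def write_boolnet(model: BipartiteBooleanModel, destination: PathLike) -> str:
    text = boolnet_text(model)
    Path(destination).write_text(text, newline="\n")
    return text


def write_symbols(model: BipartiteBooleanModel, destination: PathLike) -> None:
    """Two-column bijective map between model symbols and original names."""
    with open(destination, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["symbol", "name"])
        for t in model.targets:
            w.writerow([t.symbol, t.name])


def read_symbols(source: PathLike) -> dict[str, str]:
    with open(source, newline="") as fh:
        rows = list(csv.reader(fh))
    return {sym: name for sym, name in rows[1:]}


def write_initial_values(values: dict[str, bool], destination: PathLike) -> None:
    with open(destination, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["symbol", "value"])
        for sym, val in values.items():
            w.writerow([sym, int(val)])


def read_initial_values(source: PathLike) -> dict[str, bool]:
    with open(source, newline="") as fh:
        rows = list(csv.reader(fh))
    return {sym: bool(int(val)) for sym, val in rows[1:]}


def write_trajectory(model: BipartiteBooleanModel,
                     result: SimulationResult,
                     destination: PathLike) -> None:
    """Trajectory table: first column the target symbol, one column per
    time step with 0/1 values (time runs across columns, mirroring a
    heatmap layout)."""
    with open(destination, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["target"] + [f"t{t}" for t in range(len(result.trajectory))])
        for i, target in enumerate(model.targets):
            w.writerow([target.symbol]
                       + [int(v[i]) for v in result.trajectory])


def write_attractor(model: BipartiteBooleanModel,
                    result: SimulationResult,
                    destination: PathLike) -> None:
    """Export the attractor's first state as a new initial-values file."""
    first = result.attractor[0]
    values = {t.symbol: first[i] for i, t in enumerate(model.targets)}
    write_initial_values(values, destination)


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

def read_boolnet(source: Union[PathLike, TextIO, str]) -> BipartiteBooleanModel:
    """Load a BoolNet document back into a model.

    Target kinds are not recorded in the format: identity self-updates
    are read back as inputs, everything else as states.  Writing the
    returned model reproduces the document up to whitespace.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        p = Path(str(source))
        text = p.read_text() if "\n" not in str(source) and p.exists() else str(source)
    lines = text.splitlines()
    if not lines:
        raise BoolnetParseError("empty document")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["targets", "factors"]:
        raise BoolnetParseError("missing 'targets, factors' header", 1)
    targets: list[Target] = []
    rules: dict[str, BoolExpr] = {}
    for line_no, raw in enumerate(lines[1:], start=2):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise BoolnetParseError("expected 'symbol, expression'", line_no)
        sym, expr_text = line.split(",", 1)
        sym = sym.strip()
        if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", sym):
            raise BoolnetParseError(f"bad target symbol {sym!r}", line_no)
        if sym in rules:
            raise BoolnetParseError(f"duplicate target {sym!r}", line_no)
        expr = parse_expr(expr_text, line_no)
        kind = "input" if expr == Ref(sym) else "state"
        targets.append(Target(kind, sym, sym))
        rules[sym] = expr
    known = set(rules)
    for sym, expr in rules.items():
        for ref in expr.refs():
            if ref not in known:
                raise BoolnetParseError(
                    f"rule for {sym!r} references unknown target {ref!r}")
    model = BipartiteBooleanModel(
        targets=targets,
        rules=rules,
        initial={t.symbol: False for t in targets},
        symbol_of={t.symbol: t.symbol for t in targets},
    )
    return model
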
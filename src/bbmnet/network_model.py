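"""Reaction-contingency network model and plain-text dialect parser.

A network is described by elemental states (site-resolved observables:
a modification at a residue, a bond at a domain, their neutral
complements, a bare component, or an external input), elemental
reactions (decontextualised reaction events classified by how they act
on each state: synthesis, degradation, production or consumption), and
contingencies (Boolean constraints of states/inputs on reactions).

The plain-text model dialect holds two mandatory tables plus an
optional output-link table::

    [reactions]
    id, type, subject, object, effects
    r1, p+, Kin, A_[(r)]

    [contingencies]
    target, type, effector
    r1, !, [Stimulus]

    [outputs]
    input, effector

State-name grammar: ``A_[(r)]-{P}`` (modification at residue r, tag
``{0}`` is the neutral form), ``A_[d]--B_[e]`` (bond between domains),
``A_[d]--0`` (empty binding domain), bare ``A`` (generic component),
``[Name]`` (input).  Boolean effector nodes are declared in the
contingency table as ``<name>, AND|OR|NOT, member;member``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .expr import And, BoolExpr, FALSE, Not, Or, Ref, TRUE, and_all, not_, or_all


class NetworkError(Exception):
    """Base class for model-document and network errors."""


class ParseError(NetworkError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class ValidationError(NetworkError):
    pass


# ---------------------------------------------------------------------------
# Elemental states
# ---------------------------------------------------------------------------

class StateVariant(enum.Enum):
    MODIFICATION = "modification"
    BOND = "bond"
    EMPTY_BINDING = "empty_binding"
    COMPONENT = "component"
    INPUT = "input"


@dataclass(frozen=True, order=True)
class Locus:
    """A (component, site) pair; ``kind`` is 'residue' or 'domain'."""

    component: str
    site: str
    kind: str


@dataclass(frozen=True)
class ElementalState:
    variant: StateVariant
    loci: tuple[Locus, ...]
    label: str  # modification tag, or "" for bonds/empties/components/inputs

    @property
    def name(self) -> str:
        if self.variant is StateVariant.MODIFICATION:
            (l,) = self.loci
            return f"{l.component}_[({l.site})]-{{{self.label}}}"
        if self.variant is StateVariant.EMPTY_BINDING:
            (l,) = self.loci
            return f"{l.component}_[{l.site}]--0"
        if self.variant is StateVariant.BOND:
            a, b = self.loci
            return f"{a.component}_[{a.site}]--{b.component}_[{b.site}]"
        if self.variant is StateVariant.COMPONENT:
            return self.loci[0].component
        return f"[{self.label}]"

    @property
    def neutral(self) -> bool:
        """True exactly for unmodified modifications and empty bindings."""
        if self.variant is StateVariant.MODIFICATION:
            return self.label == "0"
        return self.variant is StateVariant.EMPTY_BINDING

    @property
    def carriers(self) -> tuple[str, ...]:
        """Distinct carrier component names, in locus order."""
        seen: list[str] = []
        for l in self.loci:
            if l.component not in seen:
                seen.append(l.component)
        return tuple(seen)

    def __repr__(self) -> str:
        return self.name


def mod_state(component: str, residue: str, tag: str) -> ElementalState:
    return ElementalState(
        StateVariant.MODIFICATION, (Locus(component, residue, "residue"),), tag
    )


def empty_binding_state(component: str, domain: str) -> ElementalState:
    return ElementalState(
        StateVariant.EMPTY_BINDING, (Locus(component, domain, "domain"),), ""
    )


def bond_state(c1: str, d1: str, c2: str, d2: str) -> ElementalState:
    """Bond between two domains; loci are stored in sorted order so the
    name is canonical regardless of argument order.  Both loci may live
    on one component (intra-molecular bond)."""
    loci = tuple(sorted([Locus(c1, d1, "domain"), Locus(c2, d2, "domain")]))
    return ElementalState(StateVariant.BOND, loci, "")


def component_state(component: str) -> ElementalState:
    return ElementalState(StateVariant.COMPONENT, (Locus(component, "", ""),), "")


def input_state(name: str) -> ElementalState:
    return ElementalState(StateVariant.INPUT, (), name)


def neutral_counterpart(state: ElementalState):
    """Neutral complement N(S) of a non-neutral state.

    Returns one state for a modification, a pair of empty-binding
    states (one per bond locus) for a bond.  Calling this on a neutral,
    component or input state is a contract violation.
    """
    if state.neutral or state.variant in (StateVariant.COMPONENT, StateVariant.INPUT):
        raise ValueError(f"{state.name} has no neutral counterpart")
    if state.variant is StateVariant.MODIFICATION:
        (l,) = state.loci
        return mod_state(l.component, l.site, "0")
    a, b = state.loci
    return (
        empty_binding_state(a.component, a.site),
        empty_binding_state(b.component, b.site),
    )


def neutral_counterparts(state: ElementalState) -> tuple[ElementalState, ...]:
    """Like :func:`neutral_counterpart` but always a tuple."""
    n = neutral_counterpart(state)
    return n if isinstance(n, tuple) else (n,)


def mutually_exclusive(s1: ElementalState, s2: ElementalState) -> bool:
    """Two distinct states are mutually exclusive iff they share a
    (component, site) locus -- all states at one locus exclude each
    other and their neutral complements."""
    if s1 == s2:
        return False
    return bool(set(s1.loci) & set(s2.loci))


# ---------------------------------------------------------------------------
# Reactions and effects
# ---------------------------------------------------------------------------

class EffectMode(enum.Enum):
    """How a reaction acts on a state; ordered by dominance
    (synthesis > degradation > production > consumption)."""

    SYNTHESIS = 3
    DEGRADATION = 2
    PRODUCTION = 1
    CONSUMPTION = 0

    def dominates(self, other: "EffectMode") -> bool:
        return self.value > other.value


@dataclass(frozen=True)
class Effect:
    state: ElementalState
    mode: EffectMode
    # Effect-specific source states.  Consumption effects carry
    # themselves; conditional productions from degradation expansion
    # carry the degraded bond.  Synthesis/degradation have none.
    guards: frozenset[ElementalState] = frozenset()


@dataclass(frozen=True)
class ComponentPattern:
    """A component occurrence in a skeleton rule with attached states."""

    component: str
    states: frozenset[ElementalState] = frozenset()


@dataclass(frozen=True)
class SkeletonRule:
    """Context-free rewrite (centre only) underlying an elemental reaction."""

    lhs: tuple[ComponentPattern, ...]
    rhs: tuple[ComponentPattern, ...]

    def _side_states(self, side: tuple[ComponentPattern, ...]) -> set[ElementalState]:
        out: set[ElementalState] = set()
        for p in side:
            out |= p.states
        return out

    @property
    def lhs_states(self) -> set[ElementalState]:
        return self._side_states(self.lhs)

    @property
    def rhs_states(self) -> set[ElementalState]:
        return self._side_states(self.rhs)

    @property
    def components(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.lhs + self.rhs:
            if p.component not in seen:
                seen.append(p.component)
        return tuple(seen)


def classify_effects(
    rule: SkeletonRule, universe: Iterable[ElementalState] = ()
) -> list[Effect]:
    """Assign each state its effect mode from the skeleton rule.

    Modes follow the four definitions: a state is *produced* if it is on
    the RHS, not the LHS, and a carrier is on the LHS; *consumed* if on
    the LHS, not the RHS, and a carrier is on the RHS; *synthesised* if
    on the RHS with no carrier on the LHS; *degraded* if a carrier is an
    unconstrained LHS component absent from the RHS and no mutually
    exclusive state is on the LHS.  Degradation is evaluated against
    ``universe`` (all declared states), since a bare component on the
    LHS degrades every state it carries, including ones the rule does
    not mention.  A state on both sides yields no effect.
    """
    lhs_states = rule.lhs_states
    rhs_states = rule.rhs_states
    lhs_components = {p.component for p in rule.lhs}
    rhs_components = {p.component for p in rule.rhs}

    candidates: list[ElementalState] = []
    seen: set[ElementalState] = set()
    for s in list(lhs_states | rhs_states) + list(universe):
        if s not in seen and s.variant is not StateVariant.INPUT:
            seen.add(s)
            candidates.append(s)
    # Deterministic order: by name.
    candidates.sort(key=lambda s: s.name)

    effects: list[Effect] = []
    for s in candidates:
        carriers = set(s.carriers)
        on_lhs = s in lhs_states
        on_rhs = s in rhs_states
        if on_lhs and on_rhs:
            continue
        if on_rhs and carriers & lhs_components:
            effects.append(Effect(s, EffectMode.PRODUCTION))
        elif on_rhs:
            effects.append(Effect(s, EffectMode.SYNTHESIS))
        elif on_lhs and carriers & rhs_components:
            effects.append(Effect(s, EffectMode.CONSUMPTION, frozenset({s})))
        elif not on_lhs and not on_rhs:
            # Degradation sweep: carrier present bare on the LHS, absent
            # from the RHS, no mutually exclusive state on the LHS.
            degraded = any(
                c in lhs_components and c not in rhs_components for c in carriers
            ) and not any(mutually_exclusive(s, t) for t in lhs_states)
            if degraded:
                effects.append(Effect(s, EffectMode.DEGRADATION))
        elif on_lhs:
            # On LHS, carrier absent from RHS -> part of a degradation.
            if not any(mutually_exclusive(s, t) for t in lhs_states):
                effects.append(Effect(s, EffectMode.DEGRADATION))
    return effects


@dataclass(frozen=True)
class ElementalReaction:
    name: str
    reacting_components: tuple[str, ...]
    effects: tuple[Effect, ...]
    bidirectional_origin: Optional[str] = None  # "forward" | "reverse"
    clamp: Optional[bool] = None  # constant reaction target when set
    rtype: str = "explicit"
    subject: str = ""
    obj: str = ""

    def consumed_states(self) -> tuple[ElementalState, ...]:
        return tuple(
            e.state for e in self.effects if e.mode is EffectMode.CONSUMPTION
        )

    def effects_on(self, state: ElementalState, mode: EffectMode) -> tuple[Effect, ...]:
        return tuple(
            e for e in self.effects if e.state == state and e.mode is mode
        )


@dataclass(frozen=True)
class Contingency:
    target: str
    ctype: str  # one of ! x K+ K- 0 ?
    effector: BoolExpr  # leaves are state names or input names


CONTINGENCY_TYPES = ("!", "x", "K+", "K-", "0", "?")


@dataclass
class Component:
    name: str
    # site name -> ordered list of state names on that site; empty for
    # generic components (their own component state is the target).
    sites: dict[str, list[str]] = field(default_factory=dict)

    @property
    def generic(self) -> bool:
        return not self.sites


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

@dataclass
class RxnconNetwork:
    components: dict[str, Component]
    states: dict[str, ElementalState]  # insertion-ordered
    reactions: list[ElementalReaction]
    contingencies: list[Contingency]
    inputs: list[str]
    output_links: dict[str, BoolExpr] = field(default_factory=dict)

    # -- derived counts ----------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_contingencies(self) -> int:
        return len(self.contingencies)

    def reaction(self, name: str) -> ElementalReaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    def contingencies_for(self, reaction_name: str) -> list[Contingency]:
        return [c for c in self.contingencies if c.target == reaction_name]

    def states_of_component(self, component: str) -> list[ElementalState]:
        """All non-component states carried by a component, declaration order."""
        return [
            s
            for s in self.states.values()
            if component in s.carriers
            and s.variant is not StateVariant.COMPONENT
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RxnconNetwork):
            return NotImplemented
        return (
            self.states == other.states
            and [
                (r.name, r.reacting_components, frozenset(r.effects), r.clamp,
                 r.bidirectional_origin)
                for r in self.reactions
            ]
            == [
                (r.name, r.reacting_components, frozenset(r.effects), r.clamp,
                 r.bidirectional_origin)
                for r in other.reactions
            ]
            and self.contingencies == other.contingencies
            and self.inputs == other.inputs
            and self.output_links == other.output_links
        )

    # -- serialisation -----------------------------------------------------
    def to_document(self) -> str:
        """Serialise to the model-document dialect (explicit effects)."""
        lines = ["[reactions]", "id, type, subject, object, effects"]
        mode_word = {
            EffectMode.SYNTHESIS: "synthesise",
            EffectMode.DEGRADATION: "degrade",
            EffectMode.PRODUCTION: "produce",
            EffectMode.CONSUMPTION: "consume",
        }
        for r in self.reactions:
            toks = []
            for e in sorted(r.effects, key=lambda e: (e.mode.value, e.state.name)):
                t = f"{mode_word[e.mode]}:{e.state.name}"
                extra = sorted(g.name for g in e.guards if g != e.state)
                if extra:
                    t += "@" + "&".join(extra)
                toks.append(t)
            if r.clamp is not None:
                toks.append(f"clamp:{int(r.clamp)}")
            if r.bidirectional_origin:
                toks.append(f"origin:{r.bidirectional_origin}")
            subject = ";".join(r.reacting_components)
            lines.append(f"{r.name}, explicit, {subject}, , {';'.join(toks)}")
        lines.append("")
        lines.append("[contingencies]")
        lines.append("target, type, effector")
        bool_rows: list[str] = []
        counter = [0]

        def effector_ref(e: BoolExpr) -> str:
            if isinstance(e, Ref):
                return e.name
            counter[0] += 1
            name = f"<b{counter[0]}>"
            if isinstance(e, Not):
                bool_rows.append(f"{name}, NOT, {effector_ref(e.child)}")
            elif isinstance(e, And):
                bool_rows.append(
                    f"{name}, AND, {';'.join(effector_ref(c) for c in e.children)}"
                )
            elif isinstance(e, Or):
                bool_rows.append(
                    f"{name}, OR, {';'.join(effector_ref(c) for c in e.children)}"
                )
            else:
                raise ValueError(f"cannot serialise effector node {e!r}")
            return name

        cont_lines = [
            f"{c.target}, {c.ctype}, {effector_ref(c.effector)}"
            for c in self.contingencies
        ]
        out_lines = [
            f"[{name}], {effector_ref(e)}" for name, e in self.output_links.items()
        ]
        lines.extend(cont_lines)
        lines.extend(bool_rows)
        if self.inputs:
            lines.append("")
            lines.append("[inputs]")
            lines.append("name")
            for i in self.inputs:
                lines.append(f"[{i}]")
        if out_lines:
            lines.append("")
            lines.append("[outputs]")
            lines.append("input, effector")
            lines.extend(out_lines)
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# State-name parsing
# ---------------------------------------------------------------------------

_MOD_RE = re.compile(r"^(\w+)_\[\((\w+)\)\]-\{(\w+)\}$")
_EMPTY_RE = re.compile(r"^(\w+)_\[(\w+)\]--0$")
_BOND_RE = re.compile(r"^(\w+)_\[(\w+)\]--(\w+)_\[(\w+)\]$")
_COMP_RE = re.compile(r"^(\w+)$")
_INPUT_RE = re.compile(r"^\[(\w+)\]$")
_RES_SITE_RE = re.compile(r"^(\w+)_\[\((\w+)\)\]$")
_DOM_SITE_RE = re.compile(r"^(\w+)_\[(\w+)\]$")


def parse_state_name(text: str) -> ElementalState:
    text = text.strip()
    m = _MOD_RE.match(text)
    if m:
        return mod_state(m.group(1), m.group(2), m.group(3))
    m = _EMPTY_RE.match(text)
    if m:
        return empty_binding_state(m.group(1), m.group(2))
    m = _BOND_RE.match(text)
    if m:
        return bond_state(m.group(1), m.group(2), m.group(3), m.group(4))
    m = _INPUT_RE.match(text)
    if m:
        return input_state(m.group(1))
    m = _COMP_RE.match(text)
    if m:
        return component_state(m.group(1))
    raise ParseError(f"cannot parse state name {text!r}")


# ---------------------------------------------------------------------------
# Document parsing
# ---------------------------------------------------------------------------

def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [c.strip() for c in line.split(sep)]


@dataclass
class _RawReaction:
    line: int
    rid: str
    rtype: str
    subject: str
    obj: str
    effects: str


_BUILTIN_TYPES = {
    "p+", "p-", "pt", "ap", "ppi", "ppi+", "ppi-", "syn", "deg", "explicit",
}


def parse_network(text: str) -> RxnconNetwork:
    """Parse a model document into a validated network.

    Bidirectional interaction entries (``ppi``) are split into forward
    ("+") and reverse ("-") reactions; degradation reactions are
    expanded (see :func:`expand_degradations`).
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current: Optional[str] = None
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]") and line[1:-1].lower() in (
            "reactions", "contingencies", "outputs", "inputs"
        ):
            current = line[1:-1].lower()
            sections[current] = []
            continue
        if current is None:
            raise ParseError("content before any section header", i)
        sections[current].append((i, line))

    if "reactions" not in sections:
        raise ParseError("missing [reactions] table")
    if "contingencies" not in sections:
        raise ParseError("missing [contingencies] table")

    # -- reactions ---------------------------------------------------------
    rows = sections["reactions"]
    if not rows:
        raise ParseError("[reactions] table has no header row")
    header = [h.lower() for h in _split_row(rows[0][1])]
    if header[:4] != ["id", "type", "subject", "object"]:
        raise ParseError(
            "[reactions] header must be 'id, type, subject, object[, effects]'",
            rows[0][0],
        )
    raw_reactions: list[_RawReaction] = []
    for line_no, line in rows[1:]:
        cells = _split_row(line)
        cells += [""] * (5 - len(cells))
        rid, rtype, subject, obj, eff = cells[:5]
        if not rid:
            raise ParseError("reaction row without id", line_no)
        if rtype not in _BUILTIN_TYPES:
            raise ParseError(f"unknown reaction type {rtype!r}", line_no)
        raw_reactions.append(_RawReaction(line_no, rid, rtype, subject, obj, eff))

    ids = [r.rid for r in raw_reactions]

    states: dict[str, ElementalState] = {}
    inputs: list[str] = []

    def declare(s: ElementalState) -> ElementalState:
        if s.variant is StateVariant.INPUT:
            if s.label not in inputs:
                inputs.append(s.label)
            return s
        return states.setdefault(s.name, s)

    def declare_site_pair(comp: str, site: str, tag: str) -> tuple[ElementalState, ElementalState]:
        neutral = declare(mod_state(comp, site, "0"))
        modified = declare(mod_state(comp, site, tag))
        return neutral, modified

    # First pass: declare the states each typed row touches.
    parsed_rows: list[tuple[_RawReaction, dict]] = []
    for r in raw_reactions:
        info: dict = {}
        try:
            if r.rtype in ("p+", "p-", "ap"):
                m = _RES_SITE_RE.match(r.obj)
                if not m:
                    raise ParseError(
                        f"{r.rtype} object must be Component_[(site)], got {r.obj!r}",
                        r.line,
                    )
                comp, site = m.group(1), m.group(2)
                declare_site_pair(comp, site, "P")
                info = {"comp": comp, "site": site}
            elif r.rtype == "pt":
                m1 = _RES_SITE_RE.match(r.subject)
                m2 = _RES_SITE_RE.match(r.obj)
                if not (m1 and m2):
                    raise ParseError(
                        "pt subject/object must be Component_[(site)]", r.line
                    )
                declare_site_pair(m1.group(1), m1.group(2), "P")
                declare_site_pair(m2.group(1), m2.group(2), "P")
                info = {
                    "donor": (m1.group(1), m1.group(2)),
                    "acceptor": (m2.group(1), m2.group(2)),
                }
            elif r.rtype in ("ppi", "ppi+", "ppi-"):
                m1 = _DOM_SITE_RE.match(r.subject)
                m2 = _DOM_SITE_RE.match(r.obj)
                if not (m1 and m2):
                    raise ParseError(
                        "ppi subject/object must be Component_[domain]", r.line
                    )
                a = (m1.group(1), m1.group(2))
                b = (m2.group(1), m2.group(2))
                declare(empty_binding_state(*a))
                declare(empty_binding_state(*b))
                declare(bond_state(a[0], a[1], b[0], b[1]))
                info = {"a": a, "b": b}
            elif r.rtype in ("syn", "deg"):
                if not _COMP_RE.match(r.obj):
                    raise ParseError(
                        f"{r.rtype} object must be a bare component name", r.line
                    )
                info = {"comp": r.obj}
            elif r.rtype == "explicit":
                pass
        except ParseError:
            raise
        # Explicit effect tokens may declare further states.
        clamp: Optional[bool] = None
        explicit_effects: list[tuple[str, ElementalState, list[ElementalState]]] = []
        if r.effects:
            for tok in r.effects.split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                if ":" not in tok:
                    raise ParseError(f"bad effect token {tok!r}", r.line)
                word, rest = tok.split(":", 1)
                word = word.strip().lower()
                if word == "clamp":
                    clamp = bool(int(rest))
                    continue
                if word == "origin":
                    info["origin"] = rest.strip()
                    continue
                if "@" in rest:
                    sname, gpart = rest.split("@", 1)
                    gstates = [declare(parse_state_name(g)) for g in gpart.split("&")]
                else:
                    sname, gstates = rest, []
                st = declare(parse_state_name(sname))
                explicit_effects.append((word, st, gstates))
        info["clamp"] = clamp
        info["explicit"] = explicit_effects
        parsed_rows.append((r, info))

    # Every site carries exactly one neutral state: declare missing
    # neutral complements of explicitly-introduced states.
    for s in list(states.values()):
        if not s.neutral and s.variant in (
            StateVariant.MODIFICATION, StateVariant.BOND
        ):
            for n in neutral_counterparts(s):
                declare(n)

    universe = list(states.values())

    # Second pass: build reactions via skeleton rules.
    word_mode = {
        "synthesise": EffectMode.SYNTHESIS,
        "synthesize": EffectMode.SYNTHESIS,
        "degrade": EffectMode.DEGRADATION,
        "produce": EffectMode.PRODUCTION,
        "consume": EffectMode.CONSUMPTION,
    }
    reactions: list[ElementalReaction] = []
    seen_names: set[str] = set()

    def add_reaction(rxn: ElementalReaction, line_no: int) -> None:
        if rxn.name in seen_names:
            raise ParseError(f"duplicate reaction name {rxn.name!r}", line_no)
        seen_names.add(rxn.name)
        reactions.append(rxn)

    def pat(comp: str, *sts: ElementalState) -> ComponentPattern:
        return ComponentPattern(comp, frozenset(sts))

    for r, info in parsed_rows:
        clamp = info["clamp"]
        subject_comp = r.subject if _COMP_RE.match(r.subject or "") else ""
        if info["explicit"]:
            effs = []
            for word, st, gstates in info["explicit"]:
                if word not in word_mode:
                    raise ParseError(f"unknown effect mode {word!r}", r.line)
                mode = word_mode[word]
                guards: frozenset[ElementalState] = frozenset()
                if mode is EffectMode.CONSUMPTION:
                    guards = frozenset({st})
                if gstates:
                    guards = guards | frozenset(gstates)
                effs.append(Effect(st, mode, guards))
            comps = tuple(c for c in (r.subject.split(";") if r.subject else []) if c)
            add_reaction(
                ElementalReaction(r.rid, comps, tuple(effs),
                                  bidirectional_origin=info.get("origin"),
                                  clamp=clamp, rtype="explicit",
                                  subject=r.subject, obj=r.obj),
                r.line,
            )
            continue
        if r.rtype in ("p+", "p-", "ap"):
            comp, site = info["comp"], info["site"]
            s0 = states[mod_state(comp, site, "0").name]
            sp = states[mod_state(comp, site, "P").name]
            lo, hi = (s0, sp) if r.rtype != "p-" else (sp, s0)
            rule = SkeletonRule(
                lhs=((pat(subject_comp),) if subject_comp and subject_comp != comp else ())
                + (pat(comp, lo),),
                rhs=((pat(subject_comp),) if subject_comp and subject_comp != comp else ())
                + (pat(comp, hi),),
            )
            comps = tuple(
                dict.fromkeys(([subject_comp] if subject_comp else []) + [comp])
            )
            add_reaction(
                ElementalReaction(r.rid, comps, tuple(classify_effects(rule)),
                                  clamp=clamp, rtype=r.rtype,
                                  subject=r.subject, obj=r.obj),
                r.line,
            )
        elif r.rtype == "pt":
            (dc, ds), (ac, asite) = info["donor"], info["acceptor"]
            rule = SkeletonRule(
                lhs=(pat(dc, states[mod_state(dc, ds, "P").name]),
                     pat(ac, states[mod_state(ac, asite, "0").name])),
                rhs=(pat(dc, states[mod_state(dc, ds, "0").name]),
                     pat(ac, states[mod_state(ac, asite, "P").name])),
            )
            comps = tuple(dict.fromkeys([dc, ac]))
            add_reaction(
                ElementalReaction(r.rid, comps, tuple(classify_effects(rule)),
                                  clamp=clamp, rtype=r.rtype,
                                  subject=r.subject, obj=r.obj),
                r.line,
            )
        elif r.rtype in ("ppi", "ppi+", "ppi-"):
            a, b = info["a"], info["b"]
            ea = states[empty_binding_state(*a).name]
            eb = states[empty_binding_state(*b).name]
            bd = states[bond_state(a[0], a[1], b[0], b[1]).name]
            comps = tuple(dict.fromkeys([a[0], b[0]]))
            fwd_rule = SkeletonRule(
                lhs=(pat(a[0], ea), pat(b[0], eb)), rhs=(pat(a[0], bd), pat(b[0], bd))
            )
            rev_rule = SkeletonRule(
                lhs=(pat(a[0], bd), pat(b[0], bd)), rhs=(pat(a[0], ea), pat(b[0], eb))
            )
            if r.rtype in ("ppi", "ppi+"):
                name = r.rid + "+" if r.rtype == "ppi" else r.rid
                add_reaction(
                    ElementalReaction(
                        name, comps, tuple(classify_effects(fwd_rule)),
                        bidirectional_origin="forward" if r.rtype == "ppi" else None,
                        clamp=clamp, rtype="ppi+", subject=r.subject, obj=r.obj),
                    r.line,
                )
            if r.rtype in ("ppi", "ppi-"):
                name = r.rid + "-" if r.rtype == "ppi" else r.rid
                add_reaction(
                    ElementalReaction(
                        name, comps, tuple(classify_effects(rev_rule)),
                        bidirectional_origin="reverse" if r.rtype == "ppi" else None,
                        clamp=clamp, rtype="ppi-", subject=r.subject, obj=r.obj),
                    r.line,
                )
        elif r.rtype == "syn":
            comp = info["comp"]
            carried = [
                s for s in universe
                if comp in s.carriers and s.variant is not StateVariant.COMPONENT
            ]
            if carried:
                rhs_states = tuple(s for s in carried if s.neutral)
            else:
                rhs_states = (declare(component_state(comp)),)
            rule = SkeletonRule(
                lhs=(pat(subject_comp),) if subject_comp else (),
                rhs=((pat(subject_comp),) if subject_comp else ())
                + (pat(comp, *rhs_states),),
            )
            comps = tuple([subject_comp] if subject_comp else [])
            add_reaction(
                ElementalReaction(r.rid, comps, tuple(classify_effects(rule)),
                                  clamp=clamp, rtype="syn",
                                  subject=r.subject, obj=r.obj),
                r.line,
            )
        elif r.rtype == "deg":
            comp = info["comp"]
            if not any(comp in s.carriers for s in universe):
                declare(component_state(comp))
            rule = SkeletonRule(
                lhs=((pat(subject_comp),) if subject_comp else ()) + (pat(comp),),
                rhs=(pat(subject_comp),) if subject_comp else (),
            )
            comps = tuple(dict.fromkeys(([subject_comp] if subject_comp else []) + [comp]))
            add_reaction(
                ElementalReaction(
                    r.rid, comps,
                    tuple(classify_effects(rule, states.values())),
                    clamp=clamp, rtype="deg", subject=r.subject, obj=r.obj),
                r.line,
            )

    # Reacting components that carry no states are generic: they are
    # represented by their own component state.
    for r in reactions:
        for comp in r.reacting_components:
            if not any(comp in s.carriers for s in states.values()):
                declare(component_state(comp))

    # -- contingencies -----------------------------------------------------
    bool_defs: dict[str, tuple[int, str, list[str]]] = {}
    cont_rows: list[tuple[int, str, str, str]] = []
    rows = sections["contingencies"]
    if rows:
        header = [h.lower() for h in _split_row(rows[0][1])]
        if header[:3] != ["target", "type", "effector"]:
            raise ParseError(
                "[contingencies] header must be 'target, type, effector'", rows[0][0]
            )
        for line_no, line in rows[1:]:
            cells = _split_row(line)
            if len(cells) < 3:
                raise ParseError("contingency row needs 3 cells", line_no)
            target, ctype, effector = cells[0], cells[1], cells[2]
            if target.startswith("<"):
                op = ctype.upper()
                if op not in ("AND", "OR", "NOT"):
                    raise ParseError(f"unknown Boolean node op {ctype!r}", line_no)
                bool_defs[target] = (line_no, op, [m.strip() for m in effector.split(";")])
            else:
                if ctype not in CONTINGENCY_TYPES:
                    raise ParseError(f"unknown contingency type {ctype!r}", line_no)
                cont_rows.append((line_no, target, ctype, effector))

    def resolve_effector(name: str, stack: tuple[str, ...] = ()) -> BoolExpr:
        name = name.strip()
        if name.startswith("<"):
            if name in stack:
                raise ParseError(f"cyclic Boolean node definition {name!r}")
            if name not in bool_defs:
                raise ParseError(f"undefined Boolean node {name!r}")
            line_no, op, members = bool_defs[name]
            children = [resolve_effector(m, stack + (name,)) for m in members]
            if op == "NOT":
                if len(children) != 1:
                    raise ParseError("NOT node needs exactly one member", line_no)
                return not_(children[0])
            return and_all(children) if op == "AND" else or_all(children)
        st = parse_state_name(name)
        if st.variant is StateVariant.INPUT:
            if st.label not in inputs:
                inputs.append(st.label)
            return Ref(st.name)
        if st.name not in states:
            raise ParseError(f"contingency references undeclared state {name!r}")
        return Ref(st.name)

    contingencies: list[Contingency] = []
    reaction_names = {x.name for x in reactions}
    base_names = {x.name[:-1] for x in reactions if x.bidirectional_origin}
    for line_no, target, ctype, effector in cont_rows:
        expr = resolve_effector(effector)
        if target in reaction_names:
            contingencies.append(Contingency(target, ctype, expr))
        elif target in base_names:
            # A contingency on an unsplit bidirectional id constrains the
            # association (forward) half.
            contingencies.append(Contingency(target + "+", ctype, expr))
        else:
            raise ParseError(
                f"contingency targets undeclared reaction {target!r}", line_no
            )

    # -- inputs / outputs --------------------------------------------------
    for line_no, line in sections.get("inputs", [])[1:] or []:
        m = _INPUT_RE.match(line.strip())
        if not m:
            raise ParseError(f"bad input declaration {line!r}", line_no)
        if m.group(1) not in inputs:
            inputs.append(m.group(1))

    output_links: dict[str, BoolExpr] = {}
    rows = sections.get("outputs", [])
    if rows:
        header = [h.lower() for h in _split_row(rows[0][1])]
        if header[:2] != ["input", "effector"]:
            raise ParseError("[outputs] header must be 'input, effector'", rows[0][0])
        for line_no, line in rows[1:]:
            cells = _split_row(line)
            if len(cells) < 2:
                raise ParseError("output row needs 2 cells", line_no)
            m = _INPUT_RE.match(cells[0])
            if not m:
                raise ParseError(f"output target must be an [input], got {cells[0]!r}",
                                 line_no)
            if m.group(1) not in inputs:
                inputs.append(m.group(1))
            output_links[m.group(1)] = resolve_effector(cells[1])

    components = _build_components(states)
    net = RxnconNetwork(
        components=components,
        states=states,
        reactions=reactions,
        contingencies=contingencies,
        inputs=inputs,
        output_links=output_links,
    )
    return expand_degradations(net)


def _build_components(states: dict[str, ElementalState]) -> dict[str, Component]:
    components: dict[str, Component] = {}
    for s in states.values():
        if s.variant is StateVariant.INPUT:
            continue
        for l in s.loci:
            comp = components.setdefault(l.component, Component(l.component))
            if s.variant is StateVariant.COMPONENT:
                continue
            site_states = comp.sites.setdefault(l.site, [])
            if s.name not in site_states:
                site_states.append(s.name)
    return components


# ---------------------------------------------------------------------------
# Degradation expansion
# ---------------------------------------------------------------------------

def expand_degradations(net: RxnconNetwork) -> RxnconNetwork:
    """Complete degradation reactions and duplicate OR-gated ones.

    Every degradation reaction of component X degrades all states X
    carries; degrading a bond X--Y additionally *produces* the partner's
    empty-binding state, guarded by the bond (degradation of the dimer
    releases the partner unbound).  A degradation reaction whose
    contingency effector is a top-level OR is duplicated once per
    disjunct.  The operation is idempotent.
    """
    new_reactions: list[ElementalReaction] = []
    new_contingencies = list(net.contingencies)
    for r in net.reactions:
        deg_effects = [e for e in r.effects if e.mode is EffectMode.DEGRADATION]
        if not deg_effects:
            new_reactions.append(r)
            continue
        degraded_comps = {c for e in deg_effects for c in e.state.carriers}
        # Components whose *every* state is degraded are the degradation
        # subjects; bond partners outside that set get a release effect.
        fully_degraded = {
            c for c in degraded_comps
            if all(
                any(e.state == s for e in deg_effects)
                for s in net.states_of_component(c)
            )
        } or degraded_comps
        effects = [e for e in r.effects if e.mode is not EffectMode.DEGRADATION]
        # Re-sweep: degrade every state carried by a degraded component.
        for comp in sorted(fully_degraded):
            carried = net.states_of_component(comp) or [
                net.states.get(comp) or component_state(comp)
            ]
            for s in carried:
                if not any(
                    e.state == s and e.mode is EffectMode.DEGRADATION for e in effects
                ):
                    effects.append(Effect(s, EffectMode.DEGRADATION))
            for s in carried:
                if s.variant is StateVariant.BOND:
                    partners = [
                        l for l in s.loci if l.component not in fully_degraded
                    ]
                    for l in partners:
                        released = empty_binding_state(l.component, l.site)
                        released = net.states.setdefault(released.name, released)
                        if not any(
                            e.state == released
                            and e.mode is EffectMode.PRODUCTION
                            and s in e.guards
                            for e in effects
                        ):
                            effects.append(
                                Effect(released, EffectMode.PRODUCTION,
                                       frozenset({s}))
                            )
        effects.sort(key=lambda e: (-e.mode.value, e.state.name))
        base = replace(r, effects=tuple(effects))
        # Duplicate per top-level OR disjunct of this reaction's contingency.
        conts = [c for c in new_contingencies if c.target == r.name]
        or_conts = [c for c in conts if isinstance(c.effector, Or)
                    and c.ctype in ("!",)]
        if len(or_conts) == 1 and not r.name.endswith("]"):
            c = or_conts[0]
            new_contingencies = [
                x for x in new_contingencies
                if not (x.target == r.name and x is c)
            ]
            for k, disjunct in enumerate(c.effector.children, start=1):
                dup_name = f"{r.name}[{k}]"
                new_reactions.append(replace(base, name=dup_name))
                new_contingencies.append(Contingency(dup_name, c.ctype, disjunct))
                for other in conts:
                    if other is not c:
                        new_contingencies.append(replace(other, target=dup_name))
            new_contingencies = [
                x for x in new_contingencies
                if not (x.target == r.name)
            ]
        else:
            new_reactions.append(base)
    net.reactions = new_reactions
    net.contingencies = new_contingencies
    net.components = _build_components(net.states)
    return net


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.message}"


def validate(net: RxnconNetwork) -> list[Diagnostic]:
    """Non-throwing structural checks; empty for all fixture models."""
    out: list[Diagnostic] = []
    referenced: set[str] = set()
    for r in net.reactions:
        referenced.update(r.reacting_components)
        for e in r.effects:
            referenced.update(e.state.carriers)
    for name in net.components:
        if name not in referenced:
            out.append(Diagnostic("warning", f"component {name} is never referenced"))
    reaction_names = {r.name for r in net.reactions}
    for c in net.contingencies:
        if c.target not in reaction_names:
            out.append(
                Diagnostic("error",
                           f"contingency on undeclared reaction {c.target!r}")
            )
        for leaf in c.effector.refs():
            st = parse_state_name(leaf)
            if st.variant is StateVariant.INPUT:
                if st.label not in net.inputs:
                    out.append(
                        Diagnostic("error", f"undeclared input {leaf!r}")
                    )
            elif leaf not in net.states:
                out.append(Diagnostic("error", f"undeclared state {leaf!r}"))
    # Synthesis-path depth: a non-neutral state is supported only when it
    # is producible directly from its neutral counterpart.
    for s in net.states.values():
        if s.neutral or s.variant in (StateVariant.COMPONENT, StateVariant.INPUT):
            continue
        producers = [
            r for r in net.reactions
            if any(e.state == s and e.mode is EffectMode.PRODUCTION
                   for e in r.effects)
        ]
        if not producers:
            continue
        neutrals = set(neutral_counterparts(s))
        for r in producers:
            eff = next(e for e in r.effects
                       if e.state == s and e.mode is EffectMode.PRODUCTION)
            sources = set(eff.guards) or set(r.consumed_states())
            if sources and not (sources & neutrals):
                out.append(
                    Diagnostic(
                        "warning",
                        f"unsupported synthesis-path depth: {s.name} is produced "
                        f"by {r.name} without consuming a neutral counterpart",
                    )
                )
    return out
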
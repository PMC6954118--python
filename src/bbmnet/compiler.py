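"""Compile a reaction-contingency network into a bipartite Boolean model.

One Boolean update rule is generated per target.  Reaction targets get
``K(R) AND L(R)``: the components the reaction acts on must be present
and the strict contingencies satisfied.  State targets follow the
generic state rule: a state is true if it is (directly or indirectly)
synthesised, or if its carriers are present, no reaction degrades it,
and it is either produced by an active primed reaction or was already
true and is not consumed.  Primed reactions pair a reaction target with
its source states, since a reaction target only records regulatory
eligibility.  Optional source-state smoothing widens the producer
check to "source present now or produced next step" (one-level
expansion of the non-smoothed rule), which removes spurious
out-of-phase oscillations from constitutive production/consumption
cycles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional

from .expr import (
    BoolExpr, FALSE, Ref, TRUE, and_all, not_, or_all, substitute,
)
from .network_model import (
    Component,
    Contingency,
    Effect,
    EffectMode,
    ElementalReaction,
    ElementalState,
    RxnconNetwork,
    StateVariant,
    ValidationError,
    neutral_counterparts,
    validate,
)


class UnsupportedSynthesisDepthError(ValidationError):
    """Raised when a synthesised state is producible only through
    intermediate non-neutral states, which the one-step synthesis term
    does not cover."""


@dataclass(frozen=True)
class CompileOptions:
    smoothing: bool = True
    k_plus_policy: Literal["ignore", "strict"] = "ignore"
    k_minus_policy: Literal["ignore", "strict"] = "ignore"


@dataclass(frozen=True)
class Target:
    kind: Literal["reaction", "state", "input"]
    name: str  # original reaction/state/input name
    symbol: str


@dataclass
class BipartiteBooleanModel:
    targets: list[Target]
    rules: dict[str, BoolExpr]  # symbol -> update expression
    initial: dict[str, bool]  # symbol -> default initial value
    symbol_of: dict[str, str] = field(default_factory=dict)  # name -> symbol

    @property
    def symbols(self) -> list[str]:
        return [t.symbol for t in self.targets]

    def target(self, name_or_symbol: str) -> Target:
        for t in self.targets:
            if t.symbol == name_or_symbol or t.name == name_or_symbol:
                return t
        raise KeyError(name_or_symbol)

    def targets_of_kind(self, kind: str) -> list[Target]:
        return [t for t in self.targets if t.kind == kind]


# ---------------------------------------------------------------------------
# Symbols
# ---------------------------------------------------------------------------

_SANITISE_STEPS = [
    ("--0", "_ub"),
    ("--", "__"),
    ("-{", "_"),
    ("+", "plus"),
    ("-", "minus"),
]


def sanitise_symbol(name: str) -> str:
    s = name
    for old, new in _SANITISE_STEPS:
        s = s.replace(old, new)
    s = re.sub(r"[^0-9A-Za-z_]", "_", s)
    s = re.sub(r"_+", "_", s).strip("_")
    if not s:
        s = "x"
    if s[0].isdigit():
        s = "_" + s
    return s


def _assign_symbols(names: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        base = sanitise_symbol(name)
        sym = base
        k = 2
        while sym in used:
            sym = f"{base}_{k}"
            k += 1
        used.add(sym)
        out[name] = sym
    return out


# ---------------------------------------------------------------------------
# The compiler
# ---------------------------------------------------------------------------

class _Compiler:
    def __init__(self, net: RxnconNetwork, opts: CompileOptions):
        self.net = net
        self.opts = opts
        names = (
            [r.name for r in net.reactions]
            + list(net.states)
            + [f"[{i}]" for i in net.inputs]
        )
        self.symbol_of = _assign_symbols(names)

    # -- Eq 1: component expression ---------------------------------------
    def component_expression(self, c: Component) -> BoolExpr:
        if c.generic:
            return Ref(self.symbol_of[c.name])
        return and_all(
            or_all(Ref(self.symbol_of[s]) for s in site_states)
            for site_states in c.sites.values()
        )

    def _component_expr_by_name(self, name: str) -> BoolExpr:
        comp = self.net.components.get(name)
        if comp is None:
            # Component known only through a component state.
            return Ref(self.symbol_of[name])
        return self.component_expression(comp)

    # -- Eq 2: reacting components ----------------------------------------
    def reacting_components(self, r: ElementalReaction) -> BoolExpr:
        return and_all(
            self._component_expr_by_name(c) for c in r.reacting_components
        )

    # -- Eq 3: carrier components -----------------------------------------
    def carrier_components(self, s: ElementalState) -> BoolExpr:
        if s.variant is StateVariant.COMPONENT:
            return Ref(self.symbol_of[s.name])
        return and_all(self._component_expr_by_name(c) for c in s.carriers)

    # -- Eq 4: primed reactions -------------------------------------------
    def primed_reaction(self, r: ElementalReaction,
                        effect: Optional[Effect] = None) -> BoolExpr:
        sources = self.effect_sources(r, effect)
        return and_all(
            [Ref(self.symbol_of[r.name])]
            + [Ref(self.symbol_of[s.name]) for s in sources]
        )

    def effect_sources(self, r: ElementalReaction,
                       effect: Optional[Effect] = None) -> list[ElementalState]:
        """Source states for a (possibly effect-specific) primed reaction:
        the effect's guards when present, else the reaction's consumed set."""
        if effect is not None and effect.guards - {effect.state}:
            sources = sorted(effect.guards - {effect.state}, key=lambda s: s.name)
        else:
            sources = [s for s in r.consumed_states()]
        return sources

    # -- Eq 5: synthesis term ---------------------------------------------
    def synthesis_term(self, s: ElementalState) -> BoolExpr:
        if s.variant is StateVariant.INPUT:
            return FALSE
        synth_of = lambda st: [
            r for r in self.net.reactions
            if any(e.state == st and e.mode is EffectMode.SYNTHESIS
                   for e in r.effects)
        ]
        if s.neutral or s.variant is StateVariant.COMPONENT:
            return or_all(self.primed_reaction(r) for r in synth_of(s))
        neutrals = neutral_counterparts(s)
        synths = []
        for n in neutrals:
            for r in synth_of(n):
                if r not in synths:
                    synths.append(r)
        if not synths:
            return FALSE
        producers: list[tuple[ElementalReaction, Effect]] = []
        for r in self.net.reactions:
            for e in r.effects:
                if e.state == s and e.mode is EffectMode.PRODUCTION:
                    producers.append((r, e))
        if producers and not any(
            set(self.effect_sources(r, e)) & set(neutrals) for r, e in producers
        ):
            raise UnsupportedSynthesisDepthError(
                f"state {s.name} is synthesised but only producible from "
                f"non-neutral states; the one-step synthesis term does not apply"
            )
        return and_all([
            or_all(self.primed_reaction(r) for r in synths),
            or_all(self.primed_reaction(r, e) for r, e in producers),
        ])

    # -- Eq 6: contingency expression --------------------------------------
    def contingency_expression(self, r: ElementalReaction) -> BoolExpr:
        terms: list[BoolExpr] = []
        for c in self.net.contingencies_for(r.name):
            ctype = c.ctype
            if ctype == "K+" and self.opts.k_plus_policy == "strict":
                ctype = "!"
            elif ctype == "K-" and self.opts.k_minus_policy == "strict":
                ctype = "x"
            if ctype not in ("!", "x"):
                continue
            effector = substitute(
                c.effector,
                {name: Ref(self.symbol_of[name]) for name in c.effector.refs()},
            )
            terms.append(effector if ctype == "!" else not_(effector))
        return and_all(terms)

    # -- Eq 7: reaction update ---------------------------------------------
    def reaction_update(self, r: ElementalReaction) -> BoolExpr:
        if r.clamp is not None:
            return TRUE if r.clamp else FALSE
        return and_all([self.reacting_components(r),
                        self.contingency_expression(r)])

    # -- Eq 8: state update (non-smoothed) ----------------------------------
    def _acting(self, s: ElementalState, mode: EffectMode):
        for r in self.net.reactions:
            for e in r.effects:
                if e.state == s and e.mode is mode:
                    yield r, e

    def state_update(self, s: ElementalState) -> BoolExpr:
        sigma = self.synthesis_term(s)
        degraders = [self.primed_reaction(r, e)
                     for r, e in self._acting(s, EffectMode.DEGRADATION)]
        producers = [self.primed_reaction(r, e)
                     for r, e in self._acting(s, EffectMode.PRODUCTION)]
        consumers = [self.primed_reaction(r, e)
                     for r, e in self._acting(s, EffectMode.CONSUMPTION)]
        persist = and_all([Ref(self.symbol_of[s.name])]
                          + [not_(c) for c in consumers])
        core = and_all(
            [self.carrier_components(s)]
            + [not_(d) for d in degraders]
            + [or_all([or_all(producers), persist])]
        )
        return or_all([sigma, core])

    # -- Eq 9: smoothed producers -------------------------------------------
    def smoothed_producer(self, r: ElementalReaction, effect: Effect,
                          unsmoothed: dict[str, BoolExpr]) -> BoolExpr:
        """Producer primed term with each source state widened to
        "present now or produced next step"; the next-step value is the
        full non-smoothed state rule expanded exactly one level."""
        terms: list[BoolExpr] = [Ref(self.symbol_of[r.name])]
        for src in self.effect_sources(r, effect):
            sym = self.symbol_of[src.name]
            terms.append(or_all([Ref(sym), unsmoothed[sym]]))
        return and_all(terms)

    def state_update_smoothed(self, s: ElementalState,
                              unsmoothed: dict[str, BoolExpr]) -> BoolExpr:
        sigma = self.synthesis_term(s)
        degraders = [self.primed_reaction(r, e)
                     for r, e in self._acting(s, EffectMode.DEGRADATION)]
        producers = [self.smoothed_producer(r, e, unsmoothed)
                     for r, e in self._acting(s, EffectMode.PRODUCTION)]
        consumers = [self.primed_reaction(r, e)
                     for r, e in self._acting(s, EffectMode.CONSUMPTION)]
        persist = and_all([Ref(self.symbol_of[s.name])]
                          + [not_(c) for c in consumers])
        core = and_all(
            [self.carrier_components(s)]
            + [not_(d) for d in degraders]
            + [or_all([or_all(producers), persist])]
        )
        return or_all([sigma, core])

    # -- assembly ------------------------------------------------------------
    def compile(self) -> BipartiteBooleanModel:
        targets: list[Target] = []
        rules: dict[str, BoolExpr] = {}
        for r in self.net.reactions:
            sym = self.symbol_of[r.name]
            targets.append(Target("reaction", r.name, sym))
            rules[sym] = self.reaction_update(r)
        unsmoothed = {
            self.symbol_of[s.name]: self.state_update(s)
            for s in self.net.states.values()
        }
        for s in self.net.states.values():
            sym = self.symbol_of[s.name]
            targets.append(Target("state", s.name, sym))
            if self.opts.smoothing:
                rules[sym] = self.state_update_smoothed(s, unsmoothed)
            else:
                rules[sym] = unsmoothed[sym]
        for i in self.net.inputs:
            name = f"[{i}]"
            sym = self.symbol_of[name]
            targets.append(Target("input", name, sym))
            if i in self.net.output_links:
                link = self.net.output_links[i]
                rules[sym] = substitute(
                    link, {n: Ref(self.symbol_of[n]) for n in link.refs()}
                )
            else:
                rules[sym] = Ref(sym)  # identity: user-set values persist
        model = BipartiteBooleanModel(
            targets=targets,
            rules=rules,
            initial={},
            symbol_of=dict(self.symbol_of),
        )
        model.initial = default_initial_state(model, self.net)
        return model


def compile_network(net: RxnconNetwork,
                    opts: CompileOptions = CompileOptions()) -> BipartiteBooleanModel:
    """Compile a validated network; deterministic for identical input."""
    blocking = [d for d in validate(net) if d.severity == "error"]
    if blocking:
        raise ValidationError("; ".join(d.message for d in blocking))
    return _Compiler(net, opts).compile()


def default_initial_state(model: BipartiteBooleanModel,
                          net: RxnconNetwork) -> dict[str, bool]:
    """Default initiation vector: all neutral elemental states true, all
    generic component states true, everything else (reactions, modified
    and bond states, inputs) false."""
    init: dict[str, bool] = {}
    state_by_name = dict(net.states)
    clamp_by_name = {r.name: r.clamp for r in net.reactions}
    for t in model.targets:
        if t.kind == "state":
            s = state_by_name[t.name]
            init[t.symbol] = bool(
                s.neutral or s.variant is StateVariant.COMPONENT
            )
        elif t.kind == "reaction" and clamp_by_name.get(t.name) is not None:
            # Clamped reaction targets are constants and start at their
            # clamped value.
            init[t.symbol] = bool(clamp_by_name[t.name])
        else:
            init[t.symbol] = False
    return init
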
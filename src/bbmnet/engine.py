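"""Synchronous deterministic simulation and attractor analysis.

All targets are updated simultaneously from time-t values; the state
space is finite, so every trajectory ends in a point or cyclic
attractor, detected exactly with a visited-vector hash map.  The
input-toggling workflow repeatedly simulates to an attractor, flips the
input values, and reseeds from the attractor until a previously seen
attractor recurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .compiler import BipartiteBooleanModel
from .expr import BoolExpr

StateVector = tuple[bool, ...]


def vector_from_mapping(model: BipartiteBooleanModel,
                        values: Mapping[str, bool]) -> StateVector:
    """Build an ordered vector from a symbol->value mapping (symbols or
    original names accepted); missing targets default to False."""
    lookup = dict(values)
    out = []
    for t in model.targets:
        if t.symbol in lookup:
            out.append(bool(lookup[t.symbol]))
        elif t.name in lookup:
            out.append(bool(lookup[t.name]))
        else:
            out.append(False)
    return tuple(out)


def mapping_from_vector(model: BipartiteBooleanModel,
                        v: StateVector) -> dict[str, bool]:
    return {t.symbol: val for t, val in zip(model.targets, v)}


def evaluate(expr: BoolExpr, env: Mapping[str, bool]) -> bool:
    """Pure Boolean evaluation of an expression under an environment."""
    return expr.evaluate(env)


def step(model: BipartiteBooleanModel, v: StateVector) -> StateVector:
    """One synchronous update: every rule reads only time-t values."""
    env = {t.symbol: val for t, val in zip(model.targets, v)}
    return tuple(model.rules[t.symbol].evaluate(env) for t in model.targets)


@dataclass
class SimulationResult:
    trajectory: list[StateVector]  # trajectory[0] is the initial state
    attractor_start: int  # first index of the recurring block
    period: int  # 1 for point attractors

    @property
    def attractor(self) -> list[StateVector]:
        return self.trajectory[self.attractor_start:
                               self.attractor_start + self.period]

    @property
    def is_point(self) -> bool:
        return self.period == 1

    def attractor_key(self) -> frozenset[StateVector]:
        """Canonical identity of the attractor (rotation-invariant)."""
        return frozenset(self.attractor)


def simulate_to_attractor(model: BipartiteBooleanModel,
                          v0: StateVector) -> SimulationResult:
    """Iterate the synchronous map until a vector recurs.

    ``attractor_start`` is the first index whose vector recurs; the
    trajectory is truncated just before the repeat, so the attractor
    block appears exactly once.
    """
    seen: dict[StateVector, int] = {}
    trajectory: list[StateVector] = []
    v = v0
    while v not in seen:
        seen[v] = len(trajectory)
        trajectory.append(v)
        v = step(model, v)
    start = seen[v]
    return SimulationResult(trajectory, start, len(trajectory) - start)


@dataclass
class Phase:
    inputs: dict[str, bool]  # input symbol -> value held this phase
    result: SimulationResult


@dataclass
class WorkflowResult:
    phases: list[Phase]
    termination: str  # "attractor-revisited" | "max-phases"
    notes: list[str] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def input_toggle_workflow(
    model: BipartiteBooleanModel,
    input_names: Optional[Sequence[str]] = None,
    max_phases: int = 10,
    v0: Optional[StateVector] = None,
) -> WorkflowResult:
    """Simulate to an attractor, toggle the inputs, and repeat.

    Phase 1 runs with the inputs at their default (false).  Each later
    phase flips the named inputs in the seed vector (inputs held by an
    identity self-update then keep the new value) and re-simulates.  The
    workflow stops when an attractor recurs or after ``max_phases``.  If
    a phase ends in a cyclic attractor, its first state seeds the next
    phase and a note is recorded.
    """
    if input_names is None:
        targets = model.targets_of_kind("input")
    else:
        targets = [model.target(n) for n in input_names]
    if v0 is None:
        v0 = vector_from_mapping(model, model.initial)
    idx = {t.symbol: i for i, t in enumerate(model.targets)}
    input_idx = [idx[t.symbol] for t in targets]

    phases: list[Phase] = []
    notes: list[str] = []
    seen_attractors: set[frozenset[StateVector]] = set()
    v = v0
    termination = "max-phases"
    for phase_no in range(max_phases):
        res = simulate_to_attractor(model, v)
        phases.append(
            Phase({model.targets[i].symbol: v[i] for i in input_idx}, res)
        )
        key = res.attractor_key()
        if key in seen_attractors:
            termination = "attractor-revisited"
            break
        seen_attractors.add(key)
        if not res.is_point:
            notes.append(
                f"phase {phase_no + 1} ended in a cyclic attractor "
                f"(period {res.period}); continuing from its first state"
            )
        seed = list(res.attractor[0])
        for i in input_idx:
            seed[i] = not seed[i]
        v = tuple(seed)
    return WorkflowResult(phases, termination, notes)
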
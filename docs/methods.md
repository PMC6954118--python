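# Methods

## Scope and semantics

`bbmnet` compiles a reaction–contingency network into a bipartite
Boolean model and simulates it synchronously.  The central semantic
choice is that targets describe **system-level** properties, not single
molecules: a state target is true when a functionally relevant pool of
molecules carries that state, and a reaction target is true when the
regulatory network can accommodate the reaction.  Consequently two
states that are mutually exclusive on one molecule (say `A-{0}` and
`A-{P}`) may be simultaneously true, and a true reaction target does
not imply the reaction fires — its source states must be present too,
which is why every occurrence of a reaction in a state rule is *primed*
(conjoined with its source states).

A quasi-steady state is assumed at every update step, which induces the
dominance order **synthesis > degradation > production > consumption**:
a protein that is both synthesised and degraded is present; a state
both produced and consumed is present; a degraded state is absent
regardless of kinase activity.  The state rule encodes this order
structurally — the synthesis term is a top-level disjunct, degradation
a top-level negated conjunct inside the carrier gate, and production
overrides the persistence/consumption term.

Only synchronous deterministic updates are provided.  Most reactions
touch several states (source and product); updating them in any other
order manufactures artefacts, so asynchronous schemes are deliberately
out of scope.

## Effect classification

Reaction effects are derived from context-free skeleton rules.  A state
is *produced* (on RHS, not LHS, carrier on LHS), *consumed* (on LHS,
not RHS, carrier on RHS), *synthesised* (on RHS, carrier absent from
LHS) or *degraded* (carrier bare on LHS and absent from RHS, no
mutually exclusive state on LHS).  Degradation is evaluated against the
full declared state universe: a bare component on the left degrades
*every* state it carries.  Degrading a bond `X--Y` from the X side
additionally *produces* `Y--0`, guarded by the bond itself — the
released partner exists only while dimers are being destroyed.  A
degradation reaction whose `!` contingency is a top-level OR is split
into one duplicate per disjunct, each gated by its own disjunct, so the
exported model keeps one conjunction-only rule per reaction target.
Contingencies written against an unsplit bidirectional interaction id
constrain the association half; the dissociation half can be addressed
with the explicit `-`-suffixed name (association is what reaction-level
regulation almost always means mechanically; regulated dissociation is
rare enough to deserve an explicit target).

## Synthesis term

The synthesis term handles states at most one production step from a
synthesised neutral state: for neutral states, the disjunction of
primed synthesis reactions; for non-neutral states, (synthesis of a
neutral counterpart) AND (some primed producer), i.e. an active path
from the synthesised form.  States further removed raise
`UnsupportedSynthesisDepthError` at compile time and are flagged by
`validate()`; supporting deeper chains would require path enumeration
that no current fixture needs.

## Smoothing

Without smoothing, a constitutive production/consumption cycle whose
site starts in a single state oscillates with period 2: each reaction
depletes the other's source pool, so they alternate.  These
oscillations are artefacts of Boolean time at the system level (many
molecules do not march in phase; fast cycles pass through both states
within one Boolean step).  Smoothing widens the producer's source check
to `S_j(t) ∪ S_j(t+1)`, where `S_j(t+1)` is the **non-smoothed** state
rule expanded exactly one level — no recursion, so expressions stay
finite and the expansion is well defined.  Smoothing applies only to
the producer disjunct of the state rule; degradation, consumption and
the synthesis term are untouched.  The motif suites verify it is
conservative: every configuration matched without smoothing keeps the
identical point attractor with it.

## Options and defaults

| option | default | meaning |
| --- | --- | --- |
| `smoothing` | `on` | widen producer source checks by one step |
| `k_plus_policy` | `ignore` | `K+` treated as `0`; `strict` folds it into `!` |
| `k_minus_policy` | `ignore` | `K-` treated as `0`; `strict` folds it into `x` |
| workflow `max_phases` | 10 | hard stop for the input-toggling loop |

Quantitative contingencies have no natural deterministic-Boolean
reading, hence the `ignore` default with strict folding as an explicit
opt-in.  `?` is always treated as `0`.

The default initial vector sets all neutral elemental states and all
generic component states true and everything else false; inputs start
false, and phase 1 of the workflow runs with the inputs at this
default.  Clamped reaction targets (used by the motif suite) are
compiled to constant rules and initialised at their clamp value, so
constant targets never change during simulation.  Inputs are identity
self-updates (a user-set value persists) unless the model declares an
output link, in which case the input target carries the linking
expression — this is how the cyclic HOG variant turns `Turgor` into a
model variable.

## Validation fixtures and what they show

The two minimal motifs enumerate *every* combination of the four
reaction types acting on one modification site (2 states, 64 variants)
or one binding pair (3 states, 128 variants), with reactions clamped
constitutively on/off.  Expected steady states follow from the
dominance order.  The modification expectations are fully determined
and implemented directly.  The interaction expectations are not all
fixed by the short verbal rules; the remaining rows were derived once
from the quasi-steady-state semantics and frozen as a 128-row table
(`src/bbmnet/data/interaction_expected_attractors.csv`) that the code
reads back — oracle and engine cannot drift together, and the table is
itself re-derived and compared in the test suite.  One derived
completion deserves mention: with degradation and association active,
no synthesis and no initial dimer, free B is lost — the association
keeps consuming `B--0` while its only producer (release from the dimer)
never activates, because degradation dominates production and the dimer
never forms.

The HOG fixture is a reconstruction, not a measurement: it shows that
locally defined update rules assemble into a functioning pathway
(signal inversion through the phosphorelay, three-phase input response,
feedback oscillation), not that the real pathway has exactly these
kinetics.  The full variant represents Ssk1's inhibition of Ssk2
mechanistically as an Ssk1–Ssk2 bond blocked by `Ssk1-{P}` and required
by the Ssk2 kinase reaction — 12 reaction targets after splitting the
bidirectional interaction, 15 elemental states (6 phosphosites + the
bond triple), the phosphatase component state and the turgor target, 29
targets in all.  A more abstract variant
(`hog_model(ssk1_ssk2_bond=False)`) replaces the bond with an Ssk2
activation site (28 targets) and shows the same qualitative behaviour.
Synthetic fixtures do not capture expression-level regulation, cross
talk, or multi-site cooperativity of the real pathway; passing tests
demonstrate the compiler's semantics, not biological completeness.

All fixture models are desk-scale (≤ 29 targets; trajectories ≤ ~15
steps), so the whole validation — 4 × (64 + 128) compile-and-simulate
runs plus the HOG workflows — completes in a few seconds.

## Numerical / degenerate-input choices

* Empty Boolean combinators: empty conjunction is TRUE (no degraders,
  no consumers, no contingencies), empty disjunction FALSE (no
  producers, no synthesis route) — so untouched states persist while
  producerless states cannot switch on spuriously.
* The producer combinator is OR over producing primed reactions ("some
  reaction produces the state"); any active degrader or consumer acts
  (AND over negations).
* Attractor detection is exact (hash map of visited vectors), feasible
  because desk-scale models are small; exhaustive initial-state scans
  are out of scope by design.
* When a workflow phase ends in a cyclic attractor the next phase is
  seeded from the attractor's first state and a note is recorded; the
  attractor-identity check uses the rotation-invariant set of states.
* Symbols are deterministic sanitisations of the original names
  (`A_[(r)]-{P}` → `A_r_P`) with a numeric de-collision suffix; the
  bijective mapping is exported as `<prefix>_symbols.csv`.
* Exported expressions parenthesise every composite sub-expression, so
  loader operator precedence can never change the parse.

## Known limitations

* Synthesis chains deeper than one production step are rejected, not
  amended.
* Only the built-in reaction shorthands (`p+`, `p-`, `pt`, `ap`,
  `ppi[±]`, `syn`, `deg`) are provided; other chemistry must be written
  as explicit effect lists.
* Native spreadsheet model files are not read; models are transcribed
  into the plain-text dialect.
* The published companion model of the yeast pheromone pathway is only
  loadable if transcribed into the dialect; its curation is not
  reproduced here.
* The BoolNet cross-check (`scripts/boolnet_crosscheck.R`) requires the
  BoolNet R package and is an optional, out-of-band verification; no
  Python test depends on it.
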
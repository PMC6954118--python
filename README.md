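# bbmnet

Parameter-free **bipartite Boolean models** of signal transduction
networks, compiled directly from reaction–contingency (rxncon-style)
network descriptions.

Mechanistic models of signalling suffer from two problems at once:
site-resolved states combine combinatorially into astronomically many
microstates, and the rate constants needed to parametrise them are
mostly unmeasured.  `bbmnet` targets the modeller who has a
reconstruction — a list of elemental reactions and the contingencies
that regulate them — and wants to *execute* it without parameters: to
check that the network transmits its signal, responds to its inputs,
and finds sensible steady states.

## The model

A network description consists of:

* **elemental states** `S_i` — site-resolved observables: a
  modification at a residue (`A_[(r)]-{P}`, neutral form `-{0}`), a
  bond between two domains (`A_[d]--B_[e]`, with unbound complements
  `A_[d]--0`, `B_[e]--0`), or a bare (generic) component;
* **elemental reactions** `R_i` — decontextualised events classified by
  how they act on each state: *synthesis*, *degradation*, *production*
  or *consumption*, derived from the reaction's context-free skeleton
  rule;
* **contingencies** — Boolean constraints of states/inputs on
  reactions: required `!`, excluding `x`, quantitative `K+`/`K-`
  (ignored by default, optionally treated strictly), `0`/`?` (no
  effect).

The compiled Boolean model is *bipartite*: one target per reaction and
one per state, updated synchronously by two generic rules.  With
`C_j = ⋂_sites ⋃_states S` (a component is present iff every site is in
some state) and the *primed* reaction `R' = R ⋂ {source states}`:

* **reaction targets** (the regulatory layer):
  `R_i(t+1) = K(R_i) ⋂ L(R_i)` — the reacting components are present
  and the `!`/`x` contingencies hold;
* **state targets** (the mechanistic layer):
  `S_i(t+1) = Σ(S_i) ∪ ( K(S_i) ⋂_deg ¬R' ⋂ { ⋃_prod R' ∪ [ S_i ⋂_cons ¬R' ] } )`
  — a state is true if synthesised (`Σ`), or if its carriers exist, it
  is not degraded, and it is either produced or persists unconsumed.

This encodes the dominance hierarchy *synthesis > degradation >
production > consumption*.  Optional **source-state smoothing**
replaces each producer's source check `S_j` by `S_j(t) ∪ S_j(t+1)`
(one-level expansion of the non-smoothed rule), removing the spurious
period-2 oscillations that constitutive production/consumption cycles
otherwise show when only one of the two site states is initially
present.

Models are exchanged in the BoolNet `targets, factors` text format with
companion symbol-map and initial-values CSVs, so they can be loaded by
any BoolNet-compatible tool.

## Worked example: the HOG pathway

The built-in fixture reconstructs the Sln1 branch of the yeast
high-osmolarity glycerol pathway: turgor-gated Sln1 autophosphorylation
feeds a phosphorelay Sln1→Ypd1→Ssk1; phosphorylated Ssk1 *blocks* the
Ssk1–Ssk2 association that the downstream kinase cascade
(Ssk2→Pbs2→Hog1→Hot1) requires, so the transcription factor Hot1 is
phosphorylated exactly when turgor is low.

```pycon
>>> from bbmnet.fixtures import hog_document
>>> open("hog.txt", "w").write(hog_document())
```

```console
$ bbmnet compile hog.txt
wrote hog.boolnet, hog_symbols.csv, hog_initial_vals.csv
$ bbmnet simulate hog.txt
attractor: point after 8 steps; wrote hog_trajectory_first.csv, hog_new_attractor.csv
$ bbmnet workflow hog.txt --input Turgor
3 phases (attractor-revisited); wrote hog_workflow.json and per-phase trajectories
```

The compiled model has 29 targets: 12 reaction targets, 16 state
targets (15 elemental states plus the generic phosphatase's component
state) and the input/output target `Turgor`.  Starting from the default
vector (all neutral states and generic components true, everything else
false), the model settles into its natural off-state after 8 steps — a
point attractor in which `Hot1_s_P` is **true** (no turgor ⇒ pathway
on).  The workflow report shows the three toggle phases, each a point
attractor, with Hot1-{P} inverted relative to turgor:

```json
{"phases": [{"phase": 1, "inputs": {"Turgor": 0}, "period": 1, "attractor_start": 8},
            {"phase": 2, "inputs": {"Turgor": 1}, "period": 1, "attractor_start": 11},
            {"phase": 3, "inputs": {"Turgor": 0}, "period": 1, "attractor_start": 12}],
 "termination": "attractor-revisited", "notes": []}
```

Compiling with `--smoothing off` instead makes every phase end in a
period-2 cyclic attractor — the out-of-phase source-state oscillations
that smoothing exists to remove.  The cyclic model variant
(`hog_document(cyclic=True)`) drives `Turgor` from `Hot1-{P}` and
oscillates: `bbmnet simulate` then reports a cyclic attractor in which
turgor itself turns on and off.

The update rules are validated exhaustively against hand-derived
expectation tables on two minimal motifs (a modification motif, 64
clamped variants, and an interaction motif, 128 variants):

```console
$ bbmnet validate-motifs
modification raw: 62/64 expected attractors reached
modification smoothed: 64/64 expected attractors reached
interaction raw: 109/128 expected attractors reached
interaction smoothed: 128/128 expected attractors reached
```

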
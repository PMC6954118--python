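"""Update-rule construction: component/carrier expressions, primed
reactions, synthesis terms, contingencies, the state rule and smoothing."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from bbmnet import CompileOptions, compile_network
from bbmnet.compiler import (
    UnsupportedSynthesisDepthError, _Compiler, default_initial_state,
    sanitise_symbol,
)
from bbmnet.engine import step, vector_from_mapping
from bbmnet.expr import FALSE, Ref, TRUE
from bbmnet.boolnet_io import boolnet_text
from bbmnet.fixtures import (
    MOD_STATES,
    MotifConfig,
    hog_document,
    interaction_motif,
    interaction_motif_document,
    modification_motif,
    modification_motif_document,
)
from bbmnet.network_model import parse_network


def _compiler(doc, **opts):
    net = parse_network(doc)
    return _Compiler(net, CompileOptions(**opts))


PHOSPHO_DOC = ("[reactions]\nid, type, subject, object\n"
               "kp, p+, K, A_[(r)]\n"
               "[contingencies]\ntarget, type, effector\n")

TWO_SITE_DOC = ("[reactions]\nid, type, subject, object\n"
                "kp, p+, K, A_[(r)]\n"
                "b, ppi, A_[d], B_[e]\n"
                "[contingencies]\ntarget, type, effector\n")


class TestStructuralExpressions:
    def test_component_expression_one_residue(self):
        c = _compiler(PHOSPHO_DOC)
        expr = c.component_expression(c.net.components["A"])
        assert repr(expr) == "(A_r_0 | A_r_P)"

    def test_generic_component_is_its_own_state(self):
        c = _compiler(PHOSPHO_DOC)
        assert c.component_expression(c.net.components["K"]) == Ref("K")

    def test_component_expression_two_sites_is_conjunction_of_sites(self):
        c = _compiler(TWO_SITE_DOC)
        expr = c.component_expression(c.net.components["A"])
        assert repr(expr) == "((A_r_0 | A_r_P) & (A_d_ub | A_d_B_e))"

    def test_reacting_components(self):
        c = _compiler(PHOSPHO_DOC)
        expr = c.reacting_components(c.net.reaction("kp"))
        assert repr(expr) == "(K & (A_r_0 | A_r_P))"

    def test_reacting_components_of_sourceless_synthesis_is_true(self):
        c = _compiler(modification_motif_document(
            MotifConfig(True, False, False, False, (False, False))))
        assert c.reacting_components(c.net.reaction("syn")) == TRUE

    def test_carrier_components_of_bond_needs_both_partners(self):
        c = _compiler(TWO_SITE_DOC)
        bond = c.net.states["A_[d]--B_[e]"]
        got = repr(c.carrier_components(bond))
        assert got == ("(((A_r_0 | A_r_P) & (A_d_ub | A_d_B_e))"
                       " & (B_e_ub | A_d_B_e))")

    def test_primed_reaction_adds_source_states(self):
        c = _compiler(PHOSPHO_DOC)
        assert repr(c.primed_reaction(c.net.reaction("kp"))) == "(kp & A_r_0)"


class TestSynthesisTerm:
    def test_neutral_state_synthesis(self):
        c = _compiler(modification_motif_document(
            MotifConfig(True, False, True, False, (False, False))))
        assert repr(c.synthesis_term(c.net.states["A_[(r)]-{0}"])) == "syn"

    def test_modified_state_needs_synthesis_and_production_path(self):
        c = _compiler(modification_motif_document(
            MotifConfig(True, False, True, False, (False, False))))
        got = repr(c.synthesis_term(c.net.states["A_[(r)]-{P}"]))
        assert got == "(syn & (pplus & A_r_0))"

    def test_no_synthesis_route_is_false(self):
        c = _compiler(PHOSPHO_DOC)
        assert c.synthesis_term(c.net.states["A_[(r)]-{P}"]) == FALSE

    def test_deep_synthesis_path_raises(self):
        doc = ("[reactions]\nid, type, subject, object, effects\n"
               "mk, explicit, K, , consume:A_[(r)]-{0};produce:A_[(r)]-{P}\n"
               "mk2, explicit, K, , consume:A_[(r)]-{P};produce:A_[(r)]-{PP}\n"
               "synA, explicit, , , synthesise:A_[(r)]-{0}\n"
               "[contingencies]\ntarget, type, effector\n")
        c = _compiler(doc)
        with pytest.raises(UnsupportedSynthesisDepthError):
            c.synthesis_term(c.net.states["A_[(r)]-{PP}"])


class TestContingencies:
    def test_required_and_inhibitory(self):
        doc = ("[reactions]\nid, type, subject, object\n"
               "kp, p+, K, A_[(r)]\nkq, p+, K, B_[(s)]\n"
               "[contingencies]\ntarget, type, effector\n"
               "kp, !, B_[(s)]-{P}\nkp, x, A_[(r)]-{P}\n")
        c = _compiler(doc)
        assert repr(c.contingency_expression(c.net.reaction("kp"))) == \
            "(B_s_P & !A_r_P)"

    def test_no_contingencies_is_true(self):
        c = _compiler(PHOSPHO_DOC)
        assert c.contingency_expression(c.net.reaction("kp")) == TRUE

    @pytest.mark.parametrize("ctype, policy_field, expected_strict", [
        ("K+", "k_plus_policy", "B_s_P"),
        ("K-", "k_minus_policy", "!B_s_P"),
    ])
    def test_quantitative_policies(self, ctype, policy_field, expected_strict):
        doc = ("[reactions]\nid, type, subject, object\n"
               "kp, p+, K, A_[(r)]\nkq, p+, K, B_[(s)]\n"
               "[contingencies]\ntarget, type, effector\n"
               f"kp, {ctype}, B_[(s)]-{{P}}\n")
        c_ignore = _compiler(doc)
        assert c_ignore.contingency_expression(c_ignore.net.reaction("kp")) \
            == TRUE
        c_strict = _compiler(doc, **{policy_field: "strict"})
        assert repr(
            c_strict.contingency_expression(c_strict.net.reaction("kp"))
        ) == expected_strict

    @pytest.mark.parametrize("ctype", ["0", "?"])
    def test_no_effect_and_unknown_always_dropped(self, ctype):
        doc = ("[reactions]\nid, type, subject, object\n"
               "kp, p+, K, A_[(r)]\nkq, p+, K, B_[(s)]\n"
               "[contingencies]\ntarget, type, effector\n"
               f"kp, {ctype}, B_[(s)]-{{P}}\n")
        c = _compiler(doc, k_plus_policy="strict", k_minus_policy="strict")
        assert c.contingency_expression(c.net.reaction("kp")) == TRUE

    def test_turgor_gated_autophosphorylation(self):
        c = _compiler(hog_document())
        got = repr(c.reaction_update(c.net.reaction("sln1_ap")))
        assert got == "((Sln1_hk_0 | Sln1_hk_P) & Turgor)"

    def test_clamped_reaction_is_constant(self):
        c = _compiler(modification_motif_document(
            MotifConfig(False, False, True, False, (True, False))))
        assert c.reaction_update(c.net.reaction("p+")) == TRUE
        assert c.reaction_update(c.net.reaction("p-")) == FALSE


class TestStateRule:
    def _independent_next(self, fwd, rev, a0, ap):
        """Hand-coded verbal state rule for the pure phosphocycle motif:
        a state persists while its carriers are present and it is not
        consumed; production overrides consumption; no synthesis or
        degradation here."""
        present = a0 or ap
        next_a0 = present and ((rev and ap) or (a0 and not (fwd and a0)))
        next_ap = present and ((fwd and a0) or (ap and not (rev and ap)))
        return next_a0, next_ap

    @pytest.mark.parametrize("fwd, rev",
                             list(itertools.product([False, True], repeat=2)))
    def test_truth_table_matches_independent_oracle(self, fwd, rev):
        cfg = MotifConfig(False, False, fwd, rev, (True, False))
        model = compile_network(modification_motif(cfg),
                                CompileOptions(smoothing=False))
        idx = {t.name: i for i, t in enumerate(model.targets)}
        for a0, ap in itertools.product([False, True], repeat=2):
            v = vector_from_mapping(model, dict(model.initial))
            v = list(v)
            v[idx[MOD_STATES[0]]] = a0
            v[idx[MOD_STATES[1]]] = ap
            nxt = step(model, tuple(v))
            assert (nxt[idx[MOD_STATES[0]]], nxt[idx[MOD_STATES[1]]]) == \
                self._independent_next(fwd, rev, a0, ap)

    def test_state_with_no_acting_reactions_is_gated_persistence(self):
        doc = ("[reactions]\nid, type, subject, object, effects\n"
               "kp, explicit, K, , consume:A_[(r)]-{0};produce:A_[(r)]-{P};"
               "produce:A_[(q)]-{P}\n"
               "[contingencies]\ntarget, type, effector\n")
        c = _compiler(doc)
        # A_[(q)]-{0} is touched by no reaction: rule is K(s) & s.
        got = repr(c.state_update(c.net.states["A_[(q)]-{0}"]))
        assert got == ("(((A_r_0 | A_r_P) & (A_q_P | A_q_0)) & A_q_0)")

    def test_degradation_release_producer_is_guard_primed(self):
        net = interaction_motif(MotifConfig(False, True, False, False,
                                            (False, True, False)))
        c = _Compiler(net, CompileOptions(smoothing=False))
        got = repr(c.state_update(net.states["B_[ad]--0"]))
        # Producer term must be (deg & A--B): the release fires only
        # while the dimer exists.
        assert "(deg & A_bd_B_ad)" in got

    def test_smoothed_producer_widens_source_window(self):
        cfg = MotifConfig(False, False, True, True, (True, False))
        net = modification_motif(cfg)
        c = _Compiler(net, CompileOptions(smoothing=True))
        unsmoothed = {c.symbol_of[s.name]: c.state_update(s)
                      for s in net.states.values()}
        kp = net.reaction("p+")
        effect = next(e for e in kp.effects if e.state.name == MOD_STATES[1])
        got = repr(c.smoothed_producer(kp, effect, unsmoothed))
        assert got.startswith("(pplus & (A_r_0 | ")
        # the expansion embeds the full non-smoothed rule of the source
        assert repr(unsmoothed[c.symbol_of[MOD_STATES[0]]]) in got

    def test_producerless_smoothed_producer_is_reaction_alone(self):
        doc = ("[reactions]\nid, type, subject, object, effects\n"
               "mk, explicit, , , produce:A_[(r)]-{P}\n"
               "[contingencies]\ntarget, type, effector\n")
        c = _compiler(doc)
        mk = c.net.reaction("mk")
        (effect,) = mk.effects
        assert repr(c.smoothed_producer(mk, effect, {})) == "mk"


class TestCompile:
    def test_modification_motif_target_counts(self):
        model = compile_network(modification_motif(
            MotifConfig(True, True, True, True, (True, False))))
        assert len(model.targets_of_kind("reaction")) == 4
        assert len(model.targets_of_kind("state")) == 2

    def test_interaction_motif_target_counts(self):
        model = compile_network(interaction_motif(
            MotifConfig(True, True, True, True, (True, False, True))))
        assert len(model.targets_of_kind("reaction")) == 4
        assert len(model.targets_of_kind("state")) == 3

    def test_compile_is_deterministic(self):
        doc = hog_document(cyclic=True)
        t1 = boolnet_text(compile_network(parse_network(doc)))
        t2 = boolnet_text(compile_network(parse_network(doc)))
        assert t1 == t2

    def test_identity_input_self_update(self):
        model = compile_network(parse_network(hog_document(cyclic=False)))
        assert model.rules[model.symbol_of["[Turgor]"]] == \
            Ref(model.symbol_of["[Turgor]"])

    def test_output_link_overrides_input_identity(self):
        model = compile_network(parse_network(hog_document(cyclic=True)))
        assert model.rules[model.symbol_of["[Turgor]"]] == \
            Ref(model.symbol_of["Hot1_[(s)]-{P}"])

    def test_default_initial_state(self):
        model = compile_network(parse_network(hog_document()))
        net = parse_network(hog_document())
        init = default_initial_state(model, net)
        by_name = {t.name: init[t.symbol] for t in model.targets}
        assert by_name["Sln1_[(hk)]-{0}"] is True
        assert by_name["Sln1_[(hk)]-{P}"] is False
        assert by_name["Ssk1_[ri]--0"] is True
        assert by_name["Ssk1_[ri]--Ssk2_[n]"] is False
        assert by_name["Ptc"] is True  # generic component
        assert by_name["[Turgor]"] is False
        assert by_name["sln1_ap"] is False

    def test_symbols_are_identifiers_and_unique(self):
        model = compile_network(parse_network(hog_document(cyclic=True)))
        syms = model.symbols
        assert len(set(syms)) == len(syms)
        for s in syms:
            assert s.isidentifier()

    def test_symbol_collision_gets_suffix(self):
        assert sanitise_symbol("A_[(r)]-{P}") == sanitise_symbol("A_[r]--P")
        doc = ("[reactions]\nid, type, subject, object\n"
               "kp, p+, K, A_[(r)]\nb, ppi, A_[r], P_[x]\n"
               "[contingencies]\ntarget, type, effector\n")
        model = compile_network(parse_network(doc))
        assert len(set(model.symbols)) == len(model.symbols)


class TestStructuralInvariants:
    """Gate properties of the compiled state rule, probed over random
    vectors of real fixture models."""

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**40 - 1), st.integers(0, 63))
    def test_states_need_carriers_or_synthesis(self, bits, cfg_bits):
        b = [bool(cfg_bits >> i & 1) for i in range(6)]
        cfg = MotifConfig(b[0], b[1], b[2], b[3], (b[4], b[5]))
        net = modification_motif(cfg)
        c = _Compiler(net, CompileOptions(smoothing=False))
        model = c.compile()
        v = tuple(bool(bits >> i & 1) for i in range(len(model.targets)))
        env = {t.symbol: val for t, val in zip(model.targets, v)}
        nxt = step(model, v)
        idx = {t.name: i for i, t in enumerate(model.targets)}
        for s in net.states.values():
            sigma = c.synthesis_term(s).evaluate(env)
            carriers = c.carrier_components(s).evaluate(env)
            if sigma:
                # synthesis dominance: a synthesised state turns true
                assert nxt[idx[s.name]] is True
            elif not carriers:
                # monotone gate: no carriers and no synthesis -> false
                assert nxt[idx[s.name]] is False
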
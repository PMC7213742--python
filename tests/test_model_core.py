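"""Single-model layer: I/O round trips, media, gene rules, FBA/FVA/deletions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import cobra
from cobra.core.gene import GPR

from gemble import (
    GeneRuleSyntaxError,
    ModelFormatError,
    ObjectiveConfigurationError,
    evaluate_gene_rule,
    optimize_fba,
    read_model,
    run_fva,
    run_single_deletions,
    set_medium,
    write_model,
)
from gemble.fixtures import FixtureSpec, make_toy_model

from _oracles import enumerate_fba_optimum


def _models_equal(a, b):
    if len(a.reactions) != len(b.reactions):
        return False
    for reaction in a.reactions:
        other = b.reactions.get_by_id(reaction.id)
        if reaction.bounds != other.bounds:
            return False
        if {m.id: c for m, c in reaction.metabolites.items()} != {
            m.id: c for m, c in other.metabolites.items()
        }:
            return False
    return True


class TestModelIO:
    @pytest.mark.parametrize("format", ["sbml", "json"])
    def test_round_trip_preserves_network(self, toy_model_2src, tmp_path, format):
        path = tmp_path / f"toy.{'xml' if format == 'sbml' else 'json'}"
        write_model(toy_model_2src, path, format=format)
        restored = read_model(path, format=format)
        assert _models_equal(toy_model_2src, restored)
        assert (
            restored.reactions.get_by_id("CONV_C1").gene_reaction_rule
            == toy_model_2src.reactions.get_by_id("CONV_C1").gene_reaction_rule
        )

    def test_cross_format_fba_objective_agrees(self, toy_model_2src, tmp_path):
        write_model(toy_model_2src, tmp_path / "toy.xml", format="sbml")
        write_model(toy_model_2src, tmp_path / "toy.json", format="json")
        from_sbml = optimize_fba(read_model(tmp_path / "toy.xml"))
        from_json = optimize_fba(read_model(tmp_path / "toy.json"))
        assert from_sbml.objective_value == pytest.approx(
            from_json.objective_value, abs=1e-6
        )

    def test_empty_gene_rule_round_trips_empty(self, toy_model, tmp_path):
        assert toy_model.reactions.get_by_id("BIOMASS").gene_reaction_rule == ""
        write_model(toy_model, tmp_path / "toy.xml")
        restored = read_model(tmp_path / "toy.xml")
        assert restored.reactions.get_by_id("BIOMASS").gene_reaction_rule == ""

    def test_negative_bounds_preserved_exactly(self, toy_model, tmp_path):
        toy_model.reactions.get_by_id("EX_C1").bounds = (-1000.0, 1000.0)
        write_model(toy_model, tmp_path / "toy.xml")
        restored = read_model(tmp_path / "toy.xml")
        assert restored.reactions.get_by_id("EX_C1").bounds == (-1000.0, 1000.0)

    def test_sbml_without_explicit_bounds_rejected(self, tmp_path):
        # SBML Level 2: no fbc flux bounds anywhere
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="nobounds">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies><species id="A" compartment="c"/></listOfSpecies>
  <listOfReactions>
   <reaction id="R1"><listOfReactants>
    <speciesReference species="A"/></listOfReactants></reaction>
  </listOfReactions>
 </model>
</sbml>"""
        path = tmp_path / "nobounds.xml"
        path.write_text(sbml)
        with pytest.raises(ModelFormatError, match="bounds"):
            read_model(path, format="sbml")

    def test_undeclared_metabolite_is_a_format_error(self, toy_model, tmp_path):
        import json

        write_model(toy_model, tmp_path / "toy.json", format="json")
        document = json.loads((tmp_path / "toy.json").read_text())
        document["reactions"][0]["metabolites"]["GHOST_c"] = -1.0
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(document))
        with pytest.raises(ModelFormatError):
            read_model(bad, format="json")


class TestMedium:
    def test_listed_exchange_opens_and_fba_follows(self, toy_model):
        set_medium(toy_model, {"EX_C1": 5.0})
        assert toy_model.reactions.get_by_id("EX_C1").lower_bound == -5.0
        assert optimize_fba(toy_model).objective_value == pytest.approx(5.0, abs=1e-6)

    def test_unlisted_exchanges_closed(self, toy_model_2src):
        set_medium(toy_model_2src, {"EX_C1": 10.0})
        assert toy_model_2src.reactions.get_by_id("EX_C2").lower_bound == 0.0
        # upper (secretion) bounds untouched
        assert toy_model_2src.reactions.get_by_id("EX_C2").upper_bound == 1000.0
        assert optimize_fba(toy_model_2src).objective_value == pytest.approx(
            10.0, abs=1e-6
        )

    def test_empty_medium_closes_everything(self, toy_model):
        set_medium(toy_model, {})
        assert optimize_fba(toy_model).objective_value == pytest.approx(0.0, abs=1e-6)

    def test_unknown_exchange_raises_key_error(self, toy_model):
        with pytest.raises(KeyError, match="NOT_AN_EXCHANGE"):
            set_medium(toy_model, {"NOT_AN_EXCHANGE": 10.0})

    def test_internal_reaction_is_not_an_exchange(self, toy_model):
        with pytest.raises(KeyError):
            set_medium(toy_model, {"T_C1": 10.0})


class TestGeneRules:
    @pytest.mark.parametrize(
        "rule,deleted,expected",
        [
            ("g1 and g2", {"g1"}, False),
            ("(g1 and g2) or g3", {"g1"}, True),
            ("", {"g1", "g2"}, True),
            ("g1 or g2", {"g1", "g2"}, False),
            ("G1 AND g2", set(), True),  # keywords case-insensitive
            ("g1 and (g2 or g3)", {"g2", "g3"}, False),
        ],
    )
    def test_rule_evaluation(self, rule, deleted, expected):
        assert evaluate_gene_rule(rule, deleted) is expected

    @pytest.mark.parametrize("rule", ["g1 and", "(g1 or g2", "g1 g2", "and g1"])
    def test_malformed_rule_reports_position(self, rule):
        with pytest.raises(GeneRuleSyntaxError) as excinfo:
            evaluate_gene_rule(rule, set())
        assert excinfo.value.position >= 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_rules_agree_with_reference_evaluator(self, data):
        """Random AND/OR trees evaluate like cobra's GPR implementation."""
        genes = [f"g{i}" for i in range(5)]

        def tree(depth):
            if depth == 0 or data.draw(st.booleans()):
                return data.draw(st.sampled_from(genes))
            op = data.draw(st.sampled_from(["and", "or"]))
            return f"({tree(depth - 1)} {op} {tree(depth - 1)})"

        rule = tree(3)
        deleted = set(data.draw(st.lists(st.sampled_from(genes), max_size=5)))
        expected = GPR.from_string(rule).eval(knockouts=deleted)
        assert evaluate_gene_rule(rule, deleted) == expected


class TestFBA:
    def test_toy_chain_matches_vertex_enumeration(self, toy_model):
        solution = optimize_fba(toy_model)
        assert solution.status == "optimal"
        assert solution.objective_value == pytest.approx(10.0, abs=1e-6)
        assert solution.objective_value == pytest.approx(
            enumerate_fba_optimum(toy_model), abs=1e-6
        )

    def test_no_uptake_no_growth(self, toy_model):
        toy_model.reactions.get_by_id("EX_C1").lower_bound = 0.0
        assert optimize_fba(toy_model).objective_value == pytest.approx(0.0, abs=1e-6)

    def test_forced_dead_end_flux_is_infeasible(self, toy_model):
        dead = cobra.Metabolite("DEADX_c", compartment="c")
        reaction = cobra.Reaction("DEADRXN", lower_bound=1.0, upper_bound=10.0)
        reaction.add_metabolites(
            {toy_model.metabolites.get_by_id("C1_c"): -1, dead: 1}
        )
        toy_model.add_reactions([reaction])
        toy_model.reactions.get_by_id("EX_C1").lower_bound = 0.0
        assert optimize_fba(toy_model).status == "infeasible"

    def test_mass_balance_and_bounds_hold_at_optimum(self, toy_model_2src):
        solution = optimize_fba(toy_model_2src)
        for reaction in toy_model_2src.reactions:
            flux = solution.fluxes[reaction.id]
            assert reaction.lower_bound - 1e-6 <= flux <= reaction.upper_bound + 1e-6
        for metabolite in toy_model_2src.metabolites:
            net = sum(
                coeff * solution.fluxes[r.id]
                for r in metabolite.reactions
                for m, coeff in r.metabolites.items()
                if m is metabolite
            )
            assert abs(net) <= 1e-6

    def test_empty_objective_is_a_configuration_error(self, toy_model):
        toy_model.objective = {}
        with pytest.raises(ObjectiveConfigurationError):
            optimize_fba(toy_model)


class TestFVA:
    def test_saturated_chain_pins_uptake(self, toy_model):
        table = run_fva(toy_model, fraction_of_optimum=1.0, reactions=["EX_C1"])
        assert table.at["EX_C1", "minimum"] == pytest.approx(-10.0, abs=1e-6)
        assert table.at["EX_C1", "maximum"] == pytest.approx(-10.0, abs=1e-6)

    def test_relaxed_objective_frees_uptake(self, toy_model):
        table = run_fva(toy_model, fraction_of_optimum=0.0, reactions=["EX_C1"])
        assert table.at["EX_C1", "minimum"] == pytest.approx(-10.0, abs=1e-6)
        assert table.at["EX_C1", "maximum"] == pytest.approx(0.0, abs=1e-6)

    def test_blocked_reaction_has_zero_range(self, toy_model):
        dead = cobra.Metabolite("DEADY_c", compartment="c")
        reaction = cobra.Reaction("BLOCKED", lower_bound=0.0, upper_bound=10.0)
        reaction.add_metabolites(
            {toy_model.metabolites.get_by_id("C1_c"): -1, dead: 1}
        )
        toy_model.add_reactions([reaction])
        table = run_fva(toy_model, fraction_of_optimum=0.0, reactions=["BLOCKED"])
        assert table.at["BLOCKED", "minimum"] == pytest.approx(0.0, abs=1e-6)
        assert table.at["BLOCKED", "maximum"] == pytest.approx(0.0, abs=1e-6)

    def test_fba_flux_inside_fva_envelope(self, toy_model_2src):
        solution = optimize_fba(toy_model_2src)
        table = run_fva(toy_model_2src, fraction_of_optimum=1.0)
        for rid in table.index:
            assert (
                table.at[rid, "minimum"] - 1e-6
                <= solution.fluxes[rid]
                <= table.at[rid, "maximum"] + 1e-6
            )


class TestDeletions:
    def test_sole_conversion_is_essential(self, toy_model):
        table = run_single_deletions(toy_model, "reaction", ["CONV_C1"])
        assert table.at["CONV_C1", "growth"] == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_pathway_is_redundant(self, toy_model):
        twin = toy_model.reactions.get_by_id("CONV_C1").copy()
        twin.id = "CONV_C1_copy"
        toy_model.add_reactions([twin])
        table = run_single_deletions(toy_model, "reaction", ["CONV_C1"])
        # independent check: FBA on a model with the reaction structurally gone
        edited = toy_model.copy()
        edited.remove_reactions([edited.reactions.get_by_id("CONV_C1")])
        assert table.at["CONV_C1", "growth"] == pytest.approx(
            optimize_fba(edited).objective_value, abs=1e-6
        )
        assert table.at["CONV_C1", "growth"] == pytest.approx(10.0, abs=1e-6)

    def test_or_redundant_gene_deletion_harmless(self, toy_model):
        # CONV_C1 carries rule "g_c1a or g_c1b"
        table = run_single_deletions(toy_model, "gene", ["g_c1a"])
        assert table.at["g_c1a", "growth"] == pytest.approx(10.0, abs=1e-6)

    def test_transporter_gene_is_essential(self, toy_model):
        table = run_single_deletions(toy_model, "gene", ["g_t1"])
        assert table.at["g_t1", "growth"] == pytest.approx(0.0, abs=1e-6)

    def test_bounds_restored_after_deletions(self, toy_model_2src):
        before = {r.id: r.bounds for r in toy_model_2src.reactions}
        run_single_deletions(toy_model_2src, "reaction")
        run_single_deletions(toy_model_2src, "gene")
        assert {r.id: r.bounds for r in toy_model_2src.reactions} == before

    def test_unknown_target_raises_key_error(self, toy_model):
        with pytest.raises(KeyError):
            run_single_deletions(toy_model, "reaction", ["NOPE"])
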
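"""SNF objective construction, coupling behaviour and the symbiotic medium."""

import pytest

from snfba import (Metabolite, Model, ObjectiveSpec, Reaction, ReactionKind,
                   apply_symbiotic_medium, build_nitrogenase_reaction,
                   build_nutrient_sharing_reaction, default_snf_medium,
                   flux_variability, load_medium, save_medium, solve_fba,
                   NITROGENASE_ID, NUTRIENT_SHARING_ID)
from snfba.gpr import reactions_disabled_by
from snfba.snf import DEFAULT_SPECIES
from snfba.synthetic import (ToyModelConfig, generate_toy_snf_model,
                             surplus_carbon_medium)


def currency_model():
    """Minimal cytosolic currency world for building nitrogenase alone."""
    m = Model(id="currency")
    for key in ("atp", "adp", "pi", "h2o", "fdred", "fdox", "n2", "h", "nh3"):
        m.add_metabolite(Metabolite(id=DEFAULT_SPECIES[key], compartment="c"))
    return m


class TestNitrogenase:
    def test_printed_stoichiometry_exact(self):
        m = build_nitrogenase_reaction(currency_model())
        s = m.reaction(NITROGENASE_ID).stoichiometry
        assert s == {"atp[c]": -16, "fdred[c]": -6, "h2o[c]": -16,
                     "n2[c]": -1, "adp[c]": 16, "fdox[c]": 6, "h[c]": 8,
                     "nh3fix[c]": 2, "pi[c]": 16}

    def test_atp_per_ammonia_is_eight(self):
        m = build_nitrogenase_reaction(currency_model())
        s = m.reaction(NITROGENASE_ID).stoichiometry
        assert -s["atp[c]"] / s["nh3fix[c]"] == pytest.approx(8.0)

    def test_ferredoxin_is_conserved(self):
        m = build_nitrogenase_reaction(currency_model())
        s = m.reaction(NITROGENASE_ID).stoichiometry
        assert -s["fdred[c]"] == s["fdox[c]"] == 6

    def test_missing_substrates_listed(self):
        m = currency_model()
        m.metabolites = [x for x in m.metabolites
                         if x.id not in ("fdred[c]", "n2[c]")]
        with pytest.raises(ValueError) as err:
            build_nitrogenase_reaction(m)
        assert "fdred[c]" in str(err.value) and "n2[c]" in str(err.value)

    def test_atp_capped_at_16_fixes_2_ammonia(self):
        """With ATP supply limited to 16 mmol/gDW/hr, the printed 16:2
        stoichiometry caps fixed-ammonia output at 2 mmol/gDW/hr."""
        m = build_nitrogenase_reaction(currency_model())
        # free supplies/sinks for everything except ATP, which is capped
        m.add_reaction(Reaction(id="ATPS",
                                stoichiometry={"adp[c]": -1, "pi[c]": -1,
                                               "atp[c]": 1},
                                upper_bound=16.0))
        for met in ("h2o[c]", "n2[c]"):
            m.add_reaction(Reaction(id=f"SRC_{met[:-3]}",
                                    stoichiometry={met: 1},
                                    upper_bound=1000))
        for met in ("h[c]", "fdox[c]"):
            m.add_reaction(Reaction(id=f"SNK_{met[:-3]}",
                                    stoichiometry={met: -1},
                                    upper_bound=1000))
        m.add_reaction(Reaction(id="FDRED",
                                stoichiometry={"fdox[c]": -1, "fdred[c]": 1},
                                upper_bound=1000))
        m.add_reaction(Reaction(id="OF_nh3",
                                stoichiometry={"nh3fix[c]": -1},
                                upper_bound=1000,
                                kind=ReactionKind.OBJECTIVE_PSEUDO))
        m.objective_reaction_ids = ["OF_nh3"]
        sol = solve_fba(m)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(2.0, abs=1e-8)


class TestNutrientSharing:
    def test_cofactor_coefficient_is_one_percent(self, toy_model):
        s = toy_model.reaction(NUTRIENT_SHARING_ID).stoichiometry
        assert s["cofact[c]"] == pytest.approx(-0.01)

    def test_all_other_coefficients_are_unit(self, toy_model):
        s = toy_model.reaction(NUTRIENT_SHARING_ID).stoichiometry
        for met, coef in s.items():
            if met != "cofact[c]":
                assert abs(coef) == pytest.approx(1.0), met

    def test_nitrogenase_knockout_abolishes_objective(self, toy_model):
        for rid in reactions_disabled_by(toy_model, {"nifD"}):
            rxn = toy_model.reaction(rid)
            rxn.lower_bound = rxn.upper_bound = 0.0
        sol = solve_fba(toy_model)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_missing_species_listed(self):
        m = build_nitrogenase_reaction(currency_model())
        with pytest.raises(ValueError) as err:
            build_nutrient_sharing_reaction(m, ObjectiveSpec())
        assert "ala[c]" in str(err.value)

    def test_removing_any_cofactor_branch_zeroes_objective(self, toy_model):
        # the pool is an AND over components: losing any branch is fatal
        for gene in ("hemA", "iscU", "modA", "hcoT", "pdxA", "cobA", "thiC",
                     "gshB"):
            m = toy_model.copy()
            for rid in reactions_disabled_by(m, {gene}):
                rxn = m.reaction(rid)
                rxn.lower_bound = rxn.upper_bound = 0.0
            assert solve_fba(m).objective_value == pytest.approx(
                0.0, abs=1e-8), gene

    def test_weighted_sum_mode_still_coupled(self):
        """The 1:1 weighted-sum objective may divert flux into surplus
        nitrogen fixation (the two modes are reported, not reconciled), but
        the structural pool coupling holds in its optimum too, and the
        pool-mode solution bounds it from below."""
        model, _ = generate_toy_snf_model(ToyModelConfig())
        pool_v = solve_fba(model).fluxes[NUTRIENT_SHARING_ID]
        model.objective_reaction_ids = [NUTRIENT_SHARING_ID, NITROGENASE_ID]
        sol = solve_fba(model)
        assert sol.optimal
        assert sol.fluxes[NUTRIENT_SHARING_ID] <= \
            2 * sol.fluxes[NITROGENASE_ID] + 1e-9
        # pool-mode optimum is feasible for the weighted objective
        assert sol.objective_value >= 1.5 * pool_v - 1e-9


class TestMedium:
    def test_shipped_rates_bit_exact(self, toy_model):
        apply_symbiotic_medium(toy_model, default_snf_medium())
        assert toy_model.reaction("EX_mal_e").lower_bound == -1.112
        assert toy_model.reaction("EX_o2_e").lower_bound == -1.26
        assert toy_model.reaction("EX_inost_e").lower_bound == -0.01
        # glutamate freely exchanged, ammonia/amino-acid export open
        assert toy_model.reaction("EX_glu_e").lower_bound == -1000.0
        assert toy_model.reaction("EX_nh3_e").lower_bound == 0.0

    def test_succinate_source_rate_and_malate_closed(self, toy_model):
        apply_symbiotic_medium(toy_model,
                               default_snf_medium(carbon_source="succinate"))
        assert toy_model.reaction("EX_succ_e").lower_bound == -1.326
        assert toy_model.reaction("EX_mal_e").lower_bound == 0.0

    def test_unknown_exchange_named(self, toy_model):
        medium = default_snf_medium()
        medium.bounds["EX_ghost_e"] = (-1.0, 1.0)
        with pytest.raises(KeyError, match="EX_ghost_e"):
            apply_symbiotic_medium(toy_model, medium)

    def test_medium_yaml_round_trip(self, tmp_path):
        medium = default_snf_medium()
        path = tmp_path / "medium.yaml"
        save_medium(medium, str(path))
        back = load_medium(str(path))
        assert back.bounds == medium.bounds
        assert back.carbon_source == medium.carbon_source

    def test_glutamate_only_sustains_fixation(self):
        model, _ = generate_toy_snf_model(
            ToyModelConfig(carbon_source="glutamate_only"))
        assert model.reaction("EX_mal_e").lower_bound == 0.0
        assert model.reaction("EX_succ_e").lower_bound == 0.0
        sol = solve_fba(model)
        assert sol.optimal and sol.objective_value > 1e-3


class TestCouplingInvariants:
    def test_ammonia_provenance_under_default_and_surplus(self):
        """Exported ammonia never exceeds twice the nitrogenase flux."""
        for medium in (None, surplus_carbon_medium()):
            model, _ = generate_toy_snf_model()
            if medium is not None:
                medium.bounds = {k: v for k, v in medium.bounds.items()
                                 if model.has_reaction(k)}
                apply_symbiotic_medium(model, medium)
            sol = solve_fba(model)
            assert sol.optimal
            exported = sol.fluxes[NUTRIENT_SHARING_ID]
            assert exported <= 2 * sol.fluxes[NITROGENASE_ID] + 1e-9

    def test_surplus_carbon_permits_glutamate_efflux(self):
        model, _ = generate_toy_snf_model()
        medium = surplus_carbon_medium()
        medium.bounds = {k: v for k, v in medium.bounds.items()
                         if model.has_reaction(k)}
        apply_symbiotic_medium(model, medium)
        fr = flux_variability(model, 1.0, reaction_ids=["EX_glu_e"])[0]
        assert fr.max_flux > 1e-6, \
            "efflux should be possible at the surplus-carbon optimum"

    def test_default_medium_imports_glutamate(self):
        model, _ = generate_toy_snf_model()
        sol = solve_fba(model)
        assert sol.fluxes["EX_glu_e"] < 0
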
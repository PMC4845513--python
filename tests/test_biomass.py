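"""Biomass compositions: normalization, producibility, assembly, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytoflux import lp_core
from phytoflux.biomass import (
    BiomassComponent,
    BiomassComposition,
    GAMRecipe,
    build_biomass_reaction,
    carbon_fraction,
    class_weight_percent,
    intersect_components,
    normalize_by_weight,
    producible,
    read_composition,
    remove_biomass_reaction,
    weight_fraction,
    write_composition,
)
from phytoflux.model_io import MetabolicModel, Metabolite, Reaction
from phytoflux.synthetic_models import ToySpec, make_toy


@pytest.fixture
def two_component():
    return BiomassComposition(
        id="pair",
        components=[
            BiomassComponent("glc", 2.0, "carbohydrate", molecular_weight=180.0,
                             carbon_atoms=6),
            BiomassComponent("aa", 1.0, "protein", molecular_weight=120.0,
                             carbon_atoms=3),
        ],
    )


class TestNormalization:
    def test_hand_arithmetic(self, two_component):
        # mass = 2*0.180 + 1*0.120 = 0.48 g -> k = 1/0.48
        norm = normalize_by_weight(two_component)
        assert norm.component("glc").coefficient == pytest.approx(2 / 0.48)
        assert norm.component("aa").coefficient == pytest.approx(1 / 0.48)
        assert norm.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, two_component):
        once = normalize_by_weight(two_component)
        twice = normalize_by_weight(once)
        for a, b in zip(once.components, twice.components):
            assert b.coefficient == pytest.approx(a.coefficient, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, scale):
        two_component = BiomassComposition(
            id="pair",
            components=[
                BiomassComponent("glc", 2.0, "carbohydrate", molecular_weight=180.0),
                BiomassComponent("aa", 1.0, "protein", molecular_weight=120.0),
            ],
        )
        scaled = two_component.copy()
        for c in scaled.components:
            c.coefficient *= scale
        a = normalize_by_weight(two_component)
        b = normalize_by_weight(scaled)
        for ca, cb in zip(a.components, b.components):
            assert cb.coefficient == pytest.approx(ca.coefficient, rel=1e-9)

    def test_gam_rescaled_only_on_request(self, two_component):
        two_component.gam = 10.0
        assert normalize_by_weight(two_component).gam == 10.0
        rescaled = normalize_by_weight(two_component, rescale_gam=True)
        assert rescaled.gam == pytest.approx(10.0 / 0.48)

    def test_missing_or_zero_mw_rejected(self):
        comp = BiomassComposition(
            id="bad", components=[BiomassComponent("x", 1.0, "other")]
        )
        with pytest.raises(ValueError, match="molecular weight"):
            normalize_by_weight(comp)
        comp2 = BiomassComposition(
            id="bad2",
            components=[BiomassComponent("x", 1.0, "other", molecular_weight=0.0)],
        )
        with pytest.raises(ValueError):
            normalize_by_weight(comp2)

    def test_mw_table_fills_gaps(self):
        comp = BiomassComposition(
            id="gap", components=[BiomassComponent("x", 1.0, "other")]
        )
        norm = normalize_by_weight(comp, mw_table={"x": 500.0})
        assert norm.total_mass() == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def test_class_weight_percent_derived(self, two_component):
        pct = class_weight_percent(two_component)
        assert pct["carbohydrate"] == pytest.approx(75.0)
        assert pct["protein"] == pytest.approx(25.0)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_class_is_100(self):
        comp = BiomassComposition(
            id="solo",
            components=[BiomassComponent("x", 3.0, "lipid", molecular_weight=250.0)],
        )
        assert class_weight_percent(comp) == {"lipid": pytest.approx(100.0)}

    def test_percentages_invariant_under_rescaling(self, two_component):
        scaled = two_component.copy()
        for c in scaled.components:
            c.coefficient *= 7.3
        assert class_weight_percent(scaled)["protein"] == pytest.approx(
            class_weight_percent(two_component)["protein"]
        )

    def test_carbon_fraction_arithmetic(self):
        comp = BiomassComposition(
            id="cf",
            components=[
                BiomassComponent("a", 1.0, "other", carbon_atoms=6),
                BiomassComponent("b", 1.0, "other", carbon_atoms=3),
            ],
        )
        f = carbon_fraction(comp)
        assert f["a"] == pytest.approx(2 / 3)
        assert f["b"] == pytest.approx(1 / 3)
        assert sum(f.values()) == pytest.approx(1.0)

    def test_carbon_fraction_scale_invariant(self):
        comp = BiomassComposition(
            id="cf",
            components=[
                BiomassComponent("a", 0.4, "other", carbon_atoms=6),
                BiomassComponent("b", 1.1, "other", carbon_atoms=3),
            ],
        )
        scaled = comp.copy()
        for c in scaled.components:
            c.coefficient *= 42.0
        assert carbon_fraction(scaled) == pytest.approx(carbon_fraction(comp))

    def test_all_zero_carbon_rejected(self):
        comp = BiomassComposition(
            id="noc",
            components=[BiomassComponent("a", 1.0, "other", carbon_atoms=0)],
        )
        with pytest.raises(ValueError, match="carbon"):
            carbon_fraction(comp)

    def test_weight_fraction_sums_to_one(self, two_component):
        assert sum(weight_fraction(two_component).values()) == pytest.approx(1.0)


class TestProducibility:
    def test_energy_producible_with_open_uptake(self, toy1):
        assert producible(toy1.model, "E")

    def test_nothing_enters_when_uptake_closed(self, toy1):
        from phytoflux.model_io import set_bounds

        closed = set_bounds(toy1.model, "EX_G", 0.0, 0.0)
        relaxed = set_bounds(closed, "NGAM", 0.0, 0.0)
        assert not producible(relaxed, "E")

    def test_metabolite_with_no_producing_reaction(self, toy1):
        model = toy1.model.copy()
        model.metabolites.append(Metabolite(id="INERT"))
        model.reactions.append(
            Reaction(id="sink_inert", stoichiometry={"INERT": -1}, lower_bound=0)
        )
        assert not producible(model, "INERT")

    def test_unknown_metabolite_raises(self, toy1):
        with pytest.raises(KeyError):
            producible(toy1.model, "GHOST")


class TestIntersection:
    def _trio(self):
        nets = [make_toy(ToySpec(), model_id=f"m{i}") for i in range(3)]
        # model m2 gets an extra metabolite that only IT can produce
        special = nets[2].model.copy()
        special.metabolites.append(Metabolite(id="S_only"))
        special.reactions.append(
            Reaction(id="make_S", stoichiometry={"E": -1, "S_only": 1}, lower_bound=0)
        )
        special.reactions.append(
            Reaction(id="EX_S_only", stoichiometry={"S_only": -1}, lower_bound=0,
                     is_exchange=True)
        )
        models = [nets[0].model, nets[1].model, special]
        comp = BiomassComposition(
            id="joint",
            components=[
                BiomassComponent("G", 0.5, "carbohydrate"),
                BiomassComponent("E", 1.0, "other"),
                BiomassComponent("S_only", 0.1, "soluble"),
            ],
        )
        return models, comp

    def test_exactly_one_component_fails_in_some_models(self):
        models, comp = self._trio()
        common, exclusions = intersect_components([comp], models)
        assert common == {"G", "E"}
        assert exclusions["m2"] == []
        assert "S_only" in exclusions["m0"]
        assert "S_only" in exclusions["m1"]

    def test_full_intersection_when_all_producible(self, toy1):
        common, exclusions = intersect_components([toy1.composition], [toy1.model])
        assert common == {"G", "E"}
        assert exclusions == {"toy1": []}

    def test_order_invariance(self):
        models, comp = self._trio()
        a, _ = intersect_components([comp], models)
        b, _ = intersect_components([comp], models[::-1])
        assert a == b


class TestBiomassReaction:
    def test_column_entries(self, toy1):
        S, rows, cols, _, _ = toy1.model.to_arrays()
        j = cols.index("Biomass")
        col = {rows[i]: S[i, j] for i in range(len(rows)) if S[i, j] != 0}
        assert col == {"G": -0.5, "E": -1.0, "biomass": 1.0}

    def test_gam_zero_adds_no_atp_terms(self, toy1):
        rebuilt = build_biomass_reaction(
            remove_biomass_reaction(toy1.model), toy1.composition,
            energy=GAMRecipe(atp="E"),
        )
        st = rebuilt.reaction("Biomass").stoichiometry
        assert st["E"] == -1.0  # only the component term, no extra hydrolysis

    def test_gam_consumes_energy_currency(self, toy1):
        comp = toy1.composition.copy()
        comp.gam = 2.5
        rebuilt = build_biomass_reaction(
            remove_biomass_reaction(toy1.model), comp, energy=GAMRecipe(atp="E")
        )
        assert rebuilt.reaction("Biomass").stoichiometry["E"] == -(1.0 + 2.5)

    def test_gam_without_recipe_rejected(self, toy1):
        comp = toy1.composition.copy()
        comp.gam = 1.0
        with pytest.raises(ValueError, match="gam"):
            build_biomass_reaction(remove_biomass_reaction(toy1.model), comp)

    def test_missing_component_metabolite_named(self, toy1):
        comp = BiomassComposition(
            id="ghostly", components=[BiomassComponent("GHOST", 1.0, "other")]
        )
        with pytest.raises(KeyError, match="GHOST"):
            build_biomass_reaction(toy1.model, comp)

    def test_remove_restores_original_exactly(self, toy1):
        stripped = remove_biomass_reaction(toy1.model)
        rebuilt = build_biomass_reaction(stripped, toy1.composition)
        assert remove_biomass_reaction(rebuilt).structurally_equal(stripped)

    def test_swapping_bof_changes_only_biomass_column(self, toy1):
        other = BiomassComposition(
            id="otherBOF",
            components=[
                BiomassComponent("G", 1.0, "carbohydrate"),
                BiomassComponent("E", 0.5, "other"),
            ],
        )
        swapped = build_biomass_reaction(toy1.model, other)
        S0, rows0, cols0, _, _ = toy1.model.to_arrays()
        S1, rows1, cols1, _, _ = swapped.to_arrays()
        assert rows0 == rows1 and cols0 == cols1
        j = cols0.index("Biomass")
        mask = np.ones(len(cols0), dtype=bool)
        mask[j] = False
        assert (S0[:, mask] == S1[:, mask]).all()
        assert not (S0[:, j] == S1[:, j]).all()


class TestIO:
    def test_tsv_roundtrip(self, two_component, tmp_path):
        path = tmp_path / "bof.tsv"
        write_composition(two_component, path)
        back = read_composition(path, id="pair")
        assert back.component_ids == two_component.component_ids
        for a, b in zip(two_component.components, back.components):
            assert b.coefficient == a.coefficient
            assert b.molecular_weight == a.molecular_weight
            assert b.carbon_atoms == a.carbon_atoms
            assert b.macro_class == a.macro_class

    def test_growth_objective_solves_after_roundtrip(self, toy1, tmp_path):
        path = tmp_path / "toy_bof.tsv"
        write_composition(toy1.composition, path)
        comp = read_composition(path)
        rebuilt = build_biomass_reaction(remove_biomass_reaction(toy1.model), comp)
        assert lp_core.solve_fba(rebuilt).objective_value == pytest.approx(11.2, abs=1e-8)
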
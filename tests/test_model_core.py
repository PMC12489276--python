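import json

import pytest

from algaegem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_condition,
    attach_media,
    fba,
    optimize_flux,
    read_model,
    split_reversible,
    standard_condition,
    write_model,
)
from algaegem.io import ModelParseError, model_from_dict, model_to_dict
from algaegem.model import ConfigurationError, ModelValidationError
from algaegem.synthetic import ToySpec, make_random_model


def toy_two_reactions():
    m = MetabolicModel(id="toy", compartments=["c", "e"])
    for mid, comp in [("a_e", "e"), ("a_c", "c"), ("b_c", "c")]:
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_a", {"a_e": -1.0}, lb=-10, ub=1000, kind="exchange"))
    m.add_reaction(Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, lb=-1000, ub=1000,
                            kind="transport"))
    m.add_reaction(Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, gpr="g1 or g2"))
    m.add_reaction(Reaction("DM_b", {"b_c": -1.0}, kind="demand"))
    m.objective = "DM_b"
    return m


class TestValidation:
    def test_duplicate_ids_rejected(self):
        m = toy_two_reactions()
        with pytest.raises(ModelValidationError):
            m.add_metabolite(Metabolite("a_c", compartment="c"))
        with pytest.raises(ModelValidationError):
            m.add_reaction(Reaction("R1", {"a_c": -1.0}))

    def test_unknown_metabolite_reference(self):
        m = toy_two_reactions()
        m.reactions[2].stoich["ghost"] = 1.0
        with pytest.raises(ModelValidationError, match="ghost"):
            m.validate()

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ModelValidationError):
            Reaction("EX_bad", {"a": -1.0, "b": 1.0}, kind="exchange")

    def test_bounds_ordering(self):
        with pytest.raises(ModelValidationError):
            Reaction("bad", {"a": 1.0}, lb=5.0, ub=1.0)


class TestRoundTrip:
    def test_json_roundtrip_identity(self, tmp_path):
        m = toy_two_reactions()
        path = tmp_path / "toy.json"
        write_model(m, path)
        back = read_model(path)
        assert model_to_dict(back) == model_to_dict(m)

    def test_sbml_preserves_stoichiometry_bounds_gpr_compartments(self, tmp_path):
        m = toy_two_reactions()
        path = tmp_path / "toy.xml"
        write_model(m, path)
        back = read_model(path)
        assert sorted(back.compartments) == sorted(m.compartments)
        assert back.objective == m.objective
        for orig in m.reactions:
            echo = back.reaction(orig.id)
            assert echo.stoich == orig.stoich
            assert (echo.lb, echo.ub) == (orig.lb, orig.ub)
            assert str(echo.gpr) == str(orig.gpr)

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelParseError):
            read_model(path)

    def test_unknown_metabolite_in_file(self, tmp_path):
        data = model_to_dict(toy_two_reactions())
        data["reactions"][0]["stoich"] = {"nowhere": -1.0}
        path = tmp_path / "bad2.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ModelParseError, match="nowhere"):
            read_model(path)


class TestSplitReversible:
    def test_bounds_after_split(self):
        m = toy_two_reactions()
        split, mapping = split_reversible(m)
        # every reversible reaction splits, exchanges included
        assert set(mapping) == {"T_a", "EX_a"}
        fwd, bwd = mapping["T_a"]
        assert split.reaction(fwd).lb == 0 and split.reaction(fwd).ub == 1000
        assert split.reaction(bwd).lb == 0 and split.reaction(bwd).ub == 1000
        assert split.reaction(bwd).stoich == {"a_e": 1.0, "a_c": -1.0}
        assert all(r.lb >= 0 for r in split.reactions)

    def test_reaction_count_matches_reversible_count(self):
        # a model with 196 reversible and 2320 irreversible reactions
        # splits to 2320 + 2 x 196 = 2712 reactions
        m = MetabolicModel(id="counts")
        m.add_metabolite(Metabolite("x", compartment="c"))
        for i in range(196):
            m.add_reaction(Reaction(f"rev{i}", {"x": 1.0}, lb=-10, ub=10))
        for i in range(2320):
            m.add_reaction(Reaction(f"irr{i}", {"x": 1.0}, lb=0, ub=10))
        split, mapping = split_reversible(m)
        assert len(split.reactions) == 2712
        assert len(mapping) == 196

    def test_already_irreversible_model_unchanged(self, chain_model):
        model, _ = chain_model
        irreversible = model.copy()
        for r in irreversible.reactions:
            r.lb = max(r.lb, 0.0)
        split, mapping = split_reversible(irreversible)
        assert mapping == {}
        assert [r.id for r in split.reactions] == [r.id for r in irreversible.reactions]

    def test_split_preserves_optimum(self):
        """Merged split fluxes reproduce the unsplit optimum (random LPs)."""
        import numpy as np

        rng = np.random.default_rng(0)
        for trial in range(5):
            m = MetabolicModel(id=f"rand{trial}")
            n_mets = 4
            for i in range(n_mets):
                m.add_metabolite(Metabolite(f"m{i}", compartment="c"))
            m.add_reaction(Reaction("src", {"m0": 1.0}, lb=0, ub=10))
            for j in range(8):
                a, b = rng.choice(n_mets, size=2, replace=False)
                lb = -10.0 if rng.random() < 0.5 else 0.0
                m.add_reaction(
                    Reaction(f"r{j}", {f"m{a}": -1.0, f"m{b}": 1.0}, lb=lb, ub=10)
                )
            m.add_reaction(Reaction("out", {f"m{n_mets - 1}": -1.0}, lb=0, ub=10))
            m.objective = "out"
            base = optimize_flux(m)
            split, mapping = split_reversible(m)
            split_best = optimize_flux(split)
            if base.ok and split_best.ok:
                assert split_best.objective == pytest.approx(base.objective, abs=1e-7)


class TestConditions:
    def test_hetero_closes_light_and_opens_acetate(self, media_model):
        cond = standard_condition("hetero", biomass_id="biomass")
        applied = apply_condition(media_model, cond)
        idx = {r.id: r for r in applied.reactions}
        assert idx["EX_photon"].lb == 0.0
        assert idx["EX_ac"].lb == -2.0  # uptake capacity 2 mmol/gDW/h
        assert idx["EX_co2"].lb == 0.0
        for ex in ("EX_h2o", "EX_h", "EX_pi", "EX_nh4", "EX_so4", "EX_fe2",
                   "EX_mg2", "EX_o2"):
            assert idx[ex].lb == -10.0

    def test_high_light_bound(self, media_model):
        cond = standard_condition("auto_3k", biomass_id="biomass")
        applied = apply_condition(media_model, cond)
        assert applied.reaction("EX_photon").lb == -3000.0
        assert applied.reaction("EX_ac").lb == 0.0
        assert applied.objective == "biomass"

    def test_idempotent(self, media_model):
        cond = standard_condition("mixo", biomass_id="biomass")
        once = apply_condition(media_model, cond)
        twice = apply_condition(once, cond)
        assert model_to_dict(once) == model_to_dict(twice)

    def test_never_widens_beyond_condition_table(self, media_model):
        cond = standard_condition("auto_100", biomass_id="biomass")
        applied = apply_condition(media_model, cond)
        for r in applied.reactions:
            if r.kind == "exchange" and r.id != "EX_co2":
                assert r.lb >= -3000.0

    def test_missing_override_reported(self, media_model):
        cond = standard_condition("auto_100", biomass_id="biomass",
                                  )
        cond.bound_overrides["EX_ghost"] = (0.0, 0.0)
        with pytest.raises(ConfigurationError, match="EX_ghost"):
            apply_condition(media_model, cond)

    def test_strict_mode_requires_all_media(self, chain_model):
        model, _ = chain_model  # has only EX_S
        cond = standard_condition("auto_100", biomass_id="biomass")
        with pytest.raises(ConfigurationError):
            apply_condition(model, cond, strict=True)


def test_fba_agrees_with_cobra_oracle():
    """Native LP solves match cobrapy on random chain models."""
    from algaegem.io import to_cobra

    for seed in range(5):
        model, records = make_random_model(ToySpec(n_reactions=4 + seed, seed=seed))
        native = fba(model)
        oracle = to_cobra(model).slim_optimize()
        assert native.objective == pytest.approx(oracle, rel=1e-9)
        assert native.objective == pytest.approx(records["expected_growth"])
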
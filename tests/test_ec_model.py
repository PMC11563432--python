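import json
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oko import (EcModel, import_gecko_sbml, make_toy_model,
                 random_toy_spec, read_ec_model_json, toy1,
                 write_ec_model_json)
from oko.ec_model import (GeckoImportError, ModelValidationError,
                          PER_S_TO_PER_H, SchemaError)


def test_toy1_structure(toy_model):
    assert len(toy_model.enzymes) == 3
    assert len(toy_model.pairs) == 3
    assert toy_model.pool_capacity == pytest.approx(0.1)
    toy_model.validate()


def test_json_round_trip_is_identity(tmp_path, toy_model):
    path = tmp_path / "m.json"
    write_ec_model_json(toy_model, path)
    back = read_ec_model_json(path)
    assert back.metabolites == toy_model.metabolites
    assert [(r.reaction_id, r.mets, r.lb, r.ub) for r in back.reactions] == \
           [(r.reaction_id, r.mets, r.lb, r.ub) for r in toy_model.reactions]
    assert back.enzymes == toy_model.enzymes
    assert back.pairs == toy_model.pairs
    assert (back.sigma, back.f, back.p_total) == \
           (toy_model.sigma, toy_model.f, toy_model.p_total)
    assert back.biomass_reaction_id == toy_model.biomass_reaction_id


def test_per_s_kcat_converted_on_load(tmp_path, toy_model):
    path = tmp_path / "m.json"
    write_ec_model_json(toy_model, path)
    doc = json.loads(path.read_text())
    doc["kcats"][0].update(value=58.30, unit="per_s")
    path.write_text(json.dumps(doc))
    model = read_ec_model_json(path)
    assert model.pairs[0].kcat == pytest.approx(209880.0)
    assert model.pairs[0].kcat_per_s == pytest.approx(58.30)


def test_zero_kcat_rejected_naming_the_pair(tmp_path, toy_model):
    path = tmp_path / "m.json"
    write_ec_model_json(toy_model, path)
    doc = json.loads(path.read_text())
    doc["kcats"][0]["value"] = 0.0
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelValidationError) as err:
        read_ec_model_json(path)
    offending = (doc["kcats"][0]["enzyme"], doc["kcats"][0]["reaction"])
    assert str(offending) in str(err.value)


def test_missing_field_named_in_schema_error(tmp_path, toy_model):
    path = tmp_path / "m.json"
    write_ec_model_json(toy_model, path)
    doc = json.loads(path.read_text())
    del doc["pool"]["sigma"]
    path.write_text(json.dumps(doc))
    with pytest.raises(SchemaError, match="sigma"):
        read_ec_model_json(path)


def test_validation_lists_all_failures():
    model = toy1()
    model.enzymes[0] = type(model.enzymes[0])("E1", mw=-1.0)
    model.pairs[0] = type(model.pairs[0])("E1", "R1", kcat=-5.0)
    with pytest.raises(ModelValidationError) as err:
        model.validate()
    assert len(err.value.failures) >= 2


def test_resolve_product_adds_demand_when_absent():
    model = toy1()
    # strip the existing product demand
    model.reactions = [r for r in model.reactions if r.reaction_id != "DM_P"]
    model.product_exchanges.clear()
    model._reindex()
    rid = model.resolve_product("P")
    rxn = model.reaction(rid)
    assert rxn.mets == {"P": -1.0}
    assert rxn.lb == 0.0 and math.isinf(rxn.ub)
    with pytest.raises(KeyError):
        model.resolve_product("nonexistent")


class TestGeckoImport:
    def test_enzymes_pairs_and_pool(self, gecko_sbml):
        model = import_gecko_sbml(gecko_sbml)
        assert {e.enzyme_id: e.mw for e in model.enzymes} == {"X1": 25.0, "X2": 40.0}
        kcats = {(p.enzyme_id, p.reaction_id): p.kcat for p in model.pairs}
        assert kcats[("X1", "R1")] == pytest.approx(3600.0)
        assert kcats[("X1", "R_pro")] == pytest.approx(200.0)
        assert kcats[("X2", "R_bio")] == pytest.approx(100.0)
        assert model.pool_capacity == pytest.approx(0.12)
        assert model.biomass_reaction_id == "R_bio"
        # no protein pseudo-metabolite survives in the stoichiometry
        assert not any(m.startswith("prot_") for m in model.metabolites)

    def test_kcat_coefficient_reciprocity(self, gecko_sbml):
        import cobra.io
        cm = cobra.io.read_sbml_model(str(gecko_sbml))
        model = import_gecko_sbml(gecko_sbml)
        for p in model.pairs:
            coeff = cm.reactions.get_by_id(p.reaction_id).get_coefficient(
                f"prot_{p.enzyme_id}")
            assert p.kcat * coeff == pytest.approx(-1.0, rel=1e-6)

    def test_round_trip_through_native_json(self, gecko_sbml, tmp_path):
        model = import_gecko_sbml(gecko_sbml)
        path = tmp_path / "g.json"
        write_ec_model_json(model, path)
        back = read_ec_model_json(path)
        assert len(back.enzymes) == len(model.enzymes)
        assert len(back.pairs) == len(model.pairs)
        for a, b in zip(model.pairs, back.pairs):
            assert b.kcat == pytest.approx(a.kcat, rel=1e-9)

    def test_missing_pool_rejected(self, gecko_sbml, tmp_path):
        import cobra.io
        cm = cobra.io.read_sbml_model(str(gecko_sbml))
        cm.remove_reactions(["prot_pool_exchange"])
        path = tmp_path / "nopool.xml"
        cobra.io.write_sbml_model(cm, str(path))
        with pytest.raises(GeckoImportError):
            import_gecko_sbml(path)

    def test_produced_protein_rejected(self, gecko_sbml, tmp_path):
        import cobra.io
        cm = cobra.io.read_sbml_model(str(gecko_sbml))
        rxn = cm.reactions.get_by_id("R1")
        prot = cm.metabolites.get_by_id("prot_X1")
        rxn.add_metabolites({prot: 2 / 3600.0})  # flips sign to positive
        path = tmp_path / "badsign.xml"
        cobra.io.write_sbml_model(cm, str(path))
        with pytest.raises(GeckoImportError, match="R1"):
            import_gecko_sbml(path)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(index=st.integers(min_value=0, max_value=500))
def test_random_toy_models_validate_and_round_trip(index, tmp_path_factory):
    model = make_toy_model(random_toy_spec(index), check=False)
    model.validate()
    path = tmp_path_factory.mktemp("rt") / "m.json"
    write_ec_model_json(model, path)
    back = read_ec_model_json(path)
    assert back.pairs == model.pairs


def test_seeded_export_is_byte_identical(tmp_path):
    spec = random_toy_spec(3)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_ec_model_json(make_toy_model(spec, check=False), p1)
    write_ec_model_json(make_toy_model(spec, check=False), p2)
    assert p1.read_bytes() == p2.read_bytes()
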
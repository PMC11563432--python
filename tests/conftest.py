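import cobra
import pytest

from oko import OkoParams, compute_reference, toy1


@pytest.fixture(scope="session")
def toy_model():
    return toy1()


@pytest.fixture(scope="session")
def toy_ref(toy_model):
    # 0.98 growth floor during product maximization gives the closed-form
    # reference state used throughout the toy checks
    return compute_reference(toy_model, "P", bio_floor_frac=0.98)


@pytest.fixture()
def params_strict():
    """Doubled production at 98% growth retention."""
    return OkoParams(f_pro=2.0, alpha_bio=0.98)


@pytest.fixture(scope="session")
def gecko_sbml(tmp_path_factory):
    """A hand-built GECKO-convention SBML file: two enzymes (one
    promiscuous), draw reactions with molecular weights, and a pool
    exchange capped at 0.12 g/gDW."""
    cm = cobra.Model("gecko_toy")
    mets = {mid: cobra.Metabolite(mid, compartment="c")
            for mid in ["S", "A", "P", "prot_X1", "prot_X2", "prot_pool"]}
    cm.add_metabolites(list(mets.values()))

    def rxn(rid, sto, lb=0.0, ub=1000.0):
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = lb, ub
        cm.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in sto.items()})

    rxn("UPT", {"S": 1}, 0, 10)
    rxn("R1", {"S": -1, "A": 1, "prot_X1": -1 / 3600.0})     # kcat 3600 /h
    rxn("R_bio", {"A": -1, "prot_X2": -1 / 100.0})           # kcat 100 /h
    rxn("R_pro", {"A": -1, "P": 1, "prot_X1": -1 / 200.0})   # kcat 200 /h
    rxn("DM_P", {"P": -1})
    rxn("draw_prot_X1", {"prot_pool": -25.0, "prot_X1": 1})  # MW 25 g/mmol
    rxn("draw_prot_X2", {"prot_pool": -40.0, "prot_X2": 1})
    rxn("prot_pool_exchange", {"prot_pool": 1}, 0, 0.12)
    cm.objective = "R_bio"
    path = tmp_path_factory.mktemp("sbml") / "gecko_toy.xml"
    cobra.io.write_sbml_model(cm, str(path))
    return path
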
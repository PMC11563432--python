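import math

import numpy as np
import pytest

from oko import (EcModel, enzyme_variability, make_toy_model, maximize_growth,
                 maximize_product, minimize_enzyme_usage, toy1)
from oko.allocation import stabilized_log_ratio
from oko.ec_model import CatalyticPair, Enzyme, Reaction


def test_toy_growth_optimum_matches_closed_form(toy_model):
    # pool 0.1 split equally over the two kcat-100 enzymes of the
    # biomass-producing route: v_bio = 100 * 0.05
    assert maximize_growth(toy_model) == pytest.approx(5.0, rel=1e-6)


def test_toy_product_maximum_matches_closed_form(toy_model):
    # pool balance at the 0.98 growth floor: 0.098 + 0.03 v_pro = 0.1
    v = maximize_product(toy_model, "P", bio_floor_frac=0.98)
    assert v == pytest.approx(1.0 / 15.0, rel=1e-3)
    # the pool is exactly exhausted at optimal growth: no slack for product
    assert maximize_product(toy_model, "P", bio_floor_frac=1.0) == \
        pytest.approx(0.0, abs=1e-9)


def test_product_maximum_non_increasing_in_growth_floor(toy_model):
    v_bio = maximize_growth(toy_model)
    vals = [maximize_product(toy_model, "P", frac, v_bio_opt=v_bio)
            for frac in (0.0, 0.5, 0.9, 0.98, 1.0)]
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


def test_biomass_as_product_recovers_growth_optimum(toy_model):
    v_bio = maximize_growth(toy_model)
    v = maximize_product(toy_model, "R_bio", bio_floor_frac=0.98,
                         v_bio_opt=v_bio)
    assert v == pytest.approx(v_bio, rel=1e-6)


def test_zero_pool_capacity_blocks_enzymatic_flux():
    model = toy1()
    model.p_total = 0.0  # constructed, not validated: capacity edge case
    assert maximize_growth(model) == pytest.approx(0.0, abs=1e-9)


def test_unknown_product_raises_lookup_error(toy_model):
    with pytest.raises(KeyError):
        maximize_product(toy_model, "no_such_product")


class TestUsageMinimization:
    def test_toy_reference_abundances(self, toy_ref):
        assert toy_ref.e_wt["E1"] == pytest.approx(0.0496533, rel=1e-4)
        assert toy_ref.e_wt["E_bio"] == pytest.approx(0.049, rel=1e-6)
        assert toy_ref.e_wt["E_pro"] == pytest.approx(0.0013067, rel=1e-3)

    def test_reference_invariants(self, toy_model, toy_ref):
        # usage split sums to abundance
        for enz in toy_model.enzymes:
            tot = sum(u for (e, _), u in toy_ref.u_wt.items()
                      if e == enz.enzyme_id)
            assert tot == pytest.approx(toy_ref.e_wt[enz.enzyme_id], abs=1e-9)
        # pool respected, total matches objective
        mass = sum(e.mw * toy_ref.e_wt[e.enzyme_id] for e in toy_model.enzymes)
        assert mass <= toy_model.pool_capacity + 1e-9
        assert sum(toy_ref.e_wt.values()) == pytest.approx(
            toy_ref.sum_e_star, abs=1e-9)

    def test_both_floors_satisfied(self, toy_model, toy_ref):
        # re-derive achieved fluxes from the usage split
        v_bio = 100.0 * toy_ref.e_wt["E_bio"]
        v_pro = 50.0 * toy_ref.e_wt["E_pro"]
        assert v_pro >= 0.98 * toy_ref.v_pro_max - 1e-6
        assert v_bio >= 0.98 * toy_ref.v_bio_opt - 1e-6

    def test_zero_product_optimum_is_feasible(self):
        model = toy1()
        # block the product drain: the optimum product flux is 0 and the
        # usage LP must still be solvable (its floor is 0)
        model.reactions = [
            r if r.reaction_id != "DM_P"
            else Reaction("DM_P", dict(r.mets), 0.0, 0.0)
            for r in model.reactions
        ]
        model._reindex()
        v_bio = maximize_growth(model)
        v_pro = maximize_product(model, "P", 0.98, v_bio)
        assert v_pro == pytest.approx(0.0, abs=1e-9)
        ref = minimize_enzyme_usage(model, "P", v_pro, v_bio)
        assert ref.sum_e_star > 0

    def test_json_round_trip(self, toy_ref, tmp_path):
        from oko import WildTypeReference
        path = tmp_path / "ref.json"
        toy_ref.to_json(path)
        back = WildTypeReference.from_json(path)
        assert back.v_bio_opt == toy_ref.v_bio_opt
        assert back.e_wt == toy_ref.e_wt
        assert back.u_wt == toy_ref.u_wt


class TestVariability:
    def test_toy_allocation_is_unique(self, toy_model, toy_ref):
        # the pool is tight on TOY1: every enzyme is pinned to its
        # reference abundance
        for rec in enzyme_variability(toy_model, toy_ref):
            assert rec.e_min == pytest.approx(toy_ref.e_wt[rec.enzyme_id],
                                              abs=1e-6)
            assert rec.e_max == pytest.approx(toy_ref.e_wt[rec.enzyme_id],
                                              abs=1e-6)
            assert rec.log_ratio >= 0.0

    def test_equality_and_inequality_modes_agree(self, toy_model, toy_ref):
        eq = enzyme_variability(toy_model, toy_ref, coupling="equality")
        ineq = enzyme_variability(toy_model, toy_ref, coupling="inequality")
        for a, b in zip(eq, ineq):
            assert a.e_min == pytest.approx(b.e_min, abs=1e-6)
            assert a.e_max == pytest.approx(b.e_max, abs=1e-6)

    def test_reference_abundance_within_range(self, toy_model, toy_ref):
        for rec in enzyme_variability(toy_model, toy_ref):
            ewt = toy_ref.e_wt[rec.enzyme_id]
            assert rec.e_min - 1e-6 <= ewt <= rec.e_max + 1e-6

    def test_fixing_extremes_preserves_minimal_usage(self, toy_model, toy_ref):
        # re-solving with one abundance pinned to its extreme must keep the
        # total usage attainable
        from oko.allocation import build_allocation_lp, ename, vname
        from oko._solver import solve
        recs = enzyme_variability(toy_model, toy_ref)
        for rec in recs:
            for val in (rec.e_min, rec.e_max):
                lm = build_allocation_lp(toy_model)
                lm.add_constraint({vname("DM_P"): 1.0},
                                  0.98 * toy_ref.v_pro_max, np.inf)
                lm.add_constraint({vname("R_bio"): 1.0},
                                  0.98 * toy_ref.v_bio_opt, np.inf)
                lm.set_bounds(ename(rec.enzyme_id),
                              max(0.0, val - 1e-9), val + 1e-9)
                lm.set_objective({ename(e.enzyme_id): 1.0
                                  for e in toy_model.enzymes}, "min")
                sol = solve(lm)
                assert sol.objective == pytest.approx(toy_ref.sum_e_star,
                                                      abs=1e-6)

    def test_unknown_enzyme_raises(self, toy_model, toy_ref):
        with pytest.raises(KeyError):
            enzyme_variability(toy_model, toy_ref, ["nope"])


def test_stabilized_log_ratio_properties():
    assert stabilized_log_ratio(0.0, 0.0) == 0.0
    assert stabilized_log_ratio(1e-3, 1e-3) == pytest.approx(0.0, abs=1e-9)
    # reduces to the plain ratio far from the stabilizer
    assert stabilized_log_ratio(1.0, 0.1) == pytest.approx(1.0, rel=1e-6)
    # bounded despite a zero minimum
    assert stabilized_log_ratio(1e-4, 0.0) < 6
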
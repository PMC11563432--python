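import dataclasses
import math

import pytest

from oko import (OkoInfeasibleError, OkoParams, PairRange, audit_strategy,
                 solve_oko, solve_oko_plus)


def test_wild_type_already_feasible_needs_no_changes(toy_model, toy_ref):
    params = OkoParams(f_pro=0.98, alpha_bio=0.98)
    s = solve_oko(toy_model, toy_ref, params)
    assert s.n_kcat_changed == 0
    assert all(not c.changed for c in s.kcat_changes)
    assert audit_strategy(toy_model, toy_ref, params, s) == []


def test_doubling_production_needs_two_changes(toy_model, toy_ref,
                                               params_strict):
    # certified against the brute-force oracle: doubling product flux on
    # TOY1 requires modifying the product kcat plus one upstream kcat to
    # free pool capacity
    s = solve_oko(toy_model, toy_ref, params_strict)
    assert s.n_kcat_changed == 2
    changed = {(c.enzyme_id, c.reaction_id) for c in s.changed}
    assert ("E_pro", "R_pro") in changed
    assert s.v_pro_achieved >= 2.0 * toy_ref.v_pro_max - 1e-6
    assert s.v_bio_achieved >= 0.98 * toy_ref.v_bio_opt - 1e-6


def test_returned_strategy_passes_arithmetic_audit(toy_model, toy_ref,
                                                   params_strict):
    s = solve_oko(toy_model, toy_ref, params_strict)
    assert audit_strategy(toy_model, toy_ref, params_strict, s) == []


def test_fold_changes_respect_beta2_band(toy_model, toy_ref, params_strict):
    s = solve_oko(toy_model, toy_ref, params_strict)
    for c in s.kcat_changes:
        assert abs(math.log(c.fold_change)) <= \
            math.log(params_strict.beta2) + 1e-6


def test_change_count_monotone_in_production_demand(toy_model, toy_ref):
    counts = []
    for f_pro in (1.0, 1.5, 2.0, 3.0):
        p = OkoParams(f_pro=f_pro, alpha_bio=0.98)
        counts.append(solve_oko(toy_model, toy_ref, p).n_kcat_changed)
    assert counts == sorted(counts)


def test_change_count_monotone_in_growth_demand(toy_model, toy_ref):
    counts = []
    for alpha_bio in (0.8, 0.9, 0.98):
        p = OkoParams(f_pro=2.0, alpha_bio=alpha_bio)
        counts.append(solve_oko(toy_model, toy_ref, p).n_kcat_changed)
    assert counts == sorted(counts)


def test_tightening_beta2_never_reduces_changes(toy_model, toy_ref):
    counts = []
    for beta2 in (10.0, 4.0, 2.0):
        p = OkoParams(f_pro=2.0, alpha_bio=0.98, beta2=beta2)
        try:
            counts.append(solve_oko(toy_model, toy_ref, p).n_kcat_changed)
        except OkoInfeasibleError:
            counts.append(math.inf)
    assert counts == sorted(counts)


def test_infeasibility_diagnosis_names_production(toy_model, toy_ref):
    # beta2 barely above 1 cannot double production: the relaxation scan
    # must blame the production requirement
    p = OkoParams(f_pro=2.0, alpha_bio=0.98, beta2=1.01)
    with pytest.raises(OkoInfeasibleError) as err:
        solve_oko(toy_model, toy_ref, p)
    assert err.value.binding == "production"


def test_params_validation():
    with pytest.raises(ValueError, match="alpha"):
        OkoParams(alpha=1.5).validate()
    with pytest.raises(ValueError, match="beta2"):
        OkoParams(beta2=0.5).validate()
    with pytest.raises(ValueError, match="beta1"):
        OkoParams(beta1=0.0).validate()
    OkoParams().validate()


def test_strategy_json_round_trip(toy_model, toy_ref, params_strict, tmp_path):
    from oko import Strategy
    s = solve_oko(toy_model, toy_ref, params_strict)
    path = tmp_path / "s.json"
    s.to_json(path)
    back = Strategy.from_json(path)
    assert back.n_kcat_changed == s.n_kcat_changed
    assert back.kcat_changes == s.kcat_changes
    assert back.usages == s.usages


class TestOkoPlus:
    def test_empty_ranges_freeze_every_pair(self, toy_model, toy_ref,
                                            params_strict):
        # with all kcats frozen, TOY1's pool cannot support doubled
        # production even with free abundances
        with pytest.raises(OkoInfeasibleError):
            solve_oko_plus(toy_model, toy_ref, [], params_strict)

    def test_single_range_enables_single_kcat_change(self, toy_model, toy_ref,
                                                     params_strict):
        ranges = [PairRange("E_pro", "R_pro", kmin=100.0, kmax=500.0,
                            n_records=3)]
        s = solve_oko_plus(toy_model, toy_ref, ranges, params_strict)
        assert s.n_kcat_changed == 1
        (c,) = s.changed
        assert (c.enzyme_id, c.reaction_id) == ("E_pro", "R_pro")
        assert 100.0 - 1e-4 <= c.kcat_star <= 500.0 + 1e-4
        assert s.n_abundance_changed >= 1  # pool reallocation is required
        assert audit_strategy(toy_model, toy_ref, params_strict, s,
                              ranges) == []

    def test_unranged_pairs_stay_unchanged(self, toy_model, toy_ref,
                                           params_strict):
        ranges = [PairRange("E_pro", "R_pro", 100.0, 500.0, 1)]
        s = solve_oko_plus(toy_model, toy_ref, ranges, params_strict)
        for c in s.kcat_changes:
            if (c.enzyme_id, c.reaction_id) != ("E_pro", "R_pro"):
                assert not c.changed
                assert c.kcat_star == c.kcat_wt

    def test_widening_ranges_never_increases_objective(self, toy_model,
                                                       toy_ref, params_strict):
        narrow = [PairRange("E_pro", "R_pro", 100.0, 200.0, 1)]
        wide = [PairRange("E_pro", "R_pro", 100.0, 500.0, 1),
                PairRange("E1", "R1", 50.0, 1000.0, 1)]
        def objective(rs):
            try:
                return solve_oko_plus(toy_model, toy_ref, rs,
                                      params_strict).objective_value
            except OkoInfeasibleError:
                return -math.inf
        assert objective(wide) >= objective(narrow) - 1e-6

    def test_range_outside_band_warns_and_freezes(self, toy_model, toy_ref,
                                                  params_strict, caplog):
        # admissible range far above beta2 * kcat: pair cannot actually move
        ranges = [PairRange("E_pro", "R_pro", 5e4, 6e4, 1)]
        with caplog.at_level("WARNING", logger="oko"):
            with pytest.raises(OkoInfeasibleError):
                solve_oko_plus(toy_model, toy_ref, ranges, params_strict)
        assert any("effectively frozen" in r.message for r in caplog.records)
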
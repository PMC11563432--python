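"""Minimum-cardinality turnover-number engineering (OKO and OKO+).

Given a wild-type reference allocation, the engineering step asks: what is
the smallest set of turnover numbers whose modification raises product flux
to ``f_pro`` times the wild-type maximum while retaining ``alpha_bio`` of
optimal growth and keeping enzyme abundances near wild type?

Per catalytic pair (i, j) the engineered rate law is

    v_j = (kcat_ij + delta_ij) * u_ij

with the bilinear term linearized through ``de_ij = delta_ij * u_ij``:

    v_j = kcat_ij * u_ij + de_ij,        -M u_ij <= de_ij <= M u_ij.

A binary ``y_ij`` equals 1 when the pair is (numerically) unchanged,
``|de_ij| <= beta1 * kcat_ij * u_ij``, enforced through big-M indicator
rows; the admissible fold-change band is ``kcat/beta2 <= kcat* <= beta2*kcat``.
The MILP maximizes the number of unchanged pairs.

OKO holds abundances inside ``(1 +/- alpha) * E^wt``.  OKO+ instead lets
abundances move, counts significantly changed ones through binaries
``ye_i`` (band ``(1 +/- beta_e) * E^wt``), restricts kcat modifications to
pairs with an externally predicted admissible range, and maximizes
``sum y_ij + w * sum ye_i``.

Numerical note: indicator big-M coefficients are tightened per constraint
from the variable bounds (capped at ``params.big_m``); a loose uniform 1e6
would leak through the solver's integrality tolerance and corrupt the
change count.  After the MILP, a polish LP re-solves the continuous part
with the binary pattern fixed and hard (band) constraints, so reported
solutions satisfy every constraint to arithmetic precision rather than MIP
tolerance.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solver import InfeasibleError, LinearModel, solve
from .allocation import WildTypeReference, ename, uname, vname
from .ec_model import EcModel, PER_S_TO_PER_H
from .kcat_catalog import PairRange

logger = logging.getLogger("oko")

__all__ = [
    "OkoParams",
    "KcatChange",
    "AbundanceChange",
    "Strategy",
    "solve_oko",
    "solve_oko_plus",
    "audit_strategy",
    "OkoInfeasibleError",
]

#: usages below this are treated as zero when recovering kcat* = kcat + de/u
USAGE_TOL = 1e-9
#: slack for arithmetic re-checks of returned strategies
AUDIT_TOL = 1e-6


class OkoInfeasibleError(InfeasibleError):
    """Engineering MILP infeasible; carries a relaxation diagnosis."""

    def __init__(self, message: str, binding: str | None):
        super().__init__(message)
        self.binding = binding


@dataclass
class OkoParams:
    """Tunable parameters of the engineering MILP.

    alpha      : half-width of the allowed relative deviation of engineered
                 abundances from wild type (OKO only).
    beta1      : relative half-width of the "unchanged" kcat band.
    beta2      : maximum admissible fold change of a kcat (> 1); the
                 engineered value stays in [kcat/beta2, beta2*kcat].
    f_pro      : required production multiple of the wild-type maximum.
    alpha_bio  : required fraction of wild-type optimal growth.  Default
                 0.85: nominally the factor is ~1, but engineered designs
                 retain on the order of 88% of optimal growth, so the
                 package forces an explicit, slightly conservative choice.
    big_m      : cap on indicator big-M coefficients.
    beta_e     : relative half-width of the "unchanged" abundance band (OKO+).
    w          : objective weight on unchanged-abundance indicators (OKO+).
    """

    alpha: float = 0.1
    beta1: float = 1e-8
    beta2: float = 10.0
    f_pro: float = 2.0
    alpha_bio: float = 0.85
    big_m: float = 1e6
    beta_e: float = 0.1
    w: float = 10.0
    mip_gap: float = 0.0
    time_limit: float | None = None
    backend: str = "highs"

    def validate(self) -> None:
        bad = []
        if not 0 < self.alpha < 1:
            bad.append(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.beta1 < 1:
            bad.append(f"beta1 must lie in (0, 1), got {self.beta1}")
        if not self.beta2 > 1:
            bad.append(f"beta2 must be > 1, got {self.beta2}")
        if not self.beta_e > 0:
            bad.append(f"beta_e must be > 0, got {self.beta_e}")
        if not self.f_pro >= 0:
            bad.append(f"f_pro must be >= 0, got {self.f_pro}")
        if not 0 <= self.alpha_bio <= 1:
            bad.append(f"alpha_bio must lie in [0, 1], got {self.alpha_bio}")
        if not self.big_m > 0:
            bad.append(f"big_m must be > 0, got {self.big_m}")
        if not self.w > 0:
            bad.append(f"w must be > 0, got {self.w}")
        if bad:
            raise ValueError("invalid OkoParams: " + "; ".join(bad))


@dataclass(frozen=True)
class KcatChange:
    enzyme_id: str
    reaction_id: str
    kcat_wt: float            # h^-1
    kcat_star: float          # h^-1
    fold_change: float
    changed: bool
    direction: str            # "increase" | "decrease" | "unchanged"
    indeterminate: bool = False   # zero usage: kcat* not recoverable


@dataclass(frozen=True)
class AbundanceChange:
    enzyme_id: str
    e_wt: float
    e_eng: float
    changed: bool


@dataclass
class Strategy:
    """Engineering strategy returned by the MILP (one solution, no
    uniqueness claim among alternate optima)."""

    method: str                               # "oko" | "oko_plus"
    kcat_changes: list[KcatChange]
    abundance_changes: list[AbundanceChange]
    n_kcat_changed: int
    n_abundance_changed: int
    v_pro_achieved: float
    v_bio_achieved: float
    fluxes: dict[str, float]
    usages: dict[tuple[str, str], float]
    abundances: dict[str, float]
    objective_value: float
    solver_status: str
    product_reaction_id: str

    @property
    def changed(self) -> list[KcatChange]:
        return [c for c in self.kcat_changes if c.changed]

    def changes_frame(self) -> pd.DataFrame:
        """One row per modified kcat, rendered in s^-1."""
        rows = [(c.enzyme_id, c.reaction_id, c.kcat_wt / PER_S_TO_PER_H,
                 c.kcat_star / PER_S_TO_PER_H, c.fold_change, c.direction)
                for c in self.changed]
        return pd.DataFrame(rows, columns=[
            "enzyme_id", "reaction_id", "kcat_wt_per_s", "kcat_star_per_s",
            "fold_change", "direction"])

    def to_json(self, path) -> None:
        doc = {
            "method": self.method,
            "kcat_changes": [vars(c) | {} for c in self.kcat_changes],
            "abundance_changes": [vars(a) | {} for a in self.abundance_changes],
            "n_kcat_changed": self.n_kcat_changed,
            "n_abundance_changed": self.n_abundance_changed,
            "v_pro_achieved": self.v_pro_achieved,
            "v_bio_achieved": self.v_bio_achieved,
            "fluxes": self.fluxes,
            "usages": [[e, r, u] for (e, r), u in self.usages.items()],
            "abundances": self.abundances,
            "objective_value": self.objective_value,
            "solver_status": self.solver_status,
            "product_reaction_id": self.product_reaction_id,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Strategy":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            method=doc["method"],
            kcat_changes=[KcatChange(**c) for c in doc["kcat_changes"]],
            abundance_changes=[AbundanceChange(**a)
                               for a in doc["abundance_changes"]],
            n_kcat_changed=doc["n_kcat_changed"],
            n_abundance_changed=doc["n_abundance_changed"],
            v_pro_achieved=doc["v_pro_achieved"],
            v_bio_achieved=doc["v_bio_achieved"],
            fluxes=doc["fluxes"],
            usages={(e, r): float(u) for e, r, u in doc["usages"]},
            abundances=doc["abundances"],
            objective_value=doc["objective_value"],
            solver_status=doc["solver_status"],
            product_reaction_id=doc["product_reaction_id"],
        )


# ---------------------------------------------------------------------------
# MILP assembly
# ---------------------------------------------------------------------------

def dname(enzyme_id: str, reaction_id: str) -> str:
    return f"d::{enzyme_id}::{reaction_id}"


def yname(enzyme_id: str, reaction_id: str) -> str:
    return f"y::{enzyme_id}::{reaction_id}"


def yename(enzyme_id: str) -> str:
    return f"ye::{enzyme_id}"


def _usage_caps(model: EcModel, e_ub: dict[str, float],
                beta2: float) -> dict[tuple[str, str], float]:
    """Finite upper bounds on per-pair usages, from abundance caps and, when
    the flux bound is finite, from v >= kcat*u/beta2."""
    caps = {}
    for p in model.pairs:
        cap = e_ub[p.enzyme_id]
        vmax = model.reaction(p.reaction_id).ub
        if math.isfinite(vmax):
            cap = min(cap, beta2 * vmax / p.kcat)
        caps[(p.enzyme_id, p.reaction_id)] = cap
    return caps


def _build_engineering_milp(model: EcModel, ref: WildTypeReference,
                            params: OkoParams,
                            ranges: dict[tuple[str, str], PairRange] | None):
    """Shared OKO / OKO+ MILP.  `ranges is None` selects plain OKO."""
    plus = ranges is not None
    # the wild-type catalysis rows v = kcat*u are replaced here by the
    # engineered rate law v = kcat*u + de, so the skeleton omits them
    lm = _base_without_catalysis(model, name="oko_plus" if plus else "oko")
    cap = model.pool_capacity

    e_ub: dict[str, float] = {}
    for enz in model.enzymes:
        ewt = ref.e_wt.get(enz.enzyme_id, 0.0)
        hard = cap / enz.mw
        if plus:
            lo, hi = 0.0, hard
        else:
            lo = max(0.0, (1 - params.alpha) * ewt)
            hi = min(hard, (1 + params.alpha) * ewt)
        lm.set_bounds(ename(enz.enzyme_id), lo, hi)
        e_ub[enz.enzyme_id] = hi
    u_cap = _usage_caps(model, e_ub, params.beta2)

    for p in model.pairs:
        key = (p.enzyme_id, p.reaction_id)
        uc = u_cap[key]
        lm.set_bounds(uname(*key), 0.0, uc)
        dlo = p.kcat * (1.0 / params.beta2 - 1.0) * uc
        dhi = p.kcat * (params.beta2 - 1.0) * uc
        lm.add_var(dname(*key), dlo, dhi)
        lm.add_binary(yname(*key))

        u, d, y = uname(*key), dname(*key), yname(*key)
        # engineered rate law (linearized): v_j = kcat*u + de
        lm.add_constraint({vname(p.reaction_id): 1.0, u: -p.kcat, d: -1.0},
                          0.0, 0.0, name=f"rate::{p.enzyme_id}::{p.reaction_id}")
        # de vanishes with usage: -M u <= de <= M u
        lm.add_constraint({d: 1.0, u: -params.big_m}, -np.inf, 0.0)
        lm.add_constraint({d: -1.0, u: -params.big_m}, -np.inf, 0.0)
        # fold-change band: kcat(1/b2 - 1) u <= de <= kcat(b2 - 1) u
        lm.add_constraint({d: 1.0, u: -p.kcat * (params.beta2 - 1.0)},
                          -np.inf, 0.0)
        lm.add_constraint({d: -1.0, u: p.kcat * (1.0 / params.beta2 - 1.0)},
                          -np.inf, 0.0)
        # unchanged indicator: y = 1 forces |de| <= beta1 * kcat * u
        m_ij = min(params.big_m,
                   p.kcat * max(params.beta2 - 1.0, 1.0 - 1.0 / params.beta2)
                   * uc + 1.0)
        lm.add_constraint({d: 1.0, u: -params.beta1 * p.kcat, y: m_ij},
                          -np.inf, m_ij)
        lm.add_constraint({d: -1.0, u: -params.beta1 * p.kcat, y: m_ij},
                          -np.inf, m_ij)

        if plus:
            rng = ranges.get(key)
            if rng is None:
                # no external prediction: the pair may not be modified
                lm.set_bounds(dname(*key), 0.0, 0.0)
                lm.set_bounds(yname(*key), 1.0, 1.0)
            else:
                lo_band = p.kcat / params.beta2
                hi_band = p.kcat * params.beta2
                if rng.kmax < lo_band or rng.kmin > hi_band:
                    logger.warning(
                        "pair (%s, %s): admissible range [%g, %g] h^-1 lies "
                        "outside the beta2 band [%g, %g]; pair is effectively "
                        "frozen", p.enzyme_id, p.reaction_id, rng.kmin,
                        rng.kmax, lo_band, hi_band)
                # changed (y=0) forces kcat* into [kmin, kmax]
                mp = ((max(abs(rng.kmin - p.kcat), abs(rng.kmax - p.kcat))
                       + params.beta1 * p.kcat) * uc + 1.0)
                lm.add_constraint({u: rng.kmin - p.kcat, d: -1.0, y: -mp},
                                  -np.inf, 0.0)
                lm.add_constraint({d: 1.0, u: -(rng.kmax - p.kcat), y: -mp},
                                  -np.inf, 0.0)

    obj = {yname(p.enzyme_id, p.reaction_id): 1.0 for p in model.pairs}
    if plus:
        for enz in model.enzymes:
            ewt = ref.e_wt.get(enz.enzyme_id, 0.0)
            ye = lm.add_binary(yename(enz.enzyme_id))
            lo_band = (1 - params.beta_e) * ewt
            hi_band = (1 + params.beta_e) * ewt
            me = min(params.big_m,
                     max(lo_band, e_ub[enz.enzyme_id] - hi_band, 0.0) + 1.0)
            # ye = 1 forces (1-be) ewt <= E <= (1+be) ewt
            lm.add_constraint({ename(enz.enzyme_id): -1.0, ye: me},
                              -np.inf, me - lo_band)
            lm.add_constraint({ename(enz.enzyme_id): 1.0, ye: me},
                              -np.inf, me + hi_band)
            obj[ye] = params.w

    # production and growth requirements
    lm.add_constraint({vname(ref.product_reaction_id): 1.0},
                      params.f_pro * ref.v_pro_max, np.inf, name="production")
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      params.alpha_bio * ref.v_bio_opt, np.inf, name="growth")
    lm.set_objective(obj, "max")
    return lm


def _base_without_catalysis(model: EcModel, name: str) -> LinearModel:
    """ec-FBA skeleton (mass balance, usage balance, pool) without the
    wild-type catalysis rows, which the MILP replaces."""
    lm = LinearModel(name=name)
    cap = model.pool_capacity
    for rxn in model.reactions:
        lm.add_var(vname(rxn.reaction_id), rxn.lb, rxn.ub)
    for enz in model.enzymes:
        lm.add_var(ename(enz.enzyme_id), 0.0, cap / enz.mw)
    for p in model.pairs:
        lm.add_var(uname(p.enzyme_id, p.reaction_id), 0.0, np.inf)
    by_met: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        for met, coeff in rxn.mets.items():
            by_met.setdefault(met, {})[vname(rxn.reaction_id)] = coeff
    for met, row in by_met.items():
        lm.add_constraint(row, 0.0, 0.0, name=f"mass::{met}")
    for enz in model.enzymes:
        row = {ename(enz.enzyme_id): -1.0}
        for p in model.pairs:
            if p.enzyme_id == enz.enzyme_id:
                row[uname(p.enzyme_id, p.reaction_id)] = 1.0
        lm.add_constraint(row, 0.0, 0.0, name=f"use::{enz.enzyme_id}")
    lm.add_constraint({ename(e.enzyme_id): e.mw for e in model.enzymes},
                      -np.inf, cap, name="pool")
    return lm


# ---------------------------------------------------------------------------
# solve + polish + extraction
# ---------------------------------------------------------------------------

def _polish(model: EcModel, ref: WildTypeReference, params: OkoParams,
            ranges: dict[tuple[str, str], PairRange] | None,
            y_pattern: dict[tuple[str, str], int],
            ye_pattern: dict[str, int] | None):
    """Fix the binary pattern and re-solve the continuous part with hard
    band constraints, maximizing product flux.  Removes MIP-tolerance noise
    from the certificate."""
    plus = ranges is not None
    lm = _base_without_catalysis(model, name="polish")
    cap = model.pool_capacity
    e_ub = {}
    for enz in model.enzymes:
        ewt = ref.e_wt.get(enz.enzyme_id, 0.0)
        hard = cap / enz.mw
        if plus:
            if ye_pattern.get(enz.enzyme_id, 1) == 1:
                lo = max(0.0, (1 - params.beta_e) * ewt)
                hi = min(hard, (1 + params.beta_e) * ewt)
            else:
                lo, hi = 0.0, hard
        else:
            lo = max(0.0, (1 - params.alpha) * ewt)
            hi = min(hard, (1 + params.alpha) * ewt)
        lm.set_bounds(ename(enz.enzyme_id), lo, hi)
        e_ub[enz.enzyme_id] = hard
    u_cap = _usage_caps(model, e_ub, params.beta2)
    for p in model.pairs:
        key = (p.enzyme_id, p.reaction_id)
        uc = u_cap[key]
        lm.set_bounds(uname(*key), 0.0, uc)
        lm.add_var(dname(*key), p.kcat * (1 / params.beta2 - 1) * uc,
                   p.kcat * (params.beta2 - 1) * uc)
        u, d = uname(*key), dname(*key)
        lm.add_constraint({vname(p.reaction_id): 1.0, u: -p.kcat, d: -1.0},
                          0.0, 0.0)
        if y_pattern[key] == 1:
            if plus and ranges.get(key) is None:
                lm.set_bounds(d, 0.0, 0.0)   # unranged pairs are frozen
            lm.add_constraint({d: 1.0, u: -params.beta1 * p.kcat}, -np.inf, 0.0)
            lm.add_constraint({d: -1.0, u: -params.beta1 * p.kcat}, -np.inf, 0.0)
        else:
            lm.add_constraint({d: 1.0, u: -p.kcat * (params.beta2 - 1)},
                              -np.inf, 0.0)
            lm.add_constraint({d: -1.0, u: p.kcat * (1 / params.beta2 - 1)},
                              -np.inf, 0.0)
            if plus:
                rng = ranges.get(key)
                if rng is not None:
                    lm.add_constraint({u: rng.kmin - p.kcat, d: -1.0},
                                      -np.inf, 0.0)
                    lm.add_constraint({d: 1.0, u: -(rng.kmax - p.kcat)},
                                      -np.inf, 0.0)
    lm.add_constraint({vname(ref.product_reaction_id): 1.0},
                      params.f_pro * ref.v_pro_max, np.inf)
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      params.alpha_bio * ref.v_bio_opt, np.inf)
    lm.set_objective({vname(ref.product_reaction_id): 1.0}, "max")
    return solve(lm, backend=params.backend)


def _extract(model: EcModel, ref: WildTypeReference, params: OkoParams,
             sol, y_pattern, ye_pattern, method: str,
             objective_value: float, status: str) -> Strategy:
    fluxes = {r.reaction_id: sol[vname(r.reaction_id)] for r in model.reactions}
    usages = {(p.enzyme_id, p.reaction_id):
              max(0.0, sol[uname(p.enzyme_id, p.reaction_id)])
              for p in model.pairs}
    abundances = {e.enzyme_id: max(0.0, sol[ename(e.enzyme_id)])
                  for e in model.enzymes}
    kcat_changes = []
    for p in model.pairs:
        key = (p.enzyme_id, p.reaction_id)
        u = usages[key]
        de = sol[dname(*key)]
        changed = y_pattern[key] == 0
        if u > USAGE_TOL:
            kstar = p.kcat + de / u
            indet = False
        else:
            kstar = p.kcat
            indet = True
        if not changed:
            # inside the beta1 band the pair is by definition unmodified;
            # report the wild-type value rather than sub-tolerance drift
            kstar = p.kcat
            direction = "unchanged"
        elif kstar > p.kcat:
            direction = "increase"
        elif kstar < p.kcat:
            direction = "decrease"
        else:
            direction = "unchanged"
        kcat_changes.append(KcatChange(
            enzyme_id=p.enzyme_id, reaction_id=p.reaction_id,
            kcat_wt=p.kcat, kcat_star=kstar, fold_change=kstar / p.kcat,
            changed=changed, direction=direction, indeterminate=indet))
    abundance_changes = []
    for enz in model.enzymes:
        eid = enz.enzyme_id
        ch = (ye_pattern.get(eid, 1) == 0) if ye_pattern is not None else False
        abundance_changes.append(AbundanceChange(
            enzyme_id=eid, e_wt=ref.e_wt.get(eid, 0.0),
            e_eng=abundances[eid], changed=ch))
    return Strategy(
        method=method,
        kcat_changes=kcat_changes,
        abundance_changes=abundance_changes,
        n_kcat_changed=sum(1 for c in kcat_changes if c.changed),
        n_abundance_changed=sum(1 for a in abundance_changes if a.changed),
        v_pro_achieved=fluxes[ref.product_reaction_id],
        v_bio_achieved=fluxes[model.biomass_reaction_id],
        fluxes=fluxes, usages=usages, abundances=abundances,
        objective_value=objective_value, solver_status=status,
        product_reaction_id=ref.product_reaction_id)


def _diagnose(model: EcModel, ref: WildTypeReference, params: OkoParams,
              ranges) -> str | None:
    """Identify which requirement makes the MILP infeasible by relaxing the
    production floor, then the growth floor, then the abundance band."""
    import dataclasses
    trials = [
        ("production", dataclasses.replace(params, f_pro=0.0)),
        ("growth", dataclasses.replace(params, alpha_bio=0.0)),
        # alpha/beta_e blown up so the band spans [0, pool_cap/MW]
        ("abundance_band", dataclasses.replace(params, alpha=1e12,
                                               beta_e=1e12)),
    ]
    for label, p in trials:
        try:
            lm = _build_engineering_milp(model, ref, p, ranges)
            solve(lm, backend=p.backend, time_limit=p.time_limit,
                  mip_gap=p.mip_gap)
            return label
        except InfeasibleError:
            continue
    return None


def _solve_engineering(model: EcModel, ref: WildTypeReference,
                       params: OkoParams,
                       ranges: dict[tuple[str, str], PairRange] | None,
                       method: str) -> Strategy:
    params.validate()
    lm = _build_engineering_milp(model, ref, params, ranges)
    try:
        sol = solve(lm, backend=params.backend, time_limit=params.time_limit,
                    mip_gap=params.mip_gap)
    except InfeasibleError:
        binding = _diagnose(model, ref, params, ranges)
        what = {"production": "the production requirement (f_pro)",
                "growth": "the growth requirement (alpha_bio)",
                "abundance_band": "the abundance band",
                None: "no single requirement (joint infeasibility)"}[binding]
        raise OkoInfeasibleError(
            f"engineering MILP infeasible; relaxation analysis: "
            f"feasibility is restored by relaxing {what}", binding) from None
    y_pattern = {(p.enzyme_id, p.reaction_id):
                 int(round(sol[yname(p.enzyme_id, p.reaction_id)]))
                 for p in model.pairs}
    ye_pattern = None
    if ranges is not None:
        ye_pattern = {e.enzyme_id: int(round(sol[yename(e.enzyme_id)]))
                      for e in model.enzymes}
    try:
        polished = _polish(model, ref, params, ranges, y_pattern, ye_pattern)
    except InfeasibleError:
        # the incumbent leaned on MIP tolerances; keep it but recount flags
        logger.warning("polish LP infeasible for the incumbent binary "
                       "pattern; reporting unpolished solution")
        polished = sol
    return _extract(model, ref, params, polished, y_pattern, ye_pattern,
                    method, sol.objective, sol.status)


def solve_oko(model: EcModel, ref: WildTypeReference,
              params: OkoParams | None = None) -> Strategy:
    """Minimum number of modified turnover numbers at fixed abundances."""
    return _solve_engineering(model, ref, params or OkoParams(), None, "oko")


def solve_oko_plus(model: EcModel, ref: WildTypeReference,
                   ranges: list[PairRange],
                   params: OkoParams | None = None) -> Strategy:
    """OKO restricted to externally predicted kcat ranges, with counted
    abundance modifications allowed."""
    rmap = {(r.enzyme_id, r.reaction_id): r for r in ranges}
    return _solve_engineering(model, ref, params or OkoParams(), rmap,
                              "oko_plus")


# ---------------------------------------------------------------------------
# arithmetic audit
# ---------------------------------------------------------------------------

def audit_strategy(model: EcModel, ref: WildTypeReference, params: OkoParams,
                   strategy: Strategy,
                   ranges: list[PairRange] | None = None,
                   tol: float = AUDIT_TOL) -> list[str]:
    """Re-check every constraint of the engineering program on the returned
    solution, outside the solver.  Returns a list of violations (empty when
    the strategy is certified)."""
    bad: list[str] = []
    v = strategy.fluxes
    u = strategy.usages
    E = strategy.abundances
    plus = strategy.method == "oko_plus"
    rmap = {(r.enzyme_id, r.reaction_id): r for r in (ranges or [])}

    # steady state
    balance: dict[str, float] = {m: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        for met, coeff in rxn.mets.items():
            balance[met] += coeff * v[rxn.reaction_id]
    for met, val in balance.items():
        if abs(val) > tol * max(1.0, max(abs(x) for x in v.values())):
            bad.append(f"mass balance violated at {met}: {val:g}")
    # flux bounds
    for rxn in model.reactions:
        x = v[rxn.reaction_id]
        if x < rxn.lb - tol or x > rxn.ub + tol:
            bad.append(f"flux bound violated for {rxn.reaction_id}: {x:g} "
                       f"not in [{rxn.lb:g}, {rxn.ub:g}]")
    # usage balance and pool
    for enz in model.enzymes:
        tot = sum(u[(p.enzyme_id, p.reaction_id)] for p in model.pairs
                  if p.enzyme_id == enz.enzyme_id)
        if abs(tot - E[enz.enzyme_id]) > tol:
            bad.append(f"usage split of {enz.enzyme_id} does not sum to its "
                       f"abundance: {tot:g} vs {E[enz.enzyme_id]:g}")
    pool = sum(e.mw * E[e.enzyme_id] for e in model.enzymes)
    if pool > model.pool_capacity + tol:
        bad.append(f"pool constraint violated: {pool:g} > "
                   f"{model.pool_capacity:g}")
    # abundance bands
    for a in strategy.abundance_changes:
        ewt = ref.e_wt.get(a.enzyme_id, 0.0)
        if plus:
            if not a.changed and not (
                    (1 - params.beta_e) * ewt - tol <= a.e_eng
                    <= (1 + params.beta_e) * ewt + tol):
                bad.append(f"unchanged abundance of {a.enzyme_id} outside the "
                           f"beta_e band: {a.e_eng:g} vs wt {ewt:g}")
        else:
            if not ((1 - params.alpha) * ewt - tol <= a.e_eng
                    <= (1 + params.alpha) * ewt + tol):
                bad.append(f"abundance of {a.enzyme_id} outside the alpha "
                           f"band: {a.e_eng:g} vs wt {ewt:g}")
    # per-pair rate law and kcat bands
    for p in model.pairs:
        key = (p.enzyme_id, p.reaction_id)
        uu = u[key]
        de = v[p.reaction_id] - p.kcat * uu
        scale = max(1.0, abs(p.kcat * uu))
        if abs(de) > params.big_m * uu + tol * scale:
            bad.append(f"de bound (big-M) violated for {key}")
        lo = p.kcat * (1 / params.beta2 - 1) * uu
        hi = p.kcat * (params.beta2 - 1) * uu
        if de < lo - tol * scale or de > hi + tol * scale:
            bad.append(f"fold-change band violated for {key}: de={de:g} "
                       f"not in [{lo:g}, {hi:g}]")
        ch = next(c for c in strategy.kcat_changes
                  if (c.enzyme_id, c.reaction_id) == key)
        if not ch.changed and abs(de) > params.beta1 * p.kcat * uu + tol * scale:
            bad.append(f"pair {key} flagged unchanged but |de|={abs(de):g} "
                       f"exceeds the beta1 band")
        if plus:
            rng = rmap.get(key)
            if rng is None:
                if ch.changed:
                    bad.append(f"pair {key} modified without an admissible range")
            elif ch.changed and uu > USAGE_TOL:
                kstar = p.kcat + de / uu
                if not (rng.kmin - tol * scale / uu <= kstar
                        <= rng.kmax + tol * scale / uu):
                    bad.append(f"pair {key}: kcat* {kstar:g} outside its "
                               f"admissible range [{rng.kmin:g}, {rng.kmax:g}]")
    # production and growth floors
    if strategy.v_pro_achieved < params.f_pro * ref.v_pro_max - tol:
        bad.append(f"production floor violated: {strategy.v_pro_achieved:g} < "
                   f"{params.f_pro * ref.v_pro_max:g}")
    if strategy.v_bio_achieved < params.alpha_bio * ref.v_bio_opt - tol:
        bad.append(f"growth floor violated: {strategy.v_bio_achieved:g} < "
                   f"{params.alpha_bio * ref.v_bio_opt:g}")
    return bad
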
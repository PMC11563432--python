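"""Wild-type proteome allocation and its robustness.

The engineering workflow starts from a wild-type reference state obtained in
three LP solves on the ec-model:

1. maximize growth  ->  v_bio^opt;
2. maximize product flux while holding growth (almost) at its optimum
   ->  v_pro^max;
3. minimize total enzyme usage  ``min sum_i E_i``  subject to retaining at
   least 98% of both optima  ->  the reference abundances E^wt and the
   per-pair usage split u^wt.

A subsequent variability analysis (per-enzyme min/max of E_i at fixed total
usage ``sum_i E_i = sum_e*``) quantifies how pinned-down the reference
abundances are; narrow ranges justify using E^wt as the anchor of the
downstream engineering MILP.

Enzyme coupling uses per-pair usage variables: ``v_j = kcat_ij * u_ij`` for
every catalytic pair and ``sum_j u_ij = E_i`` per enzyme (an inequality mode
``<=`` is available; on well-posed models the two agree because idle enzyme
mass is never forced).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import LinearModel, SolverError, solve
from .ec_model import EcModel

__all__ = [
    "WildTypeReference",
    "VariabilityRecord",
    "maximize_growth",
    "maximize_product",
    "minimize_enzyme_usage",
    "compute_reference",
    "enzyme_variability",
    "build_allocation_lp",
    "vname", "uname", "ename",
    "USAGE_FLOOR_FRAC",
    "LOG_RATIO_EPS",
]

#: retention factor applied to both optima in the usage-minimization LP
USAGE_FLOOR_FRAC = 0.98
#: stabilizer for the variability log-ratio (solver feasibility tolerance)
LOG_RATIO_EPS = 1e-9
#: growth floor used when "at optimal growth" is required (avoids knife-edge
#: infeasibility of a strict equality)
AT_OPTIMUM_FRAC = 1.0 - 1e-6


def vname(reaction_id: str) -> str:
    return f"v::{reaction_id}"


def uname(enzyme_id: str, reaction_id: str) -> str:
    return f"u::{enzyme_id}::{reaction_id}"


def ename(enzyme_id: str) -> str:
    return f"E::{enzyme_id}"


def build_allocation_lp(model: EcModel, coupling: str = "equality",
                        name: str = "allocation") -> LinearModel:
    """Assemble the ec-FBA constraint set shared by every solve in the package.

    Variables: one flux per reaction, one usage per catalytic pair, one
    abundance per enzyme.  Constraints: steady state ``N v = 0``, flux
    bounds, per-pair coupling ``v_j = kcat_ij * u_ij``, per-enzyme usage
    balance (equality or ``<=``), and the protein pool
    ``sum_i MW_i * E_i <= sigma * f * P_total``.
    """
    if coupling not in ("equality", "inequality"):
        raise ValueError(f"coupling must be 'equality' or 'inequality', "
                         f"got {coupling!r}")
    lm = LinearModel(name=name)
    cap = model.pool_capacity
    for rxn in model.reactions:
        lm.add_var(vname(rxn.reaction_id), rxn.lb, rxn.ub)
    for enz in model.enzymes:
        lm.add_var(ename(enz.enzyme_id), 0.0, cap / enz.mw)
    for p in model.pairs:
        lm.add_var(uname(p.enzyme_id, p.reaction_id), 0.0, np.inf)

    # N v = 0
    by_met: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        for met, coeff in rxn.mets.items():
            by_met.setdefault(met, {})[vname(rxn.reaction_id)] = coeff
    for met, row in by_met.items():
        lm.add_constraint(row, 0.0, 0.0, name=f"mass::{met}")

    # v_j = kcat_ij u_ij per pair
    for p in model.pairs:
        lm.add_constraint(
            {vname(p.reaction_id): 1.0, uname(p.enzyme_id, p.reaction_id): -p.kcat},
            0.0, 0.0, name=f"cat::{p.enzyme_id}::{p.reaction_id}")

    # sum_j u_ij (= or <=) E_i
    for enz in model.enzymes:
        row = {ename(enz.enzyme_id): -1.0}
        for p in model.pairs:
            if p.enzyme_id == enz.enzyme_id:
                row[uname(p.enzyme_id, p.reaction_id)] = 1.0
        lb = 0.0 if coupling == "equality" else -np.inf
        lm.add_constraint(row, lb, 0.0, name=f"use::{enz.enzyme_id}")

    # pool
    lm.add_constraint({ename(e.enzyme_id): e.mw for e in model.enzymes},
                      -np.inf, cap, name="pool")
    return lm


@dataclass
class WildTypeReference:
    """Wild-type anchor state for the engineering step."""

    v_bio_opt: float                        # h^-1
    v_pro_max: float                        # mmol gDW^-1 h^-1
    e_wt: dict[str, float]                  # enzyme -> abundance, mmol gDW^-1
    u_wt: dict[tuple[str, str], float]      # (enzyme, reaction) -> usage
    sum_e_star: float                       # mmol gDW^-1
    product_reaction_id: str
    floor_frac: float = USAGE_FLOOR_FRAC

    def to_json(self, path) -> None:
        doc = {
            "v_bio_opt": self.v_bio_opt,
            "v_pro_max": self.v_pro_max,
            "e_wt": self.e_wt,
            "u_wt": [[e, r, u] for (e, r), u in self.u_wt.items()],
            "sum_e_star": self.sum_e_star,
            "product_reaction_id": self.product_reaction_id,
            "floor_frac": self.floor_frac,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "WildTypeReference":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            v_bio_opt=doc["v_bio_opt"], v_pro_max=doc["v_pro_max"],
            e_wt={k: float(v) for k, v in doc["e_wt"].items()},
            u_wt={(e, r): float(u) for e, r, u in doc["u_wt"]},
            sum_e_star=doc["sum_e_star"],
            product_reaction_id=doc["product_reaction_id"],
            floor_frac=doc.get("floor_frac", USAGE_FLOOR_FRAC),
        )


@dataclass(frozen=True)
class VariabilityRecord:
    enzyme_id: str
    e_min: float
    e_max: float
    log_ratio: float


def maximize_growth(model: EcModel, coupling: str = "equality",
                    backend: str = "highs") -> float:
    """Maximum growth rate under the ec-FBA constraints (h^-1)."""
    lm = build_allocation_lp(model, coupling, name="max_growth")
    lm.set_objective({vname(model.biomass_reaction_id): 1.0}, "max")
    return solve(lm, backend=backend).objective


def maximize_product(model: EcModel, product: str,
                     bio_floor_frac: float = AT_OPTIMUM_FRAC,
                     v_bio_opt: float | None = None,
                     coupling: str = "equality",
                     backend: str = "highs") -> float:
    """Maximum product flux while retaining `bio_floor_frac` of optimal growth."""
    if not 0.0 <= bio_floor_frac <= 1.0:
        raise ValueError(f"bio_floor_frac must lie in [0, 1], got {bio_floor_frac}")
    product_rxn = model.resolve_product(product)
    if v_bio_opt is None:
        v_bio_opt = maximize_growth(model, coupling, backend)
    lm = build_allocation_lp(model, coupling, name="max_product")
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      bio_floor_frac * v_bio_opt, np.inf, name="bio_floor")
    lm.set_objective({vname(product_rxn): 1.0}, "max")
    return solve(lm, backend=backend).objective


def minimize_enzyme_usage(model: EcModel, product: str, v_pro_max: float,
                          v_bio_opt: float, floor_frac: float = USAGE_FLOOR_FRAC,
                          coupling: str = "equality",
                          backend: str = "highs") -> WildTypeReference:
    """Minimal-total-abundance allocation retaining both optima.

    Solves ``min sum_i E_i`` subject to the ec-FBA constraints plus
    ``v_pro >= floor_frac * v_pro_max`` and ``v_bio >= floor_frac * v_bio_opt``.
    """
    product_rxn = model.resolve_product(product)
    lm = build_allocation_lp(model, coupling, name="min_usage")
    lm.add_constraint({vname(product_rxn): 1.0},
                      floor_frac * v_pro_max, np.inf, name="pro_floor")
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      floor_frac * v_bio_opt, np.inf, name="bio_floor")
    lm.set_objective({ename(e.enzyme_id): 1.0 for e in model.enzymes}, "min")
    try:
        sol = solve(lm, backend=backend)
    except SolverError as err:
        raise SolverError(
            "usage-minimization LP infeasible although both optima were "
            "computed under identical constraints; model state is "
            "internally inconsistent") from err
    e_wt = {e.enzyme_id: max(0.0, sol[ename(e.enzyme_id)]) for e in model.enzymes}
    u_wt = {(p.enzyme_id, p.reaction_id):
            max(0.0, sol[uname(p.enzyme_id, p.reaction_id)]) for p in model.pairs}
    return WildTypeReference(
        v_bio_opt=v_bio_opt, v_pro_max=v_pro_max, e_wt=e_wt, u_wt=u_wt,
        sum_e_star=sol.objective, product_reaction_id=product_rxn,
        floor_frac=floor_frac,
    )


def compute_reference(model: EcModel, product: str,
                      bio_floor_frac: float = AT_OPTIMUM_FRAC,
                      floor_frac: float = USAGE_FLOOR_FRAC,
                      coupling: str = "equality",
                      backend: str = "highs") -> WildTypeReference:
    """Run the full wild-type pipeline (growth, product, usage minimization)."""
    v_bio_opt = maximize_growth(model, coupling, backend)
    v_pro_max = maximize_product(model, product, bio_floor_frac, v_bio_opt,
                                 coupling, backend)
    return minimize_enzyme_usage(model, product, v_pro_max, v_bio_opt,
                                 floor_frac, coupling, backend)


def stabilized_log_ratio(e_max: float, e_min: float,
                         eps: float = LOG_RATIO_EPS) -> float:
    """log10 of e_max/e_min, stabilized near zero abundances.

    Both values are offset by the solver feasibility tolerance so the ratio
    is bounded and reduces to the plain ratio when both are >> eps.
    """
    return max(0.0, math.log10((max(e_max, 0.0) + eps) / (max(e_min, 0.0) + eps)))


def enzyme_variability(model: EcModel, ref: WildTypeReference,
                       enzymes: list[str] | None = None,
                       coupling: str = "equality",
                       backend: str = "highs") -> list[VariabilityRecord]:
    """Per-enzyme abundance ranges compatible with the minimal total usage.

    For each enzyme, minimizes and maximizes E_i subject to the reference
    constraint set plus ``sum_i E_i = sum_e*``.
    """
    ids = [e.enzyme_id for e in model.enzymes] if enzymes is None else list(enzymes)
    for eid in ids:
        model.enzyme(eid)  # raises KeyError on unknown ids
    records = []
    lm = build_allocation_lp(model, coupling, name="variability")
    lm.add_constraint({vname(ref.product_reaction_id): 1.0},
                      ref.floor_frac * ref.v_pro_max, np.inf, name="pro_floor")
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      ref.floor_frac * ref.v_bio_opt, np.inf, name="bio_floor")
    # equality up to the feasibility tolerance: the stored optimum may not be
    # exactly re-attainable in floating point
    slack = LOG_RATIO_EPS * max(1.0, abs(ref.sum_e_star))
    lm.add_constraint({ename(e.enzyme_id): 1.0 for e in model.enzymes},
                      ref.sum_e_star - slack, ref.sum_e_star + slack,
                      name="total_usage")
    for eid in ids:
        lo, hi = [], []
        for sense, store in (("min", lo), ("max", hi)):
            lm.set_objective({ename(eid): 1.0}, sense)
            store.append(solve(lm, backend=backend).objective)
        e_min, e_max = max(0.0, lo[0]), max(0.0, hi[0])
        records.append(VariabilityRecord(
            enzyme_id=eid, e_min=e_min, e_max=e_max,
            log_ratio=stabilized_log_ratio(e_max, e_min)))
    return records


def variability_frame(records: list[VariabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.enzyme_id, r.e_min, r.e_max, r.log_ratio) for r in records],
        columns=["enzyme_id", "e_min", "e_max", "log_ratio"])
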
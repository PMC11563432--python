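"""Post-processing of engineering strategies.

Construction of engineered models (kcats substituted by the optimizer's
estimates or by the closest predicted values from other organisms),
re-evaluation of achievable production in those models, and classification
of the proposed modifications (direction, knockout-replaceability,
promiscuity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solver import InfeasibleError, solve
from .allocation import WildTypeReference, build_allocation_lp, ename, vname
from .ec_model import EcModel
from .kcat_catalog import PredictedKcat, closest_value
from .oko_milp import OkoParams, Strategy

logger = logging.getLogger("oko")

__all__ = [
    "StrategyReport",
    "ChangeRecord",
    "apply_strategy",
    "evaluate_strategy",
    "production_ratio",
    "classify_changes",
]

#: flux magnitude below which a reaction counts as carrying zero flux
#: (mmol gDW^-1 h^-1); a kcat decrease on such a reaction is replaceable
#: by a knockout
ZERO_FLUX_TOL = 1e-6


@dataclass(frozen=True)
class ChangeRecord:
    enzyme_id: str
    reaction_id: str
    direction: str                  # "increase" | "decrease"
    knockout_replaceable: bool
    closest_organism: str | None = None
    closest_kcat_s: float | None = None
    closest_distance_s: float | None = None


@dataclass
class StrategyReport:
    changes: list[ChangeRecord]
    n_up: int
    n_down: int
    promiscuous_fraction: float     # over changed enzymes with >= 2 pairs
    evaluation_ratio: float | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.enzyme_id, c.reaction_id, c.direction,
              c.knockout_replaceable, c.closest_organism or "",
              c.closest_distance_s if c.closest_distance_s is not None
              else float("nan"))
             for c in self.changes],
            columns=["enzyme_id", "reaction_id", "direction",
                     "knockout_replaceable", "closest_organism",
                     "closest_distance_s"])


def apply_strategy(model: EcModel, strategy: Strategy,
                   source: str = "estimated",
                   mapping: dict[tuple[str, str], list[PredictedKcat]] | None = None,
                   ) -> EcModel:
    """Engineered copy of the model with modified kcats substituted.

    ``source="estimated"`` installs the optimizer's kcat* values;
    ``source="closest"`` installs, for each modified pair, the catalog
    prediction closest to kcat* (requires a mapping covering every
    modified pair).
    """
    if source not in ("estimated", "closest"):
        raise ValueError(f"source must be 'estimated' or 'closest', got {source!r}")
    new_kcats: dict[tuple[str, str], float] = {}
    uncovered = []
    for c in strategy.changed:
        key = (c.enzyme_id, c.reaction_id)
        if source == "estimated":
            new_kcats[key] = c.kcat_star
        else:
            if mapping is None:
                raise ValueError("source='closest' requires a catalog mapping")
            m = closest_value(key, c.kcat_star, mapping)
            if m is None:
                uncovered.append(key)
            else:
                new_kcats[key] = m.kcat_s * 3600.0
    if uncovered:
        raise ValueError("source='closest': no catalog prediction for "
                         f"modified pairs {uncovered}")
    out = model.with_kcats(new_kcats)
    out.name = f"{model.name}[{source}]"
    return out


def evaluate_strategy(engineered: EcModel, ref: WildTypeReference,
                      strategy: Strategy, params: OkoParams) -> float:
    """Maximum production of the engineered model under the strategy's
    operating conditions.

    Solves a small MILP: maximize product flux subject to the ec-FBA
    constraints with the engineered kcats, growth at least the strategy's
    achieved growth (a floor, not an equality, which can be infeasible
    after float round-trip), and at most ``strategy.n_abundance_changed``
    abundances outside the ``(1 +/- beta_e) * E^wt`` band.
    """
    lm = build_allocation_lp(engineered, coupling="equality", name="evaluate")
    cap = engineered.pool_capacity
    ye_sum = {}
    for enz in engineered.enzymes:
        ewt = ref.e_wt.get(enz.enzyme_id, 0.0)
        ye = lm.add_binary(f"ye::{enz.enzyme_id}")
        lo_band = (1 - params.beta_e) * ewt
        hi_band = (1 + params.beta_e) * ewt
        me = max(lo_band, cap / enz.mw - hi_band, 0.0) + 1.0
        lm.add_constraint({ename(enz.enzyme_id): -1.0, ye: me},
                          -np.inf, me - lo_band)
        lm.add_constraint({ename(enz.enzyme_id): 1.0, ye: me},
                          -np.inf, me + hi_band)
        ye_sum[ye] = 1.0
    n_enz = len(engineered.enzymes)
    lm.add_constraint(ye_sum, n_enz - strategy.n_abundance_changed, np.inf,
                      name="abundance_budget")
    slack = 1e-9 * max(1.0, abs(strategy.v_bio_achieved))
    lm.add_constraint({vname(engineered.biomass_reaction_id): 1.0},
                      strategy.v_bio_achieved - slack, np.inf, name="bio_floor")
    lm.set_objective({vname(strategy.product_reaction_id): 1.0}, "max")
    sol = solve(lm, backend=params.backend, time_limit=params.time_limit,
                mip_gap=params.mip_gap)
    return sol.objective


def production_ratio(model: EcModel, ref: WildTypeReference,
                     strategy: Strategy, params: OkoParams,
                     mapping: dict[tuple[str, str], list[PredictedKcat]],
                     ) -> float:
    """Headline substitution check: max production with closest predicted
    kcats over max production with the optimizer's estimates.

    Returns 0 with a logged diagnostic when the closest-value model cannot
    meet the strategy's operating conditions.
    """
    est = apply_strategy(model, strategy, "estimated")
    clo = apply_strategy(model, strategy, "closest", mapping)
    v_est = evaluate_strategy(est, ref, strategy, params)
    if v_est <= 0:
        raise ValueError("estimated-kcat model achieves no production; "
                         "ratio undefined")
    try:
        v_clo = evaluate_strategy(clo, ref, strategy, params)
    except InfeasibleError as err:
        logger.warning("closest-value model infeasible under the strategy's "
                       "operating conditions (%s); reporting ratio 0", err)
        return 0.0
    return v_clo / v_est


def classify_changes(strategy: Strategy, model: EcModel,
                     mapping: dict[tuple[str, str], list[PredictedKcat]] | None = None,
                     zero_flux_tol: float = ZERO_FLUX_TOL) -> StrategyReport:
    """Classify every modified kcat of a strategy.

    Direction follows sign(kcat* - kcat_wt); a decrease whose reaction
    carries less than `zero_flux_tol` flux in the engineered solution is
    additionally flagged knockout-replaceable.  The promiscuous fraction is
    computed over the distinct modified enzymes, an enzyme counting as
    promiscuous when it has >= 2 catalytic pairs in the model.
    """
    degree: dict[str, int] = {}
    for p in model.pairs:
        degree[p.enzyme_id] = degree.get(p.enzyme_id, 0) + 1
    changes = []
    for c in sorted(strategy.changed,
                    key=lambda c: (c.enzyme_id, c.reaction_id)):
        flux = abs(strategy.fluxes.get(c.reaction_id, 0.0))
        ko = c.direction == "decrease" and flux < zero_flux_tol
        ann = (closest_value((c.enzyme_id, c.reaction_id), c.kcat_star, mapping)
               if mapping is not None else None)
        changes.append(ChangeRecord(
            enzyme_id=c.enzyme_id, reaction_id=c.reaction_id,
            direction=c.direction, knockout_replaceable=ko,
            closest_organism=ann.organism if ann else None,
            closest_kcat_s=ann.kcat_s if ann else None,
            closest_distance_s=ann.distance_s if ann else None))
    n_up = sum(1 for c in changes if c.direction == "increase")
    n_down = sum(1 for c in changes if c.direction == "decrease")
    enzymes = {c.enzyme_id for c in changes}
    prom = (sum(1 for e in enzymes if degree.get(e, 0) >= 2) / len(enzymes)
            if enzymes else 0.0)
    return StrategyReport(changes=changes, n_up=n_up, n_down=n_down,
                          promiscuous_fraction=prom)
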
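"""Toy ec-models and a brute-force certificate for the engineering MILP.

The generator builds small linear-pathway models — substrate uptake, an
enzymatic chain, and a branch point feeding biomass and product — with the
full ec-model structure (stoichiometry, bounds, per-pair kcats, molecular
weights, protein pool).  The canonical instance TOY1 has closed-form
optima: pool capacity 0.1 g/gDW split over two kcat-100 enzymes gives
``v_bio_opt = 5``, and at a 0.98 growth floor the pool balance
``0.098 + 0.03 v_pro = 0.1`` gives ``v_pro_max = 1/15 ~ 0.0667``.

The oracle certifies the MILP's minimum modification count by subset
enumeration: for every candidate set S of catalytic pairs it solves the LP
in which pairs in S may move within the fold-change band and all others
are pinned to the "unchanged" band.  This replaces the big-M indicator
logic by hard intervals — equivalent at optimality, since a binary y_ij
only encodes band membership: any MILP solution with ``y_ij = 0`` on S and
1 elsewhere is feasible for the S-LP and conversely, so the smallest
feasible |S| equals the MILP's minimum number of changed pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from ._solver import InfeasibleError, LinearModel, solve
from .allocation import WildTypeReference, ename, uname, vname
from .ec_model import CatalyticPair, EcModel, Enzyme, Reaction
from .oko_milp import OkoParams

__all__ = [
    "ToySpec",
    "GenerationError",
    "make_toy_model",
    "toy1",
    "random_toy_spec",
    "brute_force_min_changes",
    "OracleResult",
]

#: base seed for randomized toy variants; instance k uses DEFAULT_SEED + k
DEFAULT_SEED = 20240


class GenerationError(ValueError):
    """The requested toy specification yields an infeasible model."""


@dataclass
class ToySpec:
    """Linear chain uptake -> S_1 -> ... -> S_n = A, branching into biomass
    (enzymatic) and product (enzymatic, then a free demand).

    kcats lists chain enzymes first, then the biomass enzyme, then the
    product enzyme; all h^-1.
    """

    n_chain: int = 1
    kcats: list[float] = field(default_factory=lambda: [100.0, 100.0, 50.0])
    mws: list[float] | None = None            # g mmol^-1, default all 1
    pool: float = 0.1                         # sigma*f*P_total, g gDW^-1
    uptake_ub: float = 10.0                   # mmol gDW^-1 h^-1
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return self.n_chain + 2


def make_toy_model(spec: ToySpec | None = None, check: bool = True) -> EcModel:
    """Build the ec-model for a :class:`ToySpec` (defaults: TOY1)."""
    spec = spec or ToySpec()
    n = spec.n_chain
    if len(spec.kcats) != n + 2:
        raise GenerationError(f"need {n + 2} kcats for n_chain={n}, "
                              f"got {len(spec.kcats)}")
    mws = spec.mws or [1.0] * (n + 2)
    if len(mws) != n + 2:
        raise GenerationError(f"need {n + 2} molecular weights, got {len(mws)}")
    mets = [f"S{k}" for k in range(n)] + ["A", "P"]
    chain_mets = [f"S{k}" for k in range(n)] + ["A"]
    reactions = [Reaction("UPT", {"S0" if n else "A": 1.0}, 0.0, spec.uptake_ub)]
    enzymes, pairs = [], []
    for k in range(n):
        rid = f"R{k + 1}"
        reactions.append(Reaction(
            rid, {chain_mets[k]: -1.0, chain_mets[k + 1]: 1.0}, 0.0, math.inf))
        enzymes.append(Enzyme(f"E{k + 1}", mws[k]))
        pairs.append(CatalyticPair(f"E{k + 1}", rid, spec.kcats[k]))
    reactions.append(Reaction("R_bio", {"A": -1.0}, 0.0, math.inf))
    enzymes.append(Enzyme("E_bio", mws[n]))
    pairs.append(CatalyticPair("E_bio", "R_bio", spec.kcats[n]))
    reactions.append(Reaction("R_pro", {"A": -1.0, "P": 1.0}, 0.0, math.inf))
    enzymes.append(Enzyme("E_pro", mws[n + 1]))
    pairs.append(CatalyticPair("E_pro", "R_pro", spec.kcats[n + 1]))
    reactions.append(Reaction("DM_P", {"P": -1.0}, 0.0, math.inf))
    model = EcModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id="R_bio",
        enzymes=enzymes,
        pairs=pairs,
        sigma=1.0, f=1.0, p_total=spec.pool,
        product_exchanges={"P": "DM_P"},
        name=f"toy_chain{n}" + (f"_seed{spec.seed}" if spec.seed is not None else ""),
    )
    from .ec_model import ModelValidationError
    try:
        model.validate()
    except ModelValidationError as err:
        raise GenerationError(f"toy spec yields an invalid model: {err}") from err
    if check:
        from .allocation import maximize_growth
        if maximize_growth(model) <= 0:
            raise GenerationError("toy spec yields zero optimal growth")
    return model


def toy1() -> EcModel:
    """The canonical three-enzyme instance (closed-form optima known)."""
    return make_toy_model(ToySpec())


def random_toy_spec(index: int = 0, base_seed: int = DEFAULT_SEED) -> ToySpec:
    """Seeded randomized variant: chain length cycles over 1..4, kcats drawn
    log-uniformly from [10, 1000] h^-1."""
    seed = base_seed + index
    rng = np.random.default_rng(seed)
    n_chain = 1 + index % 4
    kcats = list(np.exp(rng.uniform(np.log(10.0), np.log(1000.0),
                                    size=n_chain + 2)))
    return ToySpec(n_chain=n_chain, kcats=[float(k) for k in kcats], seed=seed)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    min_count: int | None          # None: no feasible subset up to max_k
    witnesses: list[frozenset]     # all minimal subsets (of (enzyme, reaction))
    max_k: int

    def __str__(self) -> str:
        if self.min_count is None:
            return f"> {self.max_k}"
        return str(self.min_count)


def _subset_lp_feasible(model: EcModel, ref: WildTypeReference,
                        params: OkoParams,
                        free_pairs: frozenset, backend: str) -> bool:
    lm = LinearModel(name="oracle_subset")
    cap = model.pool_capacity
    for rxn in model.reactions:
        lm.add_var(vname(rxn.reaction_id), rxn.lb, rxn.ub)
    for enz in model.enzymes:
        ewt = ref.e_wt.get(enz.enzyme_id, 0.0)
        lm.add_var(ename(enz.enzyme_id),
                   max(0.0, (1 - params.alpha) * ewt),
                   min(cap / enz.mw, (1 + params.alpha) * ewt))
    for p in model.pairs:
        lm.add_var(uname(p.enzyme_id, p.reaction_id), 0.0, np.inf)
        lm.add_var(f"d::{p.enzyme_id}::{p.reaction_id}", -np.inf, np.inf)
    by_met: dict[str, dict[str, float]] = {}
    for rxn in model.reactions:
        for met, coeff in rxn.mets.items():
            by_met.setdefault(met, {})[vname(rxn.reaction_id)] = coeff
    for met, row in by_met.items():
        lm.add_constraint(row, 0.0, 0.0)
    for enz in model.enzymes:
        row = {ename(enz.enzyme_id): -1.0}
        for p in model.pairs:
            if p.enzyme_id == enz.enzyme_id:
                row[uname(p.enzyme_id, p.reaction_id)] = 1.0
        lm.add_constraint(row, 0.0, 0.0)
    lm.add_constraint({ename(e.enzyme_id): e.mw for e in model.enzymes},
                      -np.inf, cap)
    for p in model.pairs:
        key = (p.enzyme_id, p.reaction_id)
        u, d = uname(*key), f"d::{p.enzyme_id}::{p.reaction_id}"
        lm.add_constraint({vname(p.reaction_id): 1.0, u: -p.kcat, d: -1.0},
                          0.0, 0.0)
        if key in free_pairs:
            lo, hi = 1.0 / params.beta2 - 1.0, params.beta2 - 1.0
        else:
            lo, hi = -params.beta1, params.beta1
        lm.add_constraint({d: 1.0, u: -p.kcat * hi}, -np.inf, 0.0)
        lm.add_constraint({d: -1.0, u: p.kcat * lo}, -np.inf, 0.0)
    lm.add_constraint({vname(ref.product_reaction_id): 1.0},
                      params.f_pro * ref.v_pro_max, np.inf)
    lm.add_constraint({vname(model.biomass_reaction_id): 1.0},
                      params.alpha_bio * ref.v_bio_opt, np.inf)
    try:
        solve(lm, backend=backend)
        return True
    except InfeasibleError:
        return False


def brute_force_min_changes(model: EcModel, ref: WildTypeReference,
                            params: OkoParams | None = None,
                            max_k: int | None = None,
                            backend: str = "highs") -> OracleResult:
    """Certified minimum number of kcat modifications by subset enumeration.

    For k = 0, 1, ..., max_k and every k-subset S of catalytic pairs,
    solves the LP in which pairs in S range over the fold-change band and
    all others are pinned to the unchanged band, under the abundance band
    and the production/growth floors.  Returns the smallest feasible k with
    every witness subset at that k.
    """
    params = params or OkoParams()
    params.validate()
    keys = [(p.enzyme_id, p.reaction_id) for p in model.pairs]
    if len(keys) > 12:
        raise ValueError(f"oracle enumeration capped at 12 pairs, model has "
                         f"{len(keys)}")
    if max_k is None:
        max_k = len(keys)
    max_k = min(max_k, len(keys))
    for k in range(max_k + 1):
        witnesses = [frozenset(s) for s in itertools.combinations(keys, k)
                     if _subset_lp_feasible(model, ref, params,
                                            frozenset(s), backend)]
        if witnesses:
            return OracleResult(min_count=k, witnesses=witnesses, max_k=max_k)
    return OracleResult(min_count=None, witnesses=[], max_k=max_k)
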
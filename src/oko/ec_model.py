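"""Enzyme-constrained metabolic models (ecGEMs).

An :class:`EcModel` couples an ordinary stoichiometric model with enzymes:
each catalytically driven reaction ``j`` consumes capacity of its enzyme(s)
``i`` at rate ``v_j / kcat_ij``, and total enzyme mass is capped by the
protein-pool constraint ``sum_i MW_i * E_i <= sigma * f * P_total``.

Unit conventions, used throughout the package:

* fluxes: mmol gDW^-1 h^-1
* enzyme abundances / usages: mmol gDW^-1
* molecular weights: g mmol^-1
* turnover numbers: h^-1 internally; s^-1 in user-facing reports
  (the field reports kcat in s^-1, GECKO files encode 1/kcat in h)

Models can be read from a native JSON schema or imported from GECKO-style
SBML, where enzymes appear as ``prot_<accession>`` pseudo-metabolites drawn
from a shared protein pool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import sparse

__all__ = [
    "Enzyme",
    "CatalyticPair",
    "Reaction",
    "EcModel",
    "SchemaError",
    "ModelValidationError",
    "read_ec_model_json",
    "write_ec_model_json",
    "import_gecko_sbml",
    "PER_S_TO_PER_H",
]

PER_S_TO_PER_H = 3600.0


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


class ModelValidationError(ValueError):
    """Model violates one or more structural invariants."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("model validation failed:\n  - " + "\n  - ".join(failures))


@dataclass(frozen=True)
class Enzyme:
    enzyme_id: str
    mw: float                      # g mmol^-1
    accession: str | None = None


@dataclass(frozen=True)
class CatalyticPair:
    enzyme_id: str
    reaction_id: str
    kcat: float                    # h^-1

    @property
    def kcat_per_s(self) -> float:
        return self.kcat / PER_S_TO_PER_H


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    mets: dict[str, float]         # metabolite -> stoichiometric coefficient
    lb: float
    ub: float


@dataclass
class EcModel:
    metabolites: list[str]
    reactions: list[Reaction]
    biomass_reaction_id: str
    enzymes: list[Enzyme]
    pairs: list[CatalyticPair]
    sigma: float = 1.0             # average in vivo saturation, dimensionless
    f: float = 1.0                 # mass fraction of modelled enzymes
    p_total: float = 1.0           # total protein content, g gDW^-1
    product_exchanges: dict[str, str] = field(default_factory=dict)
    name: str = "ec_model"

    # -- lookups -----------------------------------------------------------
    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._rxn_index = {r.reaction_id: k for k, r in enumerate(self.reactions)}
        self._met_index = {m: k for k, m in enumerate(self.metabolites)}
        self._enz_index = {e.enzyme_id: k for k, e in enumerate(self.enzymes)}

    @property
    def pool_capacity(self) -> float:
        """sigma * f * P_total, g gDW^-1."""
        return self.sigma * self.f * self.p_total

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[reaction_id]]
        except KeyError:
            raise KeyError(f"reaction {reaction_id!r} not in model") from None

    def enzyme(self, enzyme_id: str) -> Enzyme:
        try:
            return self.enzymes[self._enz_index[enzyme_id]]
        except KeyError:
            raise KeyError(f"enzyme {enzyme_id!r} not in model") from None

    def pairs_by_enzyme(self) -> dict[str, list[CatalyticPair]]:
        out: dict[str, list[CatalyticPair]] = {e.enzyme_id: [] for e in self.enzymes}
        for p in self.pairs:
            out[p.enzyme_id].append(p)
        return out

    def pairs_by_reaction(self) -> dict[str, list[CatalyticPair]]:
        out: dict[str, list[CatalyticPair]] = {}
        for p in self.pairs:
            out.setdefault(p.reaction_id, []).append(p)
        return out

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        data, ri, ci = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.mets.items():
                ri.append(self._met_index[met])
                ci.append(j)
                data.append(coeff)
        return sparse.csr_matrix((data, (ri, ci)),
                                 shape=(len(self.metabolites), len(self.reactions)))

    # -- editing -----------------------------------------------------------
    def copy(self) -> "EcModel":
        return EcModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, mets=dict(r.mets)) for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
            enzymes=list(self.enzymes),
            pairs=list(self.pairs),
            sigma=self.sigma, f=self.f, p_total=self.p_total,
            product_exchanges=dict(self.product_exchanges),
            name=self.name,
        )

    def with_kcats(self, new_kcats: dict[tuple[str, str], float]) -> "EcModel":
        """Copy of the model with selected (enzyme, reaction) kcats replaced."""
        out = self.copy()
        out.pairs = [
            replace(p, kcat=new_kcats.get((p.enzyme_id, p.reaction_id), p.kcat))
            for p in self.pairs
        ]
        return out

    def ensure_demand(self, metabolite: str) -> str:
        """Return a demand reaction id for `metabolite`, adding one if absent.

        A demand reaction drains the metabolite irreversibly
        (coefficient -1, bounds [0, inf)).
        """
        if metabolite in self.product_exchanges:
            return self.product_exchanges[metabolite]
        if metabolite not in self._met_index:
            raise KeyError(f"metabolite {metabolite!r} not in model")
        for rxn in self.reactions:
            if rxn.mets == {metabolite: -1.0} and rxn.ub > 0 and rxn.lb >= 0:
                self.product_exchanges[metabolite] = rxn.reaction_id
                return rxn.reaction_id
        rid = f"DM_{metabolite}"
        if rid in self._rxn_index:
            rid = f"DM_{metabolite}_oko"
        self.reactions.append(Reaction(rid, {metabolite: -1.0}, 0.0, math.inf))
        self.product_exchanges[metabolite] = rid
        self._reindex()
        return rid

    def resolve_product(self, product: str) -> str:
        """Map a reaction or metabolite identifier to the product reaction id."""
        if product in self._rxn_index:
            return product
        if product in self._met_index:
            return self.ensure_demand(product)
        raise KeyError(f"product {product!r} is neither a reaction nor a "
                       "metabolite of the model")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants, raising with every failure listed."""
        bad: list[str] = []
        if len(set(self.metabolites)) != len(self.metabolites):
            bad.append("duplicate metabolite ids")
        rids = [r.reaction_id for r in self.reactions]
        if len(set(rids)) != len(rids):
            bad.append("duplicate reaction ids")
        eids = [e.enzyme_id for e in self.enzymes]
        if len(set(eids)) != len(eids):
            bad.append("duplicate enzyme ids")
        for e in self.enzymes:
            if not e.mw > 0:
                bad.append(f"enzyme {e.enzyme_id!r}: mw must be > 0, got {e.mw}")
        for r in self.reactions:
            if r.lb > r.ub:
                bad.append(f"reaction {r.reaction_id!r}: lb {r.lb} > ub {r.ub}")
            for met in r.mets:
                if met not in self._met_index:
                    bad.append(f"reaction {r.reaction_id!r}: unknown metabolite {met!r}")
        if self.biomass_reaction_id not in self._rxn_index:
            bad.append(f"biomass reaction {self.biomass_reaction_id!r} not in model")
        seen_pairs = set()
        for p in self.pairs:
            key = (p.enzyme_id, p.reaction_id)
            if key in seen_pairs:
                bad.append(f"duplicate catalytic pair {key}")
            seen_pairs.add(key)
            if not p.kcat > 0:
                bad.append(f"pair {key}: kcat must be > 0, got {p.kcat}")
            if p.enzyme_id not in self._enz_index:
                bad.append(f"pair {key}: unknown enzyme")
            if p.reaction_id not in self._rxn_index:
                bad.append(f"pair {key}: unknown reaction")
            elif self.reaction(p.reaction_id).lb < 0:
                bad.append(f"pair {key}: enzymatic reaction must be irreversible "
                           f"(lb >= 0), got lb {self.reaction(p.reaction_id).lb}")
        for nm, val in (("sigma", self.sigma), ("f", self.f)):
            if not (0 < val <= 1):
                bad.append(f"{nm} must lie in (0, 1], got {val}")
        if not self.p_total > 0:
            bad.append(f"p_total must be > 0, got {self.p_total}")
        if bad:
            raise ModelValidationError(bad)

    # -- reporting ---------------------------------------------------------
    def enzymes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.enzyme_id, e.accession or "", e.mw) for e in self.enzymes],
            columns=["enzyme_id", "accession", "mw_g_per_mmol"],
        )

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.enzyme_id, p.reaction_id, p.kcat_per_s, p.kcat) for p in self.pairs],
            columns=["enzyme_id", "reaction_id", "kcat_per_s", "kcat_per_h"],
        )

    def export_tsv(self, enzymes_path, pairs_path) -> None:
        self.enzymes_frame().to_csv(enzymes_path, sep="\t", index=False)
        self.pairs_frame().to_csv(pairs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# native JSON schema
# ---------------------------------------------------------------------------

def _require(obj: dict, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return obj[key]


def read_ec_model_json(path) -> EcModel:
    """Read an ec-model from the native JSON schema and validate it.

    kcat entries declare their unit as ``"per_s"`` or ``"per_h"``; per_s
    values are converted to the internal h^-1 on load.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path}: not valid JSON ({e})") from None
    mets = _require(doc, "metabolites", "top level")
    reactions = []
    for k, r in enumerate(_require(doc, "reactions", "top level")):
        where = f"reactions[{k}]"
        reactions.append(Reaction(
            reaction_id=str(_require(r, "id", where)),
            mets={str(m): float(c) for m, c in _require(r, "mets", where).items()},
            lb=float(_require(r, "lb", where)),
            ub=float(_require(r, "ub", where)),
        ))
    enzymes = []
    for k, e in enumerate(_require(doc, "enzymes", "top level")):
        where = f"enzymes[{k}]"
        enzymes.append(Enzyme(
            enzyme_id=str(_require(e, "id", where)),
            mw=float(_require(e, "mw", where)),
            accession=e.get("accession"),
        ))
    pairs = []
    for k, p in enumerate(_require(doc, "kcats", "top level")):
        where = f"kcats[{k}]"
        unit = _require(p, "unit", where)
        value = float(_require(p, "value", where))
        if unit == "per_s":
            kcat = value * PER_S_TO_PER_H
        elif unit == "per_h":
            kcat = value
        else:
            raise SchemaError(f"{where}: unit must be 'per_s' or 'per_h', got {unit!r}")
        pairs.append(CatalyticPair(
            enzyme_id=str(_require(p, "enzyme", where)),
            reaction_id=str(_require(p, "reaction", where)),
            kcat=kcat,
        ))
    pool = _require(doc, "pool", "top level")
    model = EcModel(
        metabolites=[str(m) for m in mets],
        reactions=reactions,
        biomass_reaction_id=str(_require(doc, "biomass", "top level")),
        enzymes=enzymes,
        pairs=pairs,
        sigma=float(_require(pool, "sigma", "pool")),
        f=float(_require(pool, "f", "pool")),
        p_total=float(_require(pool, "p_total", "pool")),
        product_exchanges={str(m): str(r)
                           for m, r in doc.get("product_exchanges", {}).items()},
        name=str(doc.get("name", "ec_model")),
    )
    model.validate()
    return model


def write_ec_model_json(model: EcModel, path) -> None:
    """Write an ec-model in the native JSON schema (kcats in h^-1)."""
    def _num(x: float):
        return x if math.isfinite(x) else ("inf" if x > 0 else "-inf")

    doc = {
        "name": model.name,
        "metabolites": list(model.metabolites),
        "reactions": [
            {"id": r.reaction_id, "mets": dict(r.mets),
             "lb": _num(r.lb), "ub": _num(r.ub)}
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
        "enzymes": [
            {"id": e.enzyme_id, "accession": e.accession, "mw": e.mw}
            for e in model.enzymes
        ],
        "kcats": [
            {"enzyme": p.enzyme_id, "reaction": p.reaction_id,
             "value": p.kcat, "unit": "per_h"}
            for p in model.pairs
        ],
        "pool": {"sigma": model.sigma, "f": model.f, "p_total": model.p_total},
        "product_exchanges": dict(model.product_exchanges),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# GECKO-style SBML import
# ---------------------------------------------------------------------------

PROT_PREFIX = "prot_"
POOL_TOKEN = "prot_pool"


class GeckoImportError(ValueError):
    """SBML file does not follow the expected GECKO conventions."""


def import_gecko_sbml(path) -> EcModel:
    """Import a GECKO-convention ecGEM from SBML.

    Decoding rules:

    * species whose id contains ``prot_pool`` is the shared protein pool;
      the reaction producing only pool is the pool exchange, and its upper
      bound is recorded as sigma*f*P_total (sigma = f = 1 individually,
      since the published files only expose the product);
    * other ``prot_<accession>`` species are enzymes; the draw reaction
      ``MW x pool -> prot_X`` yields the molecular weight;
    * a coefficient ``-c`` of ``prot_X`` in a metabolic reaction encodes
      ``kcat = 1/c`` (h^-1) for that (enzyme, reaction) pair.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))

    def is_pool(mid: str) -> bool:
        return POOL_TOKEN in mid

    def is_prot(mid: str) -> bool:
        return mid.startswith(PROT_PREFIX) and not is_pool(mid)

    pool_mets = [m.id for m in cm.metabolites if is_pool(m.id)]
    prot_mets = {m.id for m in cm.metabolites if is_prot(m.id)}
    if not pool_mets:
        raise GeckoImportError(f"{path}: no {POOL_TOKEN!r} species found")
    pool_met = pool_mets[0]

    pool_cap = None
    enzymes: dict[str, Enzyme] = {}
    pairs: list[CatalyticPair] = []
    reactions: list[Reaction] = []
    biomass_id = None
    if cm.objective is not None:
        for rxn in cm.reactions:
            if rxn.objective_coefficient:
                biomass_id = rxn.id
                break

    for rxn in cm.reactions:
        stoich = {m.id: float(c) for m, c in rxn.metabolites.items()}
        prot_part = {m: c for m, c in stoich.items() if m in prot_mets}
        pool_part = {m: c for m, c in stoich.items() if is_pool(m)}
        plain = {m: c for m, c in stoich.items()
                 if m not in prot_part and m not in pool_part}

        if pool_part and not plain and not prot_part:
            # pool exchange: -> prot_pool
            pool_cap = float(rxn.upper_bound)
            continue
        if pool_part and len(prot_part) == 1 and not plain:
            # draw reaction: MW x pool -> prot_X
            (pid, pc), = prot_part.items()
            pool_c = pool_part[pool_met]
            if pc <= 0 or pool_c >= 0:
                raise GeckoImportError(
                    f"{path}: draw reaction {rxn.id!r} has unexpected signs")
            acc = pid[len(PROT_PREFIX):].split("[")[0].rstrip("_c")
            enzymes[pid] = Enzyme(enzyme_id=acc, mw=-pool_c / pc, accession=acc)
            continue
        # metabolic (or exchange) reaction
        for pid, c in prot_part.items():
            if c >= 0:
                raise GeckoImportError(
                    f"{path}: protein {pid!r} produced (coefficient {c} >= 0) "
                    f"in reaction {rxn.id!r}")
            acc = pid[len(PROT_PREFIX):].split("[")[0].rstrip("_c")
            pairs.append(CatalyticPair(enzyme_id=acc, reaction_id=rxn.id,
                                       kcat=-1.0 / c))
        reactions.append(Reaction(rxn.id, plain,
                                  float(rxn.lower_bound), float(rxn.upper_bound)))

    if pool_cap is None:
        raise GeckoImportError(f"{path}: no pool exchange reaction found")
    if biomass_id is None:
        cands = [r.reaction_id for r in reactions
                 if "biomass" in r.reaction_id.lower() or "growth" in r.reaction_id.lower()]
        if not cands:
            raise GeckoImportError(f"{path}: cannot identify the biomass reaction")
        biomass_id = cands[0]

    used_mets = sorted({m for r in reactions for m in r.mets})
    enz_list = sorted(enzymes.values(), key=lambda e: e.enzyme_id)
    known = {e.enzyme_id for e in enz_list}
    # enzymes referenced by pairs but lacking a draw reaction get MW from
    # nothing we can recover; refuse rather than fabricate
    missing = sorted({p.enzyme_id for p in pairs} - known)
    if missing:
        raise GeckoImportError(
            f"{path}: enzymes without draw reactions (no recoverable MW): {missing}")

    model = EcModel(
        metabolites=used_mets,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        enzymes=enz_list,
        pairs=pairs,
        sigma=1.0, f=1.0, p_total=pool_cap,
        name=cm.id or "gecko_import",
    )
    model.validate()
    return model
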
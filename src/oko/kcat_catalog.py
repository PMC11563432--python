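"""Predicted-turnover catalogs and per-pair admissible ranges.

Deep-learning kcat predictors (DLKcat, TurNup and kin) emit per-organism
predictions keyed by protein accession and either a reaction or a substrate
metabolite.  This module loads such tables, maps them onto an ec-model's
catalytic pairs through a user-supplied key map (the offline stand-in for
live EC-number / MetaNetX resolution), and derives

* per-pair admissible ranges ``[kmin, kmax]`` — the min/max of all matched
  predictions across organisms, used to constrain kcat modifications; and
* closest-value queries — the prediction nearest to an engineered kcat*,
  identifying an existing enzyme (organism) that could realize it.

Catalog kcats are s^-1 on disk (predictor convention); ranges are h^-1
internally, like every other kcat in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ec_model import EcModel, PER_S_TO_PER_H

logger = logging.getLogger("oko")

__all__ = [
    "PredictedKcat",
    "PairRange",
    "ClosestMatch",
    "load_catalog",
    "load_pair_key_map",
    "map_pairs",
    "pair_ranges",
    "closest_value",
    "average_closest_distance",
    "ranges_frame",
]


@dataclass(frozen=True)
class PredictedKcat:
    accession: str
    key: str                  # reaction id or substrate metabolite id
    organism: str
    kcat_s: float             # s^-1
    source: str = ""


@dataclass(frozen=True)
class PairRange:
    enzyme_id: str
    reaction_id: str
    kmin: float               # h^-1
    kmax: float               # h^-1
    n_records: int


@dataclass(frozen=True)
class ClosestMatch:
    organism: str
    kcat_s: float
    distance_s: float         # |kcat*_s - prediction_s|, s^-1


def load_catalog(path, key_mode: str = "reaction") -> list[PredictedKcat]:
    """Load a delimited predictor table (columns: accession, key, organism,
    kcat in s^-1, optional source).

    Rows with non-positive or non-numeric kcat are skipped with a logged
    warning; duplicate (accession, key, organism) rows collapse to their
    maximum prediction.
    """
    if key_mode not in ("reaction", "metabolite"):
        raise ValueError(f"key_mode must be 'reaction' or 'metabolite', "
                         f"got {key_mode!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"{path}: none of the columns {names} found "
                         f"(have {list(df.columns)})")
    acc_c = col("accession", "enzyme", "uniprot")
    key_c = col("key", "reaction", "metabolite", "substrate")
    org_c = col("organism", "species")
    kc = col("kcat", "kcat_per_s", "kcat_s")
    src_c = cols.get("source")

    df[kc] = pd.to_numeric(df[kc], errors="coerce")
    bad = df[kc].isna() | (df[kc] <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        for idx in df.index[bad]:
            logger.warning("%s: row %d skipped (non-positive or non-numeric "
                           "kcat)", path, idx)
        logger.warning("%s: %d of %d rows skipped", path, n_bad, len(df))
        df = df[~bad]
    # duplicates collapse to the maximum prediction
    df = (df.sort_values(kc)
            .drop_duplicates(subset=[acc_c, key_c, org_c], keep="last"))
    return [
        PredictedKcat(
            accession=str(r[acc_c]), key=str(r[key_c]), organism=str(r[org_c]),
            kcat_s=float(r[kc]),
            source=str(r[src_c]) if src_c is not None and pd.notna(r[src_c]) else "")
        for _, r in df.iterrows()
    ]


def load_pair_key_map(path) -> dict[tuple[str, str], list[str]]:
    """TSV with columns enzyme, reaction, external_key: which catalog keys
    each model pair matches (one row per key)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], list[str]] = {}
    for _, r in df.iterrows():
        out.setdefault((str(r["enzyme"]), str(r["reaction"])), []).append(
            str(r["external_key"]))
    return out


def map_pairs(model: EcModel, catalog: list[PredictedKcat],
              pair_key_map: dict[tuple[str, str], list[str]],
              ) -> dict[tuple[str, str], list[PredictedKcat]]:
    """Match catalog records to model pairs.

    A pair maps to the union of records matching *any* of its external keys
    (a reaction contributes all its substrates), across all organisms.
    Accession matching uses the pair's enzyme accession when set, else the
    enzyme id.  Pairs without keys, or with keys but no hits, map to an
    empty list.
    """
    by_acc_key: dict[tuple[str, str], list[PredictedKcat]] = {}
    for rec in catalog:
        by_acc_key.setdefault((rec.accession, rec.key), []).append(rec)
    out: dict[tuple[str, str], list[PredictedKcat]] = {}
    for p in model.pairs:
        pid = (p.enzyme_id, p.reaction_id)
        enz = model.enzyme(p.enzyme_id)
        acc = enz.accession or enz.enzyme_id
        seen: set[int] = set()
        hits: list[PredictedKcat] = []
        for key in pair_key_map.get(pid, []):
            for rec in by_acc_key.get((acc, key), []):
                if id(rec) not in seen:
                    seen.add(id(rec))
                    hits.append(rec)
        out[pid] = hits
    return out


def pair_ranges(mapping: dict[tuple[str, str], list[PredictedKcat]],
                ) -> list[PairRange]:
    """[min, max] of matched predictions per pair, converted to h^-1.

    Pairs with no matched records yield no range (they stay frozen in the
    range-constrained engineering mode).
    """
    out = []
    for (eid, rid), recs in sorted(mapping.items()):
        if not recs:
            continue
        vals = [r.kcat_s * PER_S_TO_PER_H for r in recs]
        out.append(PairRange(enzyme_id=eid, reaction_id=rid,
                             kmin=min(vals), kmax=max(vals),
                             n_records=len(recs)))
    return out


def closest_value(pair: tuple[str, str], kcat_star: float,
                  mapping: dict[tuple[str, str], list[PredictedKcat]],
                  ) -> ClosestMatch | None:
    """Prediction nearest to an engineered kcat* (h^-1), across organisms.

    Returns None when no prediction is available for the pair.  Ties break
    on lexicographic organism name.
    """
    recs = mapping.get(pair, [])
    if not recs:
        return None
    target_s = kcat_star / PER_S_TO_PER_H
    best = min(recs, key=lambda r: (abs(target_s - r.kcat_s), r.organism))
    return ClosestMatch(organism=best.organism, kcat_s=best.kcat_s,
                        distance_s=abs(target_s - best.kcat_s))


def average_closest_distance(changes, mapping) -> float:
    """Arithmetic mean of closest-prediction distances (s^-1) over the
    modified pairs of a strategy that have predictions."""
    dists = []
    for c in changes:
        m = closest_value((c.enzyme_id, c.reaction_id), c.kcat_star, mapping)
        if m is not None:
            dists.append(m.distance_s)
    if not dists:
        raise ValueError("no modified pair has a catalog prediction")
    return sum(dists) / len(dists)


def ranges_frame(ranges: list[PairRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.enzyme_id, r.reaction_id, r.kmin / PER_S_TO_PER_H,
          r.kmax / PER_S_TO_PER_H, r.n_records) for r in ranges],
        columns=["enzyme", "reaction", "kmin_per_s", "kmax_per_s", "n_records"])


def read_ranges_tsv(path) -> list[PairRange]:
    df = pd.read_csv(path, sep="\t")
    return [PairRange(enzyme_id=str(r["enzyme"]), reaction_id=str(r["reaction"]),
                      kmin=float(r["kmin_per_s"]) * PER_S_TO_PER_H,
                      kmax=float(r["kmax_per_s"]) * PER_S_TO_PER_H,
                      n_records=int(r["n_records"]))
            for _, r in df.iterrows()]
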
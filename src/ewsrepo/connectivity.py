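"""Connectivity-map style reversal/mimicry scoring with permutation FDR.

The score of a drug instance against an up/down query signature is built
from two one-sided Kolmogorov–Smirnov-type enrichment statistics on the
instance's gene ranking (rank 1 = most up-regulated).  The combined score
lives in [-1, 1]: -1 means perfect reversal (the signature's up-genes sit
at the bottom of the drug's ranking and its down-genes at the top), +1
perfect mimicry, and 0 when the two halves agree in sign (no coherent
directional connectivity).

Drug-level scores aggregate replicate instances; significance comes from a
permutation null of random gene-signatures of matched sizes, and selection
applies a Benjamini–Hochberg FDR gate followed by top-K truncation, per
approach (disease / sirna / resistance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .signatures import DrugProfileDB, GeneSignature

__all__ = [
    "ks_enrichment",
    "connectivity_score",
    "score_database",
    "select_hits",
    "merge_hits",
    "HitList",
]


def ks_enrichment(positions: np.ndarray, n: int) -> float:
    """Signed KS enrichment of a gene set within a ranking of ``n`` genes.

    ``positions`` are the 1-based ranks the set's genes occupy.  With
    ``V(1) < ... < V(t)`` the sorted positions, the statistic is ``a`` if
    ``a >= b`` else ``-b`` where::

        a = max_j ( j/t - V(j)/n )      # concentration near the top
        b = max_j ( V(j)/n - (j-1)/t )  # concentration near the bottom

    Positive means the set crowds the top of the ranking (rank 1 end);
    negative the bottom.  A set spanning the whole universe scores 0 by
    convention.
    """
    v = np.sort(np.asarray(positions, dtype=float))
    t = v.size
    if t == 0:
        raise ValueError("empty gene set")
    if t > n:
        raise ValueError("gene set larger than the universe")
    if t == n:
        return 0.0
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a >= b else -b)


def _positions(sig_genes: list[str], ranking: pd.Series | dict) -> np.ndarray:
    rk = ranking if isinstance(ranking, pd.Series) else pd.Series(ranking)
    try:
        return rk.loc[sig_genes].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"signature gene missing from ranking: {exc}") from exc


def connectivity_score(sig: GeneSignature, ranking: pd.Series) -> float:
    """Signed reversal/mimicry score of one instance in [-1, 1].

    ``ranking`` maps gene id -> rank (1 = most up-regulated).  The score is
    ``(ks_up - ks_down)/2`` when the two enrichment halves disagree in sign
    (the coherent case) and 0 otherwise.  If one side of the signature is
    empty the other side's statistic is returned alone.
    """
    n = len(ranking)
    ks_up = ks_enrichment(_positions(sig.up, ranking), n) if sig.up else None
    ks_dn = ks_enrichment(_positions(sig.down, ranking), n) if sig.down else None
    if ks_up is None and ks_dn is None:
        raise ValueError("signature empty in both directions")
    if ks_dn is None:
        return ks_up
    if ks_up is None:
        return -ks_dn
    if np.sign(ks_up) == np.sign(ks_dn):
        return 0.0
    return (ks_up - ks_dn) / 2.0


# ---------------------------------------------------------------------------
# Vectorized internals (scoring many instances / permutations at once)


def _ks_matrix(pos: np.ndarray, n: int) -> np.ndarray:
    """ks_enrichment per column of a (t x m) matrix of 1-based positions."""
    v = np.sort(pos.astype(float), axis=0)
    t = v.shape[0]
    if t == n:
        return np.zeros(v.shape[1])
    j = np.arange(1, t + 1, dtype=float)[:, None]
    a = np.max(j / t - v / n, axis=0)
    b = np.max(v / n - (j - 1) / t, axis=0)
    return np.where(a >= b, a, -b)


def _score_instances(up_idx: np.ndarray, dn_idx: np.ndarray,
                     pos_matrix: np.ndarray) -> np.ndarray:
    """Combined score for every instance column of ``pos_matrix``.

    ``pos_matrix`` is genes x instances of 1-based ranks; ``up_idx``/
    ``dn_idx`` index rows (gene universe order).
    """
    n = pos_matrix.shape[0]
    ks_up = _ks_matrix(pos_matrix[up_idx, :], n)
    ks_dn = _ks_matrix(pos_matrix[dn_idx, :], n)
    s = (ks_up - ks_dn) / 2.0
    s[np.sign(ks_up) == np.sign(ks_dn)] = 0.0
    return s


_AGGREGATORS = {"median": np.median,
                "max_magnitude": lambda x: x[np.argmax(np.abs(x))]}


def score_database(sig: GeneSignature, db: DrugProfileDB, n_perm: int = 1000,
                   seed: int = 0, approach: str | None = None,
                   aggregate: str = "median") -> pd.DataFrame:
    """Score every drug in the database against a query signature.

    Per-instance scores are aggregated to a drug score (median by default;
    ``max_magnitude`` keeps the extreme instance instead).  The permutation
    null scores ``n_perm`` random signatures of identical up/down sizes
    against the same instances and aggregates them identically per drug, so
    each drug's p-value respects its own instance count:
    ``p = (1 + #{|null| >= |observed|}) / (n_perm + 1)``.  FDR is
    Benjamini–Hochberg across drugs.

    Returns a DataFrame indexed 1..n_drugs by rank (most negative score
    first) with columns drug_id, score, p_value, fdr, rank, n_instances,
    instance_scores, approach.
    """
    if not sig.up or not sig.down:
        raise ValueError("score_database needs both signature directions")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution "
                      f"(floor {1 / (n_perm + 1):.3g})", stacklevel=2)
    gene_index = {g: i for i, g in enumerate(db.genes)}
    missing = [g for g in sig.up + sig.down if g not in gene_index]
    if missing:
        raise ValueError(f"signature genes absent from database: {missing[:5]}")
    up_idx = np.array([gene_index[g] for g in sig.up])
    dn_idx = np.array([gene_index[g] for g in sig.down])
    pos = db.ranks.to_numpy(dtype=np.int32)     # genes x instances, ranks
    n_genes = pos.shape[0]

    obs = _score_instances(up_idx, dn_idx, pos)
    inst_ids = list(db.ranks.columns)
    inst_drug = db.instance_meta.set_index("instance_id")["drug_id"]
    drug_of = np.asarray(inst_drug.loc[inst_ids])
    drugs = sorted(set(drug_of))
    cols_of = {d: np.flatnonzero(drug_of == d) for d in drugs}
    agg = _AGGREGATORS[aggregate]
    drug_scores = {d: float(agg(obs[cols])) for d, cols in cols_of.items()}

    # permutation null: random matched-size signatures vs the same instances
    rng = np.random.default_rng(seed)
    t_up, t_dn = len(up_idx), len(dn_idx)
    exceed = {d: 0 for d in drugs}
    for _ in range(n_perm):
        picked = rng.choice(n_genes, size=t_up + t_dn, replace=False)
        null_inst = _score_instances(picked[:t_up], picked[t_up:], pos)
        for d, cols in cols_of.items():
            if abs(float(agg(null_inst[cols]))) >= abs(drug_scores[d]):
                exceed[d] += 1
    pvals = np.array([(1 + exceed[d]) / (n_perm + 1) for d in drugs])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    out = pd.DataFrame({
        "drug_id": drugs,
        "score": [drug_scores[d] for d in drugs],
        "p_value": pvals,
        "fdr": fdr,
        "n_instances": [len(cols_of[d]) for d in drugs],
        "instance_scores": [obs[cols_of[d]].round(6).tolist() for d in drugs],
    })
    out["approach"] = approach or sig.label
    out = out.sort_values(["score", "p_value", "drug_id"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class HitList:
    """FDR-gated, top-K truncated selection within one approach."""

    approach: str
    direction: str                       # negative_tail | positive_tail
    table: pd.DataFrame                  # drug_id, score, p_value, fdr, multiplicity
    fdr_cut: float = 0.05
    k: int = 20
    warnings: list[str] = field(default_factory=list)

    @property
    def drugs(self) -> list[str]:
        return self.table["drug_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def select_hits(results: pd.DataFrame, approach: str | None = None,
                direction: str = "negative_tail", k: int = 20,
                fdr_cut: float = 0.05) -> HitList:
    """Filter FDR < cut, sort by score toward the requested tail, keep top K.

    ``negative_tail`` selects reversers (most negative score ranks first);
    ``positive_tail`` selects mimics.  Ties break by p-value then drug id.
    Multiplicity counts the instances whose score lies in the selected tail
    (matching the convention of reporting how many times a drug "appears").
    """
    if direction not in ("negative_tail", "positive_tail"):
        raise ValueError("direction must be negative_tail or positive_tail")
    approach = approach or (results["approach"].iloc[0] if len(results) else "?")
    hits = results[results["fdr"] < fdr_cut].copy()
    warn: list[str] = []
    if hits.empty:
        warn.append(f"no drugs pass FDR < {fdr_cut} in approach {approach!r}")
    asc = direction == "negative_tail"
    # keep only drugs whose aggregated score lies in the requested tail
    hits = hits[(hits["score"] < 0) if asc else (hits["score"] > 0)]
    hits = hits.sort_values(["score", "p_value", "drug_id"],
                            ascending=[asc, True, True]).head(k)
    if "instance_scores" in hits.columns:
        tail = (lambda xs: sum(x < 0 for x in xs)) if asc else \
               (lambda xs: sum(x > 0 for x in xs))
        mult = [tail(xs) for xs in hits["instance_scores"]]
    else:
        mult = hits.get("n_instances", pd.Series(1, index=hits.index))
    table = hits[["drug_id", "score", "p_value", "fdr"]].copy()
    table["multiplicity"] = list(mult)
    table = table.reset_index(drop=True)
    return HitList(approach, direction, table, fdr_cut, k, warn)


def merge_hits(lists: list[HitList],
               exclusion: list[str] | None = None) -> pd.DataFrame:
    """Union the per-approach hit lists into one table of distinct drugs.

    One row per distinct drug with per-approach membership flags and
    multiplicities, minus drugs on the user-supplied exclusion list (the
    manually curated drop list).  Ordered by best (most extreme) score.
    """
    if not lists or all(len(h) == 0 for h in lists):
        raise ValueError("need at least one nonempty hit list")
    excl = {str(d).upper() for d in (exclusion or [])}
    rows: dict[str, dict] = {}
    for hl in lists:
        for _, r in hl.table.iterrows():
            d = r["drug_id"]
            row = rows.setdefault(d, {"drug_id": d, "best_score": r["score"]})
            row[f"in_{hl.approach}"] = True
            row[f"mult_{hl.approach}"] = int(r["multiplicity"])
            if abs(r["score"]) > abs(row["best_score"]):
                row["best_score"] = r["score"]
    for row in rows.values():           # complete missing approach columns
        for hl in lists:
            row.setdefault(f"in_{hl.approach}", False)
            row.setdefault(f"mult_{hl.approach}", 0)
    merged = pd.DataFrame(rows.values())
    excluded = merged["drug_id"].str.upper().isin(excl)
    merged.attrs["excluded_drugs"] = merged.loc[excluded, "drug_id"].tolist()
    merged = merged[~excluded]
    merged["n_approaches"] = merged[
        [c for c in merged.columns if c.startswith("in_")]].sum(axis=1).astype(int)
    merged = merged.sort_values(
        by="best_score", key=lambda s: -s.abs()).reset_index(drop=True)
    return merged
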
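"""Query gene signatures and the drug rank-profile database.

A *gene signature* is a pair of disjoint, ordered gene sets: genes
up-regulated and genes down-regulated in some contrast (disease vs normal,
fusion-gene silencing, chemo-responder vs non-responder).  A *drug profile
database* holds one rank-transformed expression profile per perturbation
*instance* (one experiment of one drug; a drug may have several instances),
stored as a genes x instances matrix where each column is a permutation of
1..n_genes, rank 1 being the most up-regulated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "DrugProfileDB",
    "OverlapReport",
    "RobustnessReport",
    "overlap_signatures",
    "derive_resistance_signature",
    "robustness_filter",
]


# ---------------------------------------------------------------------------
# Types


@dataclass
class GeneSignature:
    """Directional gene sets querying the drug profile database.

    Parameters
    ----------
    up, down
        Ordered gene identifiers; disjoint, no duplicates within a set.
    weights
        Optional per-gene magnitude (e.g. |fold-change|); informational.
    label
        One of ``disease``, ``sirna``, ``resistance`` (free-form allowed).
    """

    up: list[str]
    down: list[str]
    weights: dict[str, float] | None = None
    label: str = "disease"

    def __post_init__(self) -> None:
        self.up = [str(g).upper() for g in self.up]
        self.down = [str(g).upper() for g in self.down]
        if any(not g for g in self.up + self.down):
            raise ValueError("gene ids must be nonempty strings")
        if len(set(self.up)) != len(self.up) or len(set(self.down)) != len(self.down):
            raise ValueError("duplicate gene ids within a direction")
        clash = set(self.up) & set(self.down)
        if clash:
            raise ValueError(f"genes in both directions: {sorted(clash)}")
        if self.weights is not None:
            self.weights = {str(g).upper(): float(w) for g, w in self.weights.items()}

    @property
    def n_genes(self) -> int:
        return len(self.up) + len(self.down)

    def is_empty(self) -> bool:
        return self.n_genes == 0

    def swapped(self) -> "GeneSignature":
        """Signature with up/down directions exchanged."""
        return GeneSignature(list(self.down), list(self.up), self.weights, self.label)

    # -- TSV round-trip (columns: gene, direction[, weight]) ----------------

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up") for g in self.up] + [(g, "down") for g in self.down]
        df = pd.DataFrame(rows, columns=["gene", "direction"])
        if self.weights is not None:
            df["weight"] = [self.weights.get(g, np.nan) for g in df["gene"]]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "disease") -> "GeneSignature":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        up = df.loc[df["direction"].str.lower() == "up", "gene"].tolist()
        down = df.loc[df["direction"].str.lower() == "down", "gene"].tolist()
        weights = None
        if "weight" in df.columns and df["weight"].notna().any():
            weights = dict(zip(df["gene"], df["weight"].astype(float)))
        return cls(up, down, weights, label)


@dataclass
class DrugProfileDB:
    """Rank profiles per drug instance plus the instance -> drug map.

    ``ranks`` is a genes x instances DataFrame; each column must be a
    permutation of 1..n_genes (rank 1 = most up-regulated).
    ``instance_meta`` maps ``instance_id`` to ``drug_id`` and an
    ``experiment`` tag.
    """

    ranks: pd.DataFrame
    instance_meta: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks.index = self.ranks.index.astype(str).str.upper()
        meta = self.instance_meta
        required = {"instance_id", "drug_id"}
        if not required <= set(meta.columns):
            raise ValueError("instance_meta needs instance_id and drug_id columns")
        if meta["instance_id"].duplicated().any():
            raise ValueError("an instance id maps to more than one drug")
        if set(meta["instance_id"]) != set(self.ranks.columns):
            raise ValueError("instance_meta and rank columns disagree")

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_instances(self) -> int:
        return self.ranks.shape[1]

    @property
    def drugs(self) -> list[str]:
        return sorted(self.instance_meta["drug_id"].unique())

    def instances_of(self, drug_id: str) -> list[str]:
        m = self.instance_meta
        return m.loc[m["drug_id"] == drug_id, "instance_id"].tolist()

    def validate(self) -> None:
        """Check every instance column is a permutation of 1..n_genes."""
        n = self.n_genes
        expected = np.arange(1, n + 1)
        for col in self.ranks.columns:
            if not np.array_equal(np.sort(self.ranks[col].to_numpy()), expected):
                raise ValueError(f"instance {col!r} is not a permutation of 1..{n}")

    def subset_instances(self, instance_ids: list[str]) -> "DrugProfileDB":
        keep = [c for c in self.ranks.columns if c in set(instance_ids)]
        meta = self.instance_meta[self.instance_meta["instance_id"].isin(keep)]
        return DrugProfileDB(self.ranks[keep].copy(), meta.reset_index(drop=True),
                             dict(self.flags))

    # -- TSV round-trip -----------------------------------------------------

    def to_tsv(self, rank_path, meta_path) -> None:
        out = self.ranks.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(rank_path, sep="\t", index=False)
        self.instance_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, rank_path, meta_path) -> "DrugProfileDB":
        ranks = pd.read_csv(rank_path, sep="\t", dtype={"gene": str})
        ranks = ranks.set_index("gene")
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        return cls(ranks, meta)


@dataclass
class OverlapReport:
    """Book-keeping from overlap_signatures."""

    conflicts: list[str]          # opposite direction in the two inputs
    n_up: int
    n_down: int


@dataclass
class RobustnessReport:
    """Per-drug reproducibility assessment from robustness_filter."""

    dropped: pd.DataFrame         # drug_id, median_corr, n_instances
    retained: pd.DataFrame
    singletons: list[str]         # one instance only; kept but unassessable


# ---------------------------------------------------------------------------
# Operations


def overlap_signatures(a: GeneSignature, b: GeneSignature,
                       label: str | None = None) -> tuple[GeneSignature, OverlapReport]:
    """Intersect two signatures direction-wise.

    Genes appearing with opposite directions in the two inputs are dropped
    and listed in the report.  Raises if both directions of the result are
    empty (the query would be undefined).
    """
    if a.is_empty() or b.is_empty():
        raise ValueError("both input signatures must be nonempty")
    a_up, a_dn = set(a.up), set(a.down)
    b_up, b_dn = set(b.up), set(b.down)
    conflicts = sorted((a_up & b_dn) | (a_dn & b_up))
    up = [g for g in a.up if g in b_up and g not in conflicts]
    down = [g for g in a.down if g in b_dn and g not in conflicts]
    if not up and not down:
        raise ValueError(
            "signature overlap is empty in both directions; the intersected "
            "query is undefined — check gene id conventions of the inputs")
    out = GeneSignature(up, down, label=label or a.label)
    return out, OverlapReport(conflicts, len(up), len(down))


def derive_resistance_signature(expr: pd.DataFrame, groups: pd.Series | dict,
                                fdr_cut: float = 0.05, top_n: int = 100,
                                responder_label: str | None = None,
                                label: str = "resistance") -> GeneSignature:
    """Differential signature between responders and non-responders.

    Per-gene Wilcoxon rank-sum (Mann-Whitney; exact null distribution for
    small untied samples, mid-rank normal approximation otherwise),
    Benjamini-Hochberg across genes, direction by sign of
    the median difference (non-responders minus responders: a gene *up* in
    the signature is higher in non-responders).  Restricted to FDR <
    ``fdr_cut`` and truncated to the ``top_n`` largest |median difference|
    per direction.

    ``expr`` is genes x samples; ``groups`` maps sample -> one of exactly
    two labels.  ``responder_label`` names the reference (responder)
    group; when omitted, a label containing "respond" but not "non" is
    taken as the responders, falling back to the lexicographically
    smaller label.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    if responder_label is None:
        guess = [l for l in labels
                 if "respond" in str(l).lower() and "non" not in str(l).lower()]
        responder_label = guess[0] if len(guess) == 1 else labels[0]
    if responder_label not in labels:
        raise ValueError(f"responder label {responder_label!r} not in groups")
    ref = responder_label
    alt = labels[1] if labels[0] == ref else labels[0]
    cols_ref = groups.index[groups == ref]
    cols_alt = groups.index[groups == alt]
    if len(cols_ref) < 3 or len(cols_alt) < 3:
        raise ValueError("need at least 3 samples per group for the rank test")
    x = expr[cols_alt].to_numpy(float)
    y = expr[cols_ref].to_numpy(float)

    # vectorized Mann-Whitney across genes; the exact null is worth real
    # power at screening-cohort sizes but is only valid without ties, in
    # which case the mid-rank normal approximation takes over
    pooled = np.sort(np.hstack([x, y]), axis=1)
    has_ties = bool(np.any(pooled[:, 1:] == pooled[:, :-1]))
    small = max(x.shape[1], y.shape[1]) <= 25
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, axis=1, method=method,
                             alternative="two-sided")
    pvals = np.asarray(res.pvalue)
    effect = np.median(x, axis=1) - np.median(y, axis=1)
    rej, qvals, _, _ = multipletests(pvals, alpha=fdr_cut, method="fdr_bh")

    genes = np.asarray(expr.index.astype(str).str.upper())
    sig = pd.DataFrame({"gene": genes, "q": qvals, "effect": effect})
    sig = sig[rej & (sig["effect"] != 0)]
    up = (sig[sig["effect"] > 0]
          .sort_values(["effect", "gene"], ascending=[False, True], key=_abs_first)
          .head(top_n)["gene"].tolist())
    down = (sig[sig["effect"] < 0]
            .sort_values(["effect", "gene"], ascending=[False, True], key=_abs_first)
            .head(top_n)["gene"].tolist())
    weights = dict(zip(sig["gene"], sig["effect"].abs()))
    return GeneSignature(up, down, {g: weights[g] for g in up + down}, label)


def _abs_first(col):
    return col.abs() if col.dtype.kind == "f" else col


def robustness_filter(db: DrugProfileDB, min_corr: float = 0.3,
                      min_instances: int = 2) -> tuple[DrugProfileDB, RobustnessReport]:
    """Drop drugs whose replicate instances do not agree.

    For drugs with >= ``min_instances`` instances, the median pairwise
    Spearman correlation of their rank columns is computed over the full
    gene universe; all instances of drugs below ``min_corr`` are removed.
    Drugs with a single instance cannot be assessed: they are retained and
    flagged in the report.  Idempotent.
    """
    rows = []
    singletons = []
    keep_instances: list[str] = []
    for drug in db.drugs:
        inst = db.instances_of(drug)
        if len(inst) < min_instances:
            singletons.append(drug)
            keep_instances.extend(inst)
            continue
        # ranks are already 1..n so Spearman = Pearson on the columns
        mat = db.ranks[inst].to_numpy(float)
        corr = np.corrcoef(mat, rowvar=False)
        iu = np.triu_indices(len(inst), 1)
        med = float(np.median(corr[iu]))
        rows.append({"drug_id": drug, "median_corr": med, "n_instances": len(inst)})
        if med >= min_corr:
            keep_instances.extend(inst)
    table = pd.DataFrame(rows, columns=["drug_id", "median_corr", "n_instances"])
    dropped = table[table["median_corr"] < min_corr].reset_index(drop=True)
    retained = table[table["median_corr"] >= min_corr].reset_index(drop=True)
    out = db.subset_instances(keep_instances)
    out.flags["unassessed_singletons"] = list(singletons)
    return out, RobustnessReport(dropped, retained, singletons)
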
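"""Drought-tolerance coefficients, genotype clustering and ranking concordance.

The drought tolerance coefficient (DTC) of a genotype is the ratio of its mean
Fv/Fm under drought stress to its mean under well-watered control; higher DTC
means the genotype loses less photochemical efficiency under drought and is
therefore more tolerant.  Genotypes are ranked by descending DTC and grouped by
Ward hierarchical clustering, once from measured Fv/Fm and once from
model-predicted Fv/Fm; the screen succeeds when the two rankings agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr


def fvfm(Fo: float, Fm: float) -> float:
    """Maximum photochemical quantum yield of PSII, (Fm - Fo)/Fm."""
    if Fm <= 0:
        raise ValueError("Fm must be positive")
    if not 0 <= Fo <= Fm:
        raise ValueError("require 0 <= Fo <= Fm")
    return (Fm - Fo) / Fm


def water_content(fresh: float, dry: float) -> float:
    """Tissue water content in percent, 100 * (fresh - dry) / fresh."""
    if dry <= 0 or fresh <= 0:
        raise ValueError("weights must be positive")
    if dry > fresh:
        raise ValueError("dry weight cannot exceed fresh weight")
    return 100.0 * (fresh - dry) / fresh


def dtc_table(records: pd.DataFrame, stage: str | None = None, value_col: str = "fvfm") -> pd.DataFrame:
    """Per-genotype drought-tolerance coefficients.

    ``records`` is a tidy frame with columns ``genotype_id``, ``treatment``
    (CK/DS), ``stage`` and a value column (default ``fvfm``).  Returns one row
    per genotype with mean Fv/Fm per arm, replicate counts and
    ``dtc = mean_DS / mean_CK``, sorted by genotype id.  Every genotype must
    have at least one record in each arm (after the stage filter).
    """
    df = records
    if stage is not None:
        df = df[df["stage"] == stage]
    if df.empty:
        raise ValueError(f"no records left after stage filter {stage!r}")
    agg = df.groupby(["genotype_id", "treatment"])[value_col].agg(["mean", "count"])
    wide = agg.unstack("treatment")
    missing = [
        int(g)
        for g in wide.index
        if ("mean", "CK") not in wide.columns
        or ("mean", "DS") not in wide.columns
        or pd.isna(wide.loc[g, ("mean", "CK")])
        or pd.isna(wide.loc[g, ("mean", "DS")])
    ]
    if missing:
        raise ValueError(f"genotypes missing a treatment arm: {missing}")
    out = pd.DataFrame(
        {
            "genotype_id": wide.index.astype(int),
            "mean_fvfm_ck": wide[("mean", "CK")].to_numpy(float),
            "mean_fvfm_ds": wide[("mean", "DS")].to_numpy(float),
            "n_ck": wide[("count", "CK")].to_numpy(int),
            "n_ds": wide[("count", "DS")].to_numpy(int),
        }
    )
    out["dtc"] = out["mean_fvfm_ds"] / out["mean_fvfm_ck"]
    return out.sort_values("genotype_id").reset_index(drop=True)


@dataclass
class ClusterResult:
    """Agglomerative clustering of genotype DTC values."""

    linkage_method: str
    merge_tree: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # genotype_id -> cluster label at the chosen cut
    ranking: list[int]  # genotype ids by descending dtc, ties by id


def cluster_dtc(table: pd.DataFrame, k: int = 2, method: str = "ward") -> ClusterResult:
    """Ward (by default) hierarchical clustering of the scalar DTC values.

    Euclidean distance on the one-dimensional DTC; the tree is cut into ``k``
    clusters and genotypes are ranked by descending DTC (ties by genotype id).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 genotypes to cluster")
    dtc = table["dtc"].to_numpy(float)
    Z = hierarchy.linkage(dtc[:, None], method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = sorted(
        range(len(table)), key=lambda i: (-dtc[i], int(table["genotype_id"].iloc[i]))
    )
    ranking = [int(table["genotype_id"].iloc[i]) for i in order]
    return ClusterResult(
        linkage_method=method,
        merge_tree=Z,
        labels=pd.Series(labels, index=table["genotype_id"].to_numpy(int), name="cluster"),
        ranking=ranking,
    )


def dendrogram_newick(result: ClusterResult, table: pd.DataFrame) -> str:
    """Export the merge tree in Newick format (leaf names = genotype ids)."""
    tree = hierarchy.to_tree(result.merge_tree)
    ids = table["genotype_id"].to_numpy(int)

    def _fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:g}"
        return (
            f"({_fmt(node.left, node.dist)},{_fmt(node.right, node.dist)}):{length:g}"
        )

    return f"({_fmt(tree.left, tree.dist)},{_fmt(tree.right, tree.dist)});"


@dataclass
class ConcordanceReport:
    """Agreement between measured- and predicted-DTC genotype rankings."""

    k: int
    topk_measured: list[int]
    topk_predicted: list[int]
    overlap: int
    spearman_rho: float


def rank_and_compare(
    measured: pd.DataFrame, predicted: pd.DataFrame, k: int = 10
) -> ConcordanceReport:
    """Top-k overlap and Spearman rank correlation between two DTC tables.

    Both tables must cover the same genotype set.  Spearman uses average-rank
    tie handling on the DTC values over all genotypes.
    """
    gm = set(measured["genotype_id"].astype(int))
    gp = set(predicted["genotype_id"].astype(int))
    if gm != gp:
        raise ValueError("measured and predicted tables cover different genotype sets")
    m = measured.sort_values("genotype_id").reset_index(drop=True)
    p = predicted.sort_values("genotype_id").reset_index(drop=True)

    def _topk(t):
        order = t.sort_values(["dtc", "genotype_id"], ascending=[False, True])
        return [int(g) for g in order["genotype_id"].head(k)]

    top_m, top_p = _topk(m), _topk(p)
    rho = float(spearmanr(m["dtc"], p["dtc"]).statistic)
    return ConcordanceReport(
        k=k,
        topk_measured=top_m,
        topk_predicted=top_p,
        overlap=len(set(top_m) & set(top_p)),
        spearman_rho=rho,
    )
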
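"""Germ-cell developmental staging from a marker-gene panel.

Cells are median-normalized, clustered hierarchically on Spearman
correlation distance over a panel of marker genes (the study design uses a
72-gene panel spanning pluripotency, early/late germ-cell, meiotic and
somatic programs), and clusters are labelled PGC / LGC / MGC / somatic from
the mean expression of the panel categories. Stage-enriched marker lists are
derived with a tenfold mean-expression rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

STAGES = ("PGC", "LGC", "MGC", "somatic")

CATEGORIES = ("pluripotency", "early germ", "late", "meiotic", "somatic")


@dataclass(frozen=True)
class MarkerPanel:
    """Marker-gene panel with per-gene category tags."""

    data: pd.DataFrame  # columns: gene, category

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("marker panel must be non-empty")
        if self.data["gene"].duplicated().any():
            raise ValueError("panel genes must be unique")
        bad = set(self.data["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown panel categories: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.data["gene"])

    @classmethod
    def from_tsv(cls, path: str) -> "MarkerPanel":
        return cls(pd.read_csv(path, sep="\t", names=["gene", "category"],
                               header=None, comment="#"))


def median_normalize(
    expression_matrix: pd.DataFrame, target_median: float | None = None
) -> pd.DataFrame:
    """Median-normalize a cells x genes expression matrix.

    Each cell's values are divided by that cell's median over its positive
    genes, then rescaled by ``target_median`` (default: the global median of
    the per-cell medians, preserving the original scale).
    """
    values = expression_matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be >= 0")
    medians = np.empty(values.shape[0])
    for i, row in enumerate(values):
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(
                f"cell {expression_matrix.index[i]!r} has no positive genes"
            )
        medians[i] = np.median(pos)
    if target_median is None:
        target_median = float(np.median(medians))
    out = values / medians[:, None] * target_median
    return pd.DataFrame(
        out, index=expression_matrix.index, columns=expression_matrix.columns
    )


def _spearman_distance(cells_by_genes: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Spearman correlation distance between cells."""
    # rank per cell over panel genes, then Pearson on ranks == Spearman
    ranks = cells_by_genes.rank(axis=1).to_numpy(dtype=float)
    corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def cluster_and_stage(
    normalized: pd.DataFrame,
    panel: MarkerPanel,
    k: int = 4,
    linkage_method: str = "average",
) -> pd.DataFrame:
    """Cluster cells over panel genes and assign developmental stages.

    Distance is 1 - Spearman correlation over the panel genes present in the
    matrix (missing panel genes are dropped with a warning); the
    average-linkage tree is cut into ``k`` clusters. Clusters are labelled by
    per-gene z-scored mean expression of the panel categories: highest
    pluripotency + early germ -> PGC, highest meiotic -> MGC, highest
    somatic -> somatic, intermediate -> LGC.

    Returns a DataFrame with columns ``cell_id, stage, cluster_id``.
    """
    if k > len(normalized):
        raise ValueError(f"k={k} exceeds number of cells {len(normalized)}")
    present = [g for g in panel.genes if g in normalized.columns]
    missing = [g for g in panel.genes if g not in normalized.columns]
    if missing:
        warnings.warn(
            f"{len(missing)} panel gene(s) absent from matrix, dropped: "
            + "; ".join(missing)
        )
    if not present:
        raise ValueError("no panel genes present in expression matrix")
    sub = normalized.loc[:, present]

    if k == 1:
        labels = np.ones(len(sub), dtype=int)
    else:
        condensed = _spearman_distance(sub)
        tree = hierarchy.linkage(condensed, method=linkage_method)
        labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")

    categories = panel.data.set_index("gene")["category"].loc[present]
    # z-score genes so category scores are comparable across expression scales
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0).replace(0.0, 1.0)
    cat_scores = z.T.groupby(categories.values).mean().T  # cells x categories
    cat_scores = cat_scores.reindex(columns=CATEGORIES, fill_value=0.0)

    cluster_ids = sorted(set(labels))
    means = pd.DataFrame(
        {
            c: cat_scores.loc[labels == c].mean(axis=0)
            for c in cluster_ids
        }
    ).T  # clusters x categories
    stage_scores = pd.DataFrame(
        {
            "PGC": (means["pluripotency"] + means["early germ"]) / 2.0,
            "LGC": means["late"],
            "MGC": means["meiotic"],
            "somatic": means["somatic"],
        }
    )

    assignment: dict[int, str] = {}
    if len(cluster_ids) == len(STAGES):
        # unique greedy assignment: somatic, then meiotic, then PGC; rest LGC
        remaining = list(cluster_ids)
        for stage in ("somatic", "MGC", "PGC"):
            best = stage_scores.loc[remaining, stage].idxmax()
            assignment[best] = stage
            remaining.remove(best)
        assignment[remaining[0]] = "LGC"
    else:
        for c in cluster_ids:
            assignment[c] = stage_scores.loc[c].idxmax()

    return pd.DataFrame(
        {
            "cell_id": normalized.index,
            "stage": [assignment[c] for c in labels],
            "cluster_id": labels,
        }
    ).reset_index(drop=True)


def tenfold_enriched_genes(
    normalized: pd.DataFrame, groups: pd.Series | dict
) -> dict[str, list[str]]:
    """Genes at least tenfold higher in one group than the rest combined.

    Gene g is enriched in group A iff mean_A(g) >= 10 x mean_notA(g) and
    mean_A(g) > 0 (a silent complement makes any expressed gene enriched).
    """
    groups = pd.Series(groups)
    groups = groups.reindex(normalized.index)
    if groups.isna().any():
        raise ValueError("every cell must be assigned a group")
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    out: dict[str, list[str]] = {}
    for name in names:
        in_g = normalized.loc[groups == name]
        out_g = normalized.loc[groups != name]
        mean_in = in_g.mean(axis=0)
        mean_out = out_g.mean(axis=0)
        enriched = (mean_in > 0) & (mean_in >= 10.0 * mean_out)
        out[name] = list(normalized.columns[enriched])
    return out
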
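"""Imprinted-gene allelic expression and the random-dropout significance model.

For each (cell, imprinted gene) with allelic reads, the expected-allele
ratio is the fraction of reads from the allele predicted to be expressed
under imprinting (1 = fully imprinted, 0.5 = biallelic/erased). Ratios are
aggregated per imprinted gene-cluster, since each cluster is controlled by
one imprinting control region and erases as a unit.

Because single-cell data suffer allelic dropout, observing one allele in a
single cell is uninformative. Under a null where dropout reveals either
allele with probability 1/2 independently per cell, observing the *same
expected* allele in n cells has probability (1/2)^n — monoallelic expression
in 5 or more cells is significant at alpha = 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .counts import AllelicCountMatrix

IMPRINT_CLUSTERS = (
    "H19/IGF2",
    "DLK1-DIO3/MEG3",
    "KCNQ1/KCNQ1OT1",
    "PEG3/ZIM",
    "SNURF-SNRPN/UBE3A",
)


def expected_allele_ratio(
    maternal_reads: int, paternal_reads: int, expected_allele: str
) -> float:
    """Fraction of a gene's allelic reads from the expected imprinted allele."""
    total = maternal_reads + paternal_reads
    if total < 1:
        raise ValueError("expected-allele ratio undefined for zero reads")
    exp = maternal_reads if expected_allele == "maternal" else paternal_reads
    return exp / total


def expected_allele_ratios(
    matrix: AllelicCountMatrix, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-(cell, gene) expected-allele ratios for confirmed imprinted genes.

    ``annotation`` needs columns ``gene, imprint_cluster, expected_allele``
    and optionally ``status``; genes with status other than ``confirmed``
    (e.g. the merely predicted categories) are excluded, as are entries with
    zero allelic reads.
    """
    ann = annotation.copy()
    if "status" in ann.columns:
        ann = ann[ann["status"] == "confirmed"]
    ann = ann[ann["expected_allele"].isin(["maternal", "paternal"])]
    d = matrix.data.merge(
        ann[["gene", "imprint_cluster", "expected_allele"]], on="gene"
    )
    d["total_reads"] = d["maternal_reads"] + d["paternal_reads"]
    d = d[d["total_reads"] >= 1].copy()
    expected = np.where(
        d["expected_allele"] == "maternal",
        d["maternal_reads"],
        d["paternal_reads"],
    )
    d["ratio"] = expected / d["total_reads"]
    return d[
        ["cell_id", "gene", "imprint_cluster", "ratio", "total_reads"]
    ].reset_index(drop=True)


def monoallelic_dropout_test(
    n_cells_same_allele: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """Significance of monoallelic expression under the random-dropout null.

    Null: each cell's observed allele is an independent fair coin, so the
    probability that n cells all show the specific expected allele is
    (1/2)^n. One-sided toward the expected allele; significant iff p < alpha.
    """
    if n_cells_same_allele < 0:
        raise ValueError("cell count must be >= 0")
    p = 0.5 ** n_cells_same_allele
    return p, p < alpha


def min_cells_for_significance(alpha: float = 0.05) -> int:
    """Smallest number of consistently monoallelic cells significant at alpha."""
    n = 0
    while True:
        n += 1
        p, significant = monoallelic_dropout_test(n, alpha)
        if significant:
            return n


def count_monoallelic_cells(
    ratios: pd.DataFrame, min_reads: int = 1
) -> pd.DataFrame:
    """Per-gene count of cells fully monoallelic for the expected allele.

    A cell counts when its expected-allele ratio is exactly 1 with at least
    ``min_reads`` allelic reads.
    """
    mono = ratios[(ratios["ratio"] == 1.0) & (ratios["total_reads"] >= min_reads)]
    out = mono.groupby("gene").size().rename("n_monoallelic_cells")
    return out.reset_index()


def cluster_bias_summary(
    ratios: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    groups: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Summarize expected-allele ratios per imprinted cluster (and cell group).

    Returns median/mean ratio, number of cells and number of reads per
    (cluster, group). Clusters annotated but empty of ratios are omitted
    with a warning.
    """
    d = ratios.copy()
    if groups is not None:
        gmap = pd.Series(groups)
        d["group"] = d["cell_id"].map(gmap)
    else:
        d["group"] = "all"
    if annotation is not None and "imprint_cluster" in annotation.columns:
        annotated = set(annotation["imprint_cluster"].dropna()) - {"none"}
        empty = annotated - set(d["imprint_cluster"].dropna())
        for c in sorted(empty):
            warnings.warn(f"imprinted cluster {c!r} has no allelic ratios")
    out = (
        d.dropna(subset=["imprint_cluster"])
        .groupby(["imprint_cluster", "group"])
        .agg(
            median_ratio=("ratio", "median"),
            mean_ratio=("ratio", "mean"),
            n_cells=("cell_id", "nunique"),
            n_reads=("total_reads", "sum"),
        )
        .reset_index()
    )
    return out


def compare_bias_distributions(
    group_a, group_b, alternative: str = "greater"
) -> float:
    """One-sided Mann-Whitney-Wilcoxon p-value comparing two ratio groups.

    Exact enumeration when both groups have at most 8 observations and no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)
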
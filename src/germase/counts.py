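"""Allele-of-origin read assignment, allelic count matrices and cell QC.

Reads aligned once against each parental reference are assigned a parental
origin by edit distance: only reads mapping uniquely against *both*
references are usable, and among those the strictly smaller edit distance
wins (ties are ambiguous and dropped, not fractionally split). Counts are
kept as raw reads — not TPM — so sampling effects and allelic dropout can be
modelled downstream.

Cell-level QC: a transcriptome-wide filter keeping cells with at least 7500
expressed genes, and an allelic filter removing cells in the lowest quintile
of either the number of allelic reads or the number of SNP-containing genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["cell_id", "gene", "maternal_reads", "paternal_reads"]


@dataclass(frozen=True)
class ReadAlignmentPair:
    """One read's alignments against the two parental references."""

    read_id: str
    gene: str
    unique_maternal: bool
    unique_paternal: bool
    edit_distance_maternal: int
    edit_distance_paternal: int

    def __post_init__(self) -> None:
        if self.edit_distance_maternal < 0 or self.edit_distance_paternal < 0:
            raise ValueError("edit distances must be >= 0")


def assign_read_origin(pair: ReadAlignmentPair) -> str:
    """Assign a read's parental allele of origin.

    Returns ``maternal``, ``paternal``, ``ambiguous`` (equal edit distances)
    or ``unusable`` (not uniquely mapped against both references).
    """
    if not (pair.unique_maternal and pair.unique_paternal):
        return "unusable"
    if pair.edit_distance_maternal < pair.edit_distance_paternal:
        return "maternal"
    if pair.edit_distance_paternal < pair.edit_distance_maternal:
        return "paternal"
    return "ambiguous"


class AllelicCountMatrix:
    """Cell x gene table of (maternal, paternal) read counts.

    Backed by a tidy DataFrame with columns ``cell_id, gene, maternal_reads,
    paternal_reads``. Per-cell totals (number of SNP-containing genes and
    number of allelic reads) are recomputed from the entries.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        missing = set(COUNT_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        data = data.loc[:, COUNT_COLUMNS].reset_index(drop=True)
        if (data["maternal_reads"] < 0).any() or (
            data["paternal_reads"] < 0
        ).any():
            raise ValueError("counts must be >= 0")
        if data.duplicated(["cell_id", "gene"]).any():
            raise ValueError("duplicate (cell_id, gene) entries")
        self.data = data

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cells(self) -> list[str]:
        return sorted(self.data["cell_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def cell_totals(self) -> pd.DataFrame:
        """Per-cell n_snp_genes (genes with >=1 allelic read) and n_allelic_reads."""
        d = self.data.assign(
            total=self.data["maternal_reads"] + self.data["paternal_reads"]
        )
        d = d[d["total"] > 0]
        out = d.groupby("cell_id").agg(
            n_snp_genes=("gene", "nunique"), n_allelic_reads=("total", "sum")
        )
        return out.reset_index()

    def subset_cells(self, cell_ids) -> "AllelicCountMatrix":
        keep = self.data["cell_id"].isin(set(cell_ids))
        return AllelicCountMatrix(self.data.loc[keep])

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "AllelicCountMatrix":
        return cls(pd.read_csv(path, sep="\t"))


def count_alleles(
    pairs: list[ReadAlignmentPair], cell_id: str
) -> pd.DataFrame:
    """Tabulate per-gene parental read counts for one cell.

    Ambiguous and unusable reads are excluded; genes with no assigned reads
    are absent from the output.
    """
    maternal: Counter = Counter()
    paternal: Counter = Counter()
    for pair in pairs:
        origin = assign_read_origin(pair)
        if origin == "maternal":
            maternal[pair.gene] += 1
        elif origin == "paternal":
            paternal[pair.gene] += 1
    genes = sorted(set(maternal) | set(paternal))
    return pd.DataFrame(
        [(cell_id, g, maternal[g], paternal[g]) for g in genes],
        columns=COUNT_COLUMNS,
    )


def filter_cells_expression(
    expression_matrix: pd.DataFrame, min_genes: int = 7500
) -> set[str]:
    """Keep cells expressing at least ``min_genes`` genes (inclusive).

    ``expression_matrix`` is cells x genes with nonnegative values; a gene
    counts as expressed at value > 0.
    """
    if expression_matrix.empty:
        return set()
    if (expression_matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be >= 0")
    n_expressed = (expression_matrix > 0).sum(axis=1)
    return set(expression_matrix.index[n_expressed >= min_genes])


def filter_cells_allelic_quintile(
    matrix: AllelicCountMatrix, quintile: float = 0.2
) -> set[str]:
    """Remove cells in the lowest quintile of allelic reads OR SNP genes.

    A cell is excluded when its number of allelic reads or its number of
    SNP-containing genes lies strictly below the corresponding 20th-percentile
    value (union of exclusions); ties at the threshold are kept, which makes
    the rule deterministic and order-independent.
    """
    totals = matrix.cell_totals()
    if len(totals) < 5:
        raise ValueError("quintile filter needs at least 5 cells")
    reads_cut = np.quantile(totals["n_allelic_reads"], quintile)
    genes_cut = np.quantile(totals["n_snp_genes"], quintile)
    drop = (totals["n_allelic_reads"] < reads_cut) | (
        totals["n_snp_genes"] < genes_cut
    )
    return set(totals.loc[~drop, "cell_id"])
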
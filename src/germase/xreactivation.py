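"""X-reactivation classification against a binned autosomal empirical null.

Female germ cells reactivate their inactive X during development; whether a
given cell's X is still (partly) inactive can be read from its allelic bias.
Per cell and chromosome, maternal and paternal reads of SNP-containing genes
are summed (X excludes known XCI escapees, which stay biallelic on an
inactive X); the scalar compared is the max-allele fraction
``bias = max(M, P) / (M + P)`` in [0.5, 1], so the autosomal null is
one-sided and direction-free, with the parental direction reported
separately as the paternal fraction.

Because allelic bias of a sum depends on its read depth, chromosomes are
binned so each bin carries an equal share of allelic transcripts, and per
bin an empirical interval containing 95% of the autosomal points defines
the biallelic range. A cell's X falling strictly above its bin's upper
bound is significantly biased, i.e. not (fully) reactivated (XiXa); inside
the range it is XaXa-like. A geometric-mean variant (per-gene biases with a
+1 pseudocount, 99% autosomal interval) provides an outlier-robust check,
and a simple median-per-gene-bias classifier reproduces the >=95%
monoallelic-bias rule used for datasets without chromosome-level depth.

``XReactivationModel`` wraps the pipeline statsmodels-style: construct from
a count matrix and gene annotation, ``fit()`` builds the null and returns an
``XReactivationResults`` with calls, intervals and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .counts import AllelicCountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene partition and chromosome summaries


@dataclass(frozen=True)
class EscapeePartition:
    """X-linked genes split into XCI-proper vs escapee sets."""

    proper_genes: frozenset
    escapee_genes: frozenset

    def __post_init__(self) -> None:
        if self.proper_genes & self.escapee_genes:
            raise ValueError("proper and escapee gene sets must be disjoint")


def partition_x_genes(
    annotation: pd.DataFrame,
    escapee_list=None,
    x_chromosome: str = "X",
) -> EscapeePartition:
    """Partition annotated X genes into proper vs escapee.

    Escapees come from ``escapee_list`` or from a boolean ``escapee``
    annotation column; they are excluded from all X-bias computations.
    """
    x_genes = set(
        annotation.loc[
            annotation["chromosome"].astype(str) == x_chromosome, "gene"
        ]
    )
    if escapee_list is not None:
        escapees = x_genes & set(escapee_list)
    elif "escapee" in annotation.columns:
        flagged = annotation.loc[
            annotation["escapee"].fillna(False).astype(bool), "gene"
        ]
        escapees = x_genes & set(flagged)
    else:
        escapees = set()
    return EscapeePartition(
        proper_genes=frozenset(x_genes - escapees),
        escapee_genes=frozenset(escapees),
    )


def chromosome_allelic_sums(
    matrix: AllelicCountMatrix,
    annotation: pd.DataFrame,
    partition: EscapeePartition | None = None,
    x_chromosome: str = "X",
) -> pd.DataFrame:
    """Sum maternal/paternal reads per (cell, chromosome).

    On the X only proper (non-escapee) genes contribute. Chromosomes with
    zero allelic reads in a cell are omitted. Returns columns ``cell_id,
    chromosome, maternal, paternal, total, paternal_fraction, bias,
    n_snp_genes``.
    """
    ann = annotation[["gene", "chromosome"]].copy()
    ann["chromosome"] = ann["chromosome"].astype(str)
    d = matrix.data.merge(ann, on="gene", how="left")
    if d["chromosome"].isna().any():
        missing = sorted(d.loc[d["chromosome"].isna(), "gene"].unique())
        raise ValueError(f"genes without chromosome annotation: {missing[:5]}")
    if partition is not None:
        on_x = d["chromosome"] == x_chromosome
        d = d[~on_x | d["gene"].isin(partition.proper_genes)]
    d = d.assign(total=d["maternal_reads"] + d["paternal_reads"])
    d = d[d["total"] > 0]
    out = (
        d.groupby(["cell_id", "chromosome"])
        .agg(
            maternal=("maternal_reads", "sum"),
            paternal=("paternal_reads", "sum"),
            n_snp_genes=("gene", "nunique"),
        )
        .reset_index()
    )
    out["total"] = out["maternal"] + out["paternal"]
    out = out[out["total"] > 0].copy()
    out["paternal_fraction"] = out["paternal"] / out["total"]
    out["bias"] = np.maximum(out["maternal"], out["paternal"]) / out["total"]
    return out.reset_index(drop=True)


def filter_x_cells(
    summaries: pd.DataFrame,
    min_x_genes: int = 3,
    min_x_reads: int = 33,
    x_chromosome: str = "X",
) -> set[str]:
    """Cells assessable for X state: >= 3 proper X genes and >= 33 X reads.

    Both thresholds are inclusive.
    """
    x = summaries[summaries["chromosome"] == x_chromosome]
    ok = x[(x["n_snp_genes"] >= min_x_genes) & (x["total"] >= min_x_reads)]
    return set(ok["cell_id"])


def assign_active_x(maternal: int, paternal: int) -> str:
    """Presumably active X: the parent with more summed X reads."""
    if maternal + paternal < 1:
        raise ValueError("active X undefined without X reads")
    if maternal > paternal:
        return "maternal"
    if paternal > maternal:
        return "paternal"
    return "tied"


# ---------------------------------------------------------------------------
# equal-transcript binning and empirical intervals


def bin_by_total(totals, n_bins: int) -> np.ndarray:
    """Bin boundaries such that reads are equally distributed per bin.

    ``totals`` are per-(cell, chromosome) allelic read totals; each bin
    should hold as near as possible an equal share of summed reads. Returns
    the upper edge (inclusive) of each bin in total-read units; points with
    a total equal to a boundary fall in the lower bin, so equal totals share
    a bin.
    """
    totals = np.asarray(totals)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values, counts = np.unique(totals, return_counts=True)
    if len(values) < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct totals, got {len(values)}"
        )
    if n_bins == 1:
        return np.array([values[-1]])
    reads = values * counts
    cum = np.cumsum(reads)
    grand = cum[-1]
    edges = []
    start = 0
    for b in range(1, n_bins):
        target = grand * b / n_bins
        # first distinct value at which the cumulative share reaches target
        i = int(np.searchsorted(cum, target, side="left"))
        i = max(i, start)  # never emit an empty bin
        i = min(i, len(values) - (n_bins - b) - 1)
        edges.append(values[i])
        start = i + 1
    edges.append(values[-1])
    return np.asarray(edges)


def locate_bin(total: float, edges: np.ndarray) -> int:
    """Bin index for a total; values beyond the range go to the nearest bin."""
    i = int(np.searchsorted(edges, total, side="left"))
    if i >= len(edges):
        logger.info("total %s above all bins; assigned to last bin", total)
        i = len(edges) - 1
    return i


def autosomal_interval(biases, level: float = 0.95) -> tuple[float, float]:
    """Empirical quantile interval containing ``level`` of autosome biases.

    Uses linear-interpolation quantiles at (1-level)/2 and 1-(1-level)/2.
    """
    biases = np.asarray(biases, dtype=float)
    if biases.size == 0:
        raise ValueError("empty bin: no autosomal points")
    lo = (1.0 - level) / 2.0
    lower, upper = np.quantile(biases, [lo, 1.0 - lo], method="linear")
    return float(lower), float(upper)


@dataclass
class BinnedNull:
    """Per-bin empirical biallelic intervals built from autosomes."""

    edges: np.ndarray  # upper inclusive edge of each bin (total reads)
    intervals: list[tuple[float, float]]
    n_autosome_points: list[int]
    level: float
    statistic: str = "bias"  # scalar the intervals were built on

    def locate(self, total: float) -> int:
        return locate_bin(total, self.edges)

    def to_frame(self) -> pd.DataFrame:
        lowers = [i[0] for i in self.intervals]
        uppers = [i[1] for i in self.intervals]
        return pd.DataFrame(
            {
                "bin_id": range(len(self.edges)),
                "total_upper_edge": self.edges,
                "lower": lowers,
                "upper": uppers,
                "n_autosome_points": self.n_autosome_points,
            }
        )


def build_binned_null(
    summaries: pd.DataFrame,
    n_bins: int = 4,
    level: float = 0.95,
    x_chromosome: str = "X",
    statistic: str = "bias",
    min_points_warn: int = 20,
) -> BinnedNull:
    """Build the binned autosomal null from chromosome summaries.

    Bin boundaries come from all points (equal-transcript rule); the
    per-bin interval uses autosomal points only, so the X never shapes its
    own null.
    """
    autosomes = summaries[summaries["chromosome"] != x_chromosome]
    if autosomes.empty:
        raise ValueError("no autosomal points to build the null from")
    edges = bin_by_total(summaries["total"].to_numpy(), n_bins)
    bins = np.array([locate_bin(t, edges) for t in autosomes["total"]])
    intervals = []
    n_points = []
    stat = autosomes[statistic].to_numpy(dtype=float)
    for b in range(len(edges)):
        vals = stat[bins == b]
        if vals.size == 0:
            raise ValueError(f"bin {b} holds no autosomal points")
        if vals.size < min_points_warn:
            warnings.warn(
                f"bin {b} has only {vals.size} autosomal points; interval "
                "estimate is unstable"
            )
        intervals.append(autosomal_interval(vals, level))
        n_points.append(int(vals.size))
    return BinnedNull(
        edges=edges,
        intervals=intervals,
        n_autosome_points=n_points,
        level=level,
        statistic=statistic,
    )


def classify_x_state(
    summaries: pd.DataFrame,
    null: BinnedNull,
    assessable_cells: set[str] | None = None,
    x_chromosome: str = "X",
    statistic: str = "bias",
) -> pd.DataFrame:
    """Classify each cell's X against the binned autosomal null.

    A cell is ``XiXa_biased`` iff its X statistic lies strictly above its
    bin's upper bound (the bias scalar is >= 0.5 by construction, so only
    the upper tail indicates monoallelic expression); at or below the bound
    it is ``XaXa_range``. Cells outside ``assessable_cells`` (or without X
    reads) are ``unassessable``.
    """
    x = summaries[summaries["chromosome"] == x_chromosome].set_index("cell_id")
    cells = sorted(set(summaries["cell_id"]))
    rows = []
    for cell in cells:
        if cell not in x.index or (
            assessable_cells is not None and cell not in assessable_cells
        ):
            rows.append((cell, "unassessable", -1, np.nan, np.nan, np.nan, None))
            continue
        row = x.loc[cell]
        b = null.locate(row["total"])
        lower, upper = null.intervals[b]
        value = float(row[statistic])
        state = "XiXa_biased" if value > upper else "XaXa_range"
        rows.append(
            (
                cell,
                state,
                b,
                value,
                lower,
                upper,
                assign_active_x(int(row["maternal"]), int(row["paternal"])),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "state",
            "bin_id",
            "x_bias",
            "lower",
            "upper",
            "active_x_parent",
        ],
    )


# ---------------------------------------------------------------------------
# geometric-mean variant


def gene_bias(maternal, paternal, pseudocount: float = 1.0) -> np.ndarray:
    """Per-gene max-allele fraction with a pseudocount on both alleles."""
    m = np.asarray(maternal, dtype=float) + pseudocount
    p = np.asarray(paternal, dtype=float) + pseudocount
    return np.maximum(m, p) / (m + p)


def gm_chromosome_stats(
    matrix: AllelicCountMatrix,
    annotation: pd.DataFrame,
    partition: EscapeePartition | None = None,
    pseudocount: float = 1.0,
    x_chromosome: str = "X",
) -> pd.DataFrame:
    """Geometric mean of per-gene biases per (cell, chromosome).

    The pseudocount (+1 on both alleles) shrinks low-coverage genes toward
    0.5, making the statistic robust to dropout-driven outliers. Returns
    chromosome summaries with an additional ``gm_bias`` column.
    """
    sums = chromosome_allelic_sums(matrix, annotation, partition, x_chromosome)
    ann = annotation[["gene", "chromosome"]].copy()
    ann["chromosome"] = ann["chromosome"].astype(str)
    d = matrix.data.merge(ann, on="gene", how="left")
    if partition is not None:
        on_x = d["chromosome"] == x_chromosome
        d = d[~on_x | d["gene"].isin(partition.proper_genes)]
    d = d[(d["maternal_reads"] + d["paternal_reads"]) > 0].copy()
    d["gene_bias"] = gene_bias(
        d["maternal_reads"], d["paternal_reads"], pseudocount
    )
    gm = (
        d.assign(log_bias=np.log(d["gene_bias"]))
        .groupby(["cell_id", "chromosome"])["log_bias"]
        .mean()
        .pipe(np.exp)
        .rename("gm_bias")
        .reset_index()
    )
    return sums.merge(gm, on=["cell_id", "chromosome"], how="left")


def gm_interval_classify(
    matrix: AllelicCountMatrix,
    annotation: pd.DataFrame,
    partition: EscapeePartition | None = None,
    n_bins: int = 4,
    level: float = 0.99,
    assessable_cells: set[str] | None = None,
    pseudocount: float = 1.0,
    x_chromosome: str = "X",
) -> tuple[pd.DataFrame, BinnedNull]:
    """Classify X state with the geometric-mean statistic at its own level."""
    stats_df = gm_chromosome_stats(
        matrix, annotation, partition, pseudocount, x_chromosome
    )
    null = build_binned_null(
        stats_df, n_bins=n_bins, level=level, x_chromosome=x_chromosome,
        statistic="gm_bias",
    )
    calls = classify_x_state(
        stats_df, null, assessable_cells, x_chromosome, statistic="gm_bias"
    )
    return calls, null


# ---------------------------------------------------------------------------
# summaries, ranking, simple classifiers


def paternal_fraction_summary(
    summaries: pd.DataFrame,
    groups: pd.Series | dict | None = None,
    x_chromosome: str = "X",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell X paternal fraction and per-group quartiles.

    Returns ``(per_cell, quartiles)`` where quartiles are the 25/50/75%
    points of the paternal fraction per cell group.
    """
    x = summaries[summaries["chromosome"] == x_chromosome].copy()
    if groups is not None:
        gmap = pd.Series(groups)
        x["group"] = x["cell_id"].map(gmap).fillna("unknown")
    else:
        x["group"] = "all"
    per_cell = x[["cell_id", "group", "paternal_fraction", "total"]]
    quartiles = (
        per_cell.groupby("group")["paternal_fraction"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "q50", 0.75: "q75"})
        .reset_index()
    )
    return per_cell.reset_index(drop=True), quartiles


def rank_cells_by_x_bias(
    summaries: pd.DataFrame, x_chromosome: str = "X"
) -> pd.DataFrame:
    """Cells ordered by decreasing X bias (reactivation status).

    Ties break by total reads (descending) then cell_id, so the order is
    deterministic.
    """
    x = summaries[summaries["chromosome"] == x_chromosome].copy()
    x = x.sort_values(
        ["bias", "total", "cell_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    x.index.name = "rank"
    return x.reset_index()


def median_bias_classifier(
    per_gene_biases, threshold: float = 0.95
) -> str:
    """XCI call from the median per-gene monoallelic bias of one cell.

    ``XCI`` iff the median over proper X genes of the per-gene max-allele
    fraction is >= threshold (inclusive); no genes -> ``unassessable``.
    """
    biases = np.asarray(per_gene_biases, dtype=float)
    if biases.size == 0:
        return "unassessable"
    return "XCI" if float(np.median(biases)) >= threshold else "not_XCI"


# ---------------------------------------------------------------------------
# negative-binomial differential expression


def _mom_dispersion(y: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled within groups, floored at 0."""
    alphas = []
    for g in np.unique(groups):
        v = y[groups == g]
        if v.size < 2:
            continue
        m = v.mean()
        if m <= 0:
            continue
        s2 = v.var(ddof=1)
        alphas.append((s2 - m) / m**2)
    if not alphas:
        return 0.0
    return max(0.0, float(np.mean(alphas)))


def differential_expression_nb(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene negative-binomial two-group test with BH adjustment.

    ``counts`` is a cells x genes matrix of nonnegative integers. Per gene,
    dispersion is estimated by method of moments within groups (floored at
    Poisson) and a GLM Wald test of equal means is run; all-zero genes are
    skipped. Returns columns ``gene, mean_a, mean_b, log2_fold_change,
    p_value, q_value, significant`` with q from Benjamini-Hochberg across
    tested genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    sub = counts.loc[group_a + group_b]
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    design = sm.add_constant(labels.astype(float))

    rows = []
    for gene in sub.columns:
        y = sub[gene].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        mean_a = y[labels == 0].mean()
        mean_b = y[labels == 1].mean()
        disp = _mom_dispersion(y, labels)
        if disp > 1e-8:
            family = sm.families.NegativeBinomial(alpha=disp)
        else:
            family = sm.families.Poisson()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, design, family=family).fit()
            p = float(fit.pvalues[1])
        except Exception:  # perfect separation / non-convergence
            p = np.nan
        if not np.isfinite(p):
            continue
        log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
        rows.append((gene, mean_a, mean_b, log2fc, p))

    out = pd.DataFrame(
        rows, columns=["gene", "mean_a", "mean_b", "log2_fold_change", "p_value"]
    )
    if out.empty:
        out["q_value"] = []
        out["significant"] = []
        return out
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha_fdr
    return out.sort_values("p_value").reset_index(drop=True)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results


class XReactivationModel:
    """Per-cell X-reactivation classifier against a binned autosomal null.

    Parameters
    ----------
    counts : AllelicCountMatrix or DataFrame
        Tidy per-cell per-gene (maternal, paternal) read counts.
    annotation : DataFrame
        Columns ``gene, chromosome`` and optionally ``escapee``.
    escapee_genes : iterable, optional
        Overrides the annotation's escapee flags.
    n_bins, level : binning/interval settings for the bias-scalar null.
    gm_level : confidence level of the geometric-mean variant.
    min_x_genes, min_x_reads : assessability filters for the X.
    """

    def __init__(
        self,
        counts,
        annotation: pd.DataFrame,
        escapee_genes=None,
        *,
        n_bins: int = 4,
        level: float = 0.95,
        gm_level: float = 0.99,
        min_x_genes: int = 3,
        min_x_reads: int = 33,
        x_chromosome: str = "X",
    ) -> None:
        if not isinstance(counts, AllelicCountMatrix):
            counts = AllelicCountMatrix(counts)
        self.counts = counts
        self.annotation = annotation
        self.n_bins = n_bins
        self.level = level
        self.gm_level = gm_level
        self.min_x_genes = min_x_genes
        self.min_x_reads = min_x_reads
        self.x_chromosome = x_chromosome
        self.partition = partition_x_genes(
            annotation, escapee_genes, x_chromosome
        )

    @classmethod
    def from_files(
        cls, counts_tsv: str, annotation_tsv: str, **kwargs
    ) -> "XReactivationModel":
        counts = AllelicCountMatrix.from_tsv(counts_tsv)
        annotation = pd.read_csv(annotation_tsv, sep="\t")
        return cls(counts, annotation, **kwargs)

    def fit(self, with_gm: bool = True) -> "XReactivationResults":
        summaries = chromosome_allelic_sums(
            self.counts, self.annotation, self.partition, self.x_chromosome
        )
        assessable = filter_x_cells(
            summaries, self.min_x_genes, self.min_x_reads, self.x_chromosome
        )
        null = build_binned_null(
            summaries, self.n_bins, self.level, self.x_chromosome
        )
        calls = classify_x_state(
            summaries, null, assessable, self.x_chromosome
        )
        gm_calls = gm_null = None
        if with_gm:
            gm_calls, gm_null = gm_interval_classify(
                self.counts,
                self.annotation,
                self.partition,
                n_bins=self.n_bins,
                level=self.gm_level,
                assessable_cells=assessable,
                x_chromosome=self.x_chromosome,
            )
        return XReactivationResults(
            model=self,
            summaries=summaries,
            assessable_cells=assessable,
            null=null,
            calls=calls,
            gm_null=gm_null,
            gm_calls=gm_calls,
        )


@dataclass
class XReactivationResults:
    """Fitted X-reactivation calls, their null intervals and diagnostics."""

    model: XReactivationModel
    summaries: pd.DataFrame
    assessable_cells: set[str]
    null: BinnedNull
    calls: pd.DataFrame
    gm_null: BinnedNull | None = None
    gm_calls: pd.DataFrame | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_assessable(self) -> int:
        return len(self.assessable_cells)

    @property
    def n_biased(self) -> int:
        return int((self.calls["state"] == "XiXa_biased").sum())

    @property
    def fraction_biased(self) -> float:
        n = self.n_assessable
        return self.n_biased / n if n else float("nan")

    def paternal_fraction_summary(self, groups=None):
        return paternal_fraction_summary(
            self.summaries, groups, self.model.x_chromosome
        )

    def rank_cells(self) -> pd.DataFrame:
        return rank_cells_by_x_bias(self.summaries, self.model.x_chromosome)

    def differential_expression(
        self, expression_counts: pd.DataFrame
    ) -> pd.DataFrame:
        """NB differential expression between XiXa-biased and XaXa-range cells."""
        biased = list(
            self.calls.loc[self.calls["state"] == "XiXa_biased", "cell_id"]
        )
        in_range = list(
            self.calls.loc[self.calls["state"] == "XaXa_range", "cell_id"]
        )
        biased = [c for c in biased if c in expression_counts.index]
        in_range = [c for c in in_range if c in expression_counts.index]
        return differential_expression_nb(expression_counts, in_range, biased)

    def summary(self) -> str:
        """Human-readable fit summary."""
        states = self.calls["state"].value_counts()
        lines = [
            "X-reactivation classification".center(62),
            "=" * 62,
            f"cells (total / assessable): {self.calls.shape[0]} / "
            f"{self.n_assessable}",
            f"interval level: {self.null.level:.0%} over {len(self.null.edges)}"
            " equal-transcript bins",
            f"X filters: >= {self.model.min_x_genes} proper genes, "
            f">= {self.model.min_x_reads} allelic reads",
            "-" * 62,
        ]
        for state in ("XaXa_range", "XiXa_biased", "unassessable"):
            lines.append(f"{state:<16} {int(states.get(state, 0)):>5}")
        if self.n_assessable:
            lines.append(
                f"fraction significantly biased (XiXa): "
                f"{self.fraction_biased:.1%}"
            )
        directions = self.calls.loc[
            self.calls["state"] == "XiXa_biased", "active_x_parent"
        ].value_counts()
        if len(directions):
            lines.append(
                "biased-call direction: "
                + ", ".join(f"{k}={v}" for k, v in directions.items())
            )
        lines.append("-" * 62)
        lines.append("per-bin autosomal intervals:")
        lines.append(self.null.to_frame().to_string(index=False))
        if self.gm_calls is not None:
            gm_states = self.gm_calls["state"].value_counts()
            lines.append("-" * 62)
            lines.append(
                f"GM variant ({self.gm_null.level:.0%}): "
                f"biased={int(gm_states.get('XiXa_biased', 0))}, "
                f"in-range={int(gm_states.get('XaXa_range', 0))}"
            )
        return "\n".join(lines)

    def plot_bias(self, ax=None):
        """Scatter of per-chromosome bias vs total reads with the null bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        xc = self.model.x_chromosome
        autos = self.summaries[self.summaries["chromosome"] != xc]
        x = self.summaries[self.summaries["chromosome"] == xc]
        ax.scatter(
            autos["total"], autos["bias"], s=8, c="black", alpha=0.3,
            label="autosomes",
        )
        biased_cells = set(
            self.calls.loc[self.calls["state"] == "XiXa_biased", "cell_id"]
        )
        is_biased = x["cell_id"].isin(biased_cells)
        ax.scatter(
            x.loc[~is_biased, "total"], x.loc[~is_biased, "bias"],
            s=20, c="tab:red", label="X (in range)",
        )
        ax.scatter(
            x.loc[is_biased, "total"], x.loc[is_biased, "bias"],
            s=30, facecolors="none", edgecolors="orange", label="X (biased)",
        )
        prev = 0.0
        for edge, (lo, hi) in zip(self.null.edges, self.null.intervals):
            ax.fill_between([prev, edge], [lo, lo], [hi, hi],
                            color="gold", alpha=0.25)
            ax.axvline(edge, color="gray", lw=0.5)
            prev = edge
        ax.set_xscale("log")
        ax.set_xlabel("allelic reads per chromosome")
        ax.set_ylabel("allelic bias (max-allele fraction)")
        ax.legend(frameon=False, fontsize=8)
        return ax
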
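"""Synthetic trio, allelic-count and methylation data with ground truth.

The generators emulate the statistical structure of trio-phased single-cell
allele-specific expression data:

* trio genotypes where informative sites (fetus heterozygous, mother
  homozygous) determine the parental origin of each fetal allele;
* per-cell, per-gene (maternal, paternal) read counts with biallelic binomial
  sampling on autosomes, per-cell X-inactivation state with random parental
  choice of the active X, per-cluster imprint erasure, gene-level allelic
  dropout, and heavy-tailed (negative-binomial) depth variation;
* read-level CpG methylation call tables with per-allele methylation rates.

Every simulated object ships with its truth labels so downstream operations
can be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = np.array(["A", "C", "G", "T"])

#: chromosome lengths (bp, GRCh37 scale) used by default for SNP placement
DEFAULT_CHROMOSOME_LENGTHS: dict[str, int] = {
    **{str(i): int(2.5e8 - i * 8e6) for i in range(1, 23)},
    "X": 155_270_560,
}


@dataclass(frozen=True)
class TrioSimConfig:
    """Parameters for simulating fetal/maternal variant tables.

    ``het_rate_fetus`` is the fraction of simulated sites heterozygous in the
    fetus; ``maternal_hom_rate`` the fraction homozygous in the mother. The
    defaults give an informative-site yield comparable to exome trios (on the
    order of half the fetal-het sites usable). ``indel_rate`` / ``lowq_rate``
    inject non-SNP and non-PASS records so that filter behaviour is testable;
    ``missing_in_mother_rate`` drops sites from the maternal table.
    """

    n_snps: int
    het_rate_fetus: float = 0.15
    maternal_hom_rate: float = 0.7
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS)
    )
    seed: int = 0
    indel_rate: float = 0.02
    lowq_rate: float = 0.02
    missing_in_mother_rate: float = 0.02
    genotype_error_rate: float = 0.002

    def __post_init__(self) -> None:
        for name in (
            "het_rate_fetus",
            "maternal_hom_rate",
            "indel_rate",
            "lowq_rate",
            "missing_in_mother_rate",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


@dataclass(frozen=True)
class CellSimProfile:
    """Ground-truth profile of one simulated cell.

    ``x_bias`` is the probability that an X-proper read in an XiXa cell comes
    from the active X; the default 0.98 leaves a 2% residual leak from the
    inactive allele, emulating incomplete or ongoing reactivation rather than
    a degenerate fully-monoallelic X.
    """

    cell_id: str
    stage_truth: str  # one of PGC, LGC, MGC, somatic
    x_state_truth: str  # XaXa or XiXa
    active_x_parent_truth: str  # maternal or paternal
    depth: float
    dropout_rate: float
    x_bias: float = 0.98

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if not 0.0 <= self.x_bias <= 1.0:
            raise ValueError("x_bias must be in [0, 1]")
        if self.stage_truth not in {"PGC", "LGC", "MGC", "somatic"}:
            raise ValueError(f"unknown stage {self.stage_truth!r}")
        if self.x_state_truth not in {"XaXa", "XiXa"}:
            raise ValueError(f"unknown X state {self.x_state_truth!r}")
        if self.active_x_parent_truth not in {"maternal", "paternal"}:
            raise ValueError(
                f"unknown active X parent {self.active_x_parent_truth!r}"
            )


@dataclass(frozen=True)
class ImprintSimState:
    """Erasure state of one imprinted gene-cluster.

    ``erasure_fraction`` is the probability that a germ cell has erased the
    cluster's imprint and expresses the normally silenced allele biallelically.
    """

    cluster_id: str
    erasure_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.erasure_fraction <= 1.0:
            raise ValueError("erasure_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth companion to a simulated allelic count matrix."""

    cells: pd.DataFrame  # cell_id, stage, x_state, active_x_parent
    erasure: pd.DataFrame  # cell_id, cluster_id, erased
    dropout: pd.DataFrame  # cell_id, gene, dropout, retained_allele


def simulate_trio(
    config: TrioSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate fetal and maternal variant tables with known phase.

    Returns ``(fetal, maternal, truth_phase)``. The variant tables carry
    columns ``chromosome, position, ref, alt, gt, filter``; ``truth_phase``
    records, for every informative site (fetal het x maternal hom, both PASS
    SNPs), which allele is paternal.
    """
    if config.n_snps == 0:
        raise ValueError("n_snps must be > 0: cannot simulate an empty trio")
    rng = np.random.default_rng(config.seed)

    chroms = np.array(list(config.chromosome_lengths))
    lengths = np.array(
        [config.chromosome_lengths[c] for c in chroms], dtype=float
    )
    weights = lengths / lengths.sum()

    # rejection-sample unique (chromosome, position) pairs
    records: dict[tuple[str, int], None] = {}
    while len(records) < config.n_snps:
        need = config.n_snps - len(records)
        ci = rng.choice(len(chroms), size=need, p=weights)
        pos = (rng.random(need) * lengths[ci]).astype(np.int64) + 1
        for c, p in zip(chroms[ci], pos):
            records.setdefault((str(c), int(p)), None)
    sites = sorted(records, key=lambda cp: (cp[0], cp[1]))
    n = len(sites)

    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_i]
    alt = _BASES[alt_i].astype(object)
    is_indel = rng.random(n) < config.indel_rate
    # indels modelled as single-base insertions in ALT
    ins = _BASES[rng.integers(0, 4, size=n)]
    alt[is_indel] = alt[is_indel] + ins[is_indel]

    mat_hom = rng.random(n) < config.maternal_hom_rate
    mat_hom_alt = rng.random(n) < 0.5
    mat_gt = np.where(mat_hom, np.where(mat_hom_alt, "1/1", "0/0"), "0/1")
    mat_filter = np.where(rng.random(n) < config.lowq_rate, "LowQual", "PASS")
    mat_present = rng.random(n) >= config.missing_in_mother_rate

    # fetal hom genotypes follow Mendelian transmission of a maternal allele;
    # a small genotype-error rate injects contradictory calls
    fet_het = rng.random(n) < config.het_rate_fetus
    fet_coin = rng.random(n) < 0.5
    fet_hom_alt = np.where(mat_hom, mat_hom_alt, fet_coin)
    gt_error = rng.random(n) < config.genotype_error_rate
    fet_hom_alt = np.where(gt_error, ~fet_hom_alt.astype(bool), fet_hom_alt)
    fet_gt = np.where(fet_het, "0/1", np.where(fet_hom_alt, "1/1", "0/0"))
    fet_filter = np.where(rng.random(n) < config.lowq_rate, "LowQual", "PASS")

    base = pd.DataFrame(
        {
            "chromosome": [c for c, _ in sites],
            "position": [p for _, p in sites],
            "ref": ref,
            "alt": alt,
        }
    )
    fetal = base.assign(gt=fet_gt, filter=fet_filter)
    maternal = base.assign(gt=mat_gt, filter=mat_filter).loc[mat_present]
    maternal = maternal.reset_index(drop=True)

    informative = (
        fet_het
        & (fet_filter == "PASS")
        & ~is_indel
        & mat_present
        & mat_hom
        & (mat_filter == "PASS")
    )
    tp = base.loc[informative].copy()
    hom_alt = mat_hom_alt[informative]
    # mother 0/0 -> maternal allele is REF, paternal is ALT; mother 1/1 flips
    tp["paternal_allele"] = np.where(hom_alt, tp["ref"], tp["alt"])
    tp["maternal_allele"] = np.where(hom_alt, tp["alt"], tp["ref"])
    tp["informative_class"] = np.where(
        hom_alt, "mother_hom_alt", "mother_hom_ref"
    )
    truth_phase = tp.reset_index(drop=True)
    return fetal, maternal, truth_phase


def _maternal_prob(
    profile: CellSimProfile,
    chromosome: str,
    escapee: bool,
    cluster: str | None,
    expected_allele: str | None,
    erased: bool,
) -> float:
    """Probability that a read from this gene is maternal."""
    if chromosome == "X" and not escapee:
        if profile.x_state_truth == "XiXa":
            b = profile.x_bias
            return b if profile.active_x_parent_truth == "maternal" else 1 - b
        return 0.5
    if cluster is not None and not erased:
        return 1.0 if expected_allele == "maternal" else 0.0
    return 0.5


def simulate_allelic_counts(
    profiles: list[CellSimProfile],
    annotation: pd.DataFrame,
    imprint_states: list[ImprintSimState] | None = None,
    seed: int = 0,
    *,
    nb_dispersion: float = 1.0,
) -> tuple["AllelicCountMatrix", SimTruth]:
    """Simulate a per-cell per-gene allelic count matrix with ground truth.

    ``annotation`` needs columns ``gene`` and ``chromosome``; optional
    ``escapee`` (bool), ``imprint_cluster`` and ``expected_allele``. Gene
    totals are negative-binomial (dispersion ``nb_dispersion``, mean
    ``depth / n_genes`` per gene) to reproduce sparse, overdispersed
    single-cell counts; maternal counts are binomial at the gene's underlying
    maternal probability; dropout reassigns all of a gene's reads to one
    allele (chosen at that probability), so maternal + paternal always equals
    the drawn gene total.
    """
    from .counts import AllelicCountMatrix

    ann = annotation.set_index("gene")
    if ann.index.has_duplicates:
        raise ValueError("duplicate genes in annotation")
    known = set(DEFAULT_CHROMOSOME_LENGTHS) | {"Y", "MT", "M"}
    unknown = set(ann["chromosome"].astype(str)) - known
    if unknown:
        raise ValueError(f"unknown chromosome(s) in annotation: {sorted(unknown)}")

    escapee = (
        ann["escapee"].fillna(False).astype(bool)
        if "escapee" in ann
        else pd.Series(False, index=ann.index)
    )
    cluster = (
        ann["imprint_cluster"]
        if "imprint_cluster" in ann
        else pd.Series(None, index=ann.index, dtype=object)
    )
    cluster = cluster.where(cluster.notna() & (cluster != "none"), None)
    expected = (
        ann["expected_allele"]
        if "expected_allele" in ann
        else pd.Series(None, index=ann.index, dtype=object)
    )
    erasure_fraction = {
        s.cluster_id: s.erasure_fraction for s in (imprint_states or [])
    }

    rng = np.random.default_rng(seed)
    genes = ann.index.to_numpy()
    n_genes = len(genes)
    chrom_arr = ann["chromosome"].astype(str).to_numpy()
    escapee_arr = escapee.to_numpy()
    cluster_arr = cluster.to_numpy(dtype=object)
    expected_arr = expected.to_numpy(dtype=object)
    rows = []
    erasure_rows = []
    dropout_rows = []
    for prof in profiles:
        # per-(cell, cluster) erasure events
        erased: dict[str, bool] = {}
        for cid, frac in erasure_fraction.items():
            hit = bool(rng.random() < frac) and prof.stage_truth != "somatic"
            erased[cid] = hit
            erasure_rows.append((prof.cell_id, cid, hit))
        mean = prof.depth / n_genes
        r = nb_dispersion
        totals = rng.negative_binomial(r, r / (r + mean), size=n_genes)
        drop = rng.random(n_genes) < prof.dropout_rate
        for gi, (g, total, d) in enumerate(zip(genes, totals, drop)):
            if total == 0:
                continue
            clu = cluster_arr[gi]
            p_m = _maternal_prob(
                prof,
                chrom_arr[gi],
                bool(escapee_arr[gi]),
                clu,
                expected_arr[gi],
                erased.get(clu, False) if clu else False,
            )
            if d:
                retained = "maternal" if rng.random() < p_m else "paternal"
                m = total if retained == "maternal" else 0
                dropout_rows.append((prof.cell_id, g, True, retained))
            else:
                m = rng.binomial(total, p_m)
            rows.append((prof.cell_id, g, int(m), int(total - m)))

    data = pd.DataFrame(
        rows, columns=["cell_id", "gene", "maternal_reads", "paternal_reads"]
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            [
                (
                    p.cell_id,
                    p.stage_truth,
                    p.x_state_truth,
                    p.active_x_parent_truth,
                )
                for p in profiles
            ],
            columns=["cell_id", "stage", "x_state", "active_x_parent"],
        ),
        erasure=pd.DataFrame(
            erasure_rows, columns=["cell_id", "cluster_id", "erased"]
        ),
        dropout=pd.DataFrame(
            dropout_rows,
            columns=["cell_id", "gene", "dropout", "retained_allele"],
        ),
    )
    return AllelicCountMatrix(data), truth


def simulate_biallelic_counts(
    n_cells: int,
    n_autosomes: int = 22,
    genes_per_chromosome: int = 6,
    chrom_total_mean: float = 200.0,
    dispersion: float = 1.0,
    seed: int = 0,
) -> tuple["AllelicCountMatrix", pd.DataFrame]:
    """Fully biallelic autosomal counts for empirical-null calibration.

    Per (cell, chromosome) a total is drawn from a negative binomial (mean
    ``chrom_total_mean``, dispersion ``dispersion``), split uniformly
    (multinomial) over the chromosome's genes, and each gene's maternal count
    is Binomial(total, 0.5). Chromosome sums therefore follow the same
    negative-binomial/binomial law exactly. Returns the count matrix and its
    gene annotation.
    """
    from .counts import AllelicCountMatrix

    rng = np.random.default_rng(seed)
    r = dispersion
    p_nb = r / (r + chrom_total_mean)
    genes = [
        (f"g{c}_{j}", str(c))
        for c in range(1, n_autosomes + 1)
        for j in range(genes_per_chromosome)
    ]
    annotation = pd.DataFrame(genes, columns=["gene", "chromosome"])
    share = np.full(genes_per_chromosome, 1.0 / genes_per_chromosome)

    rows = []
    for i in range(n_cells):
        cell = f"cell{i}"
        for c in range(1, n_autosomes + 1):
            total = rng.negative_binomial(r, p_nb)
            if total == 0:
                continue
            per_gene = rng.multinomial(total, share)
            for j, t in enumerate(per_gene):
                if t == 0:
                    continue
                m = rng.binomial(t, 0.5)
                rows.append((cell, f"g{c}_{j}", int(m), int(t - m)))
    data = pd.DataFrame(
        rows, columns=["cell_id", "gene", "maternal_reads", "paternal_reads"]
    )
    return AllelicCountMatrix(data), annotation


def simulate_methylation_reads(
    cpg_positions: list[int],
    per_allele_rate: dict[str, float],
    n_reads: int | dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate read-level CpG methylation calls for one region.

    Each read carries an allele tag and independent per-CpG 0/1 calls drawn
    at the allele's methylation rate. Returns a long table with columns
    ``read_id, allele, cpg_index, position, call``.
    """
    if len(cpg_positions) < 1:
        raise ValueError("region must contain at least one CpG position")
    for a, rate in per_allele_rate.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for allele {a!r} must be in [0, 1]")
    if isinstance(n_reads, int):
        n_reads = {a: n_reads for a in per_allele_rate}
    if any(n < 0 for n in n_reads.values()):
        raise ValueError("n_reads must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    read_no = 0
    for allele in sorted(per_allele_rate):
        rate = per_allele_rate[allele]
        for _ in range(n_reads.get(allele, 0)):
            read_id = f"read{read_no}"
            read_no += 1
            calls = rng.random(len(cpg_positions)) < rate
            for idx, (pos, call) in enumerate(zip(cpg_positions, calls)):
                rows.append((read_id, allele, idx, pos, int(call)))
    return pd.DataFrame(
        rows, columns=["read_id", "allele", "cpg_index", "position", "call"]
    )


# archetype expression per (stage, panel category): geometrically graded so
# every stage has a distinct category ordering (stable under rank-based
# clustering, no flat stretches whose ranks would be noise-driven)
_STAGE_ARCHETYPES = {
    "PGC": {"pluripotency": 64.0, "early germ": 32.0, "late": 8.0,
            "meiotic": 2.0, "somatic": 4.0},
    "LGC": {"pluripotency": 4.0, "early germ": 8.0, "late": 64.0,
            "meiotic": 16.0, "somatic": 2.0},
    "MGC": {"pluripotency": 2.0, "early germ": 4.0, "late": 16.0,
            "meiotic": 64.0, "somatic": 8.0},
    "somatic": {"pluripotency": 8.0, "early germ": 2.0, "late": 4.0,
                "meiotic": 16.0, "somatic": 64.0},
}


def simulate_stage_expression(
    n_cells_per_stage: dict[str, int],
    panel: "MarkerPanel | pd.DataFrame",
    seed: int = 0,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate marker-panel expression for cells at known stages.

    Cells are drawn around stage archetypes with lognormal noise
    (``noise_sd`` on the log scale). Returns (cells x genes expression
    matrix, per-cell truth stage).
    """
    from .staging import MarkerPanel

    if isinstance(panel, MarkerPanel):
        panel_df = panel.data
    else:
        panel_df = panel
    rng = np.random.default_rng(seed)
    n_genes = len(panel_df)
    # fixed per-gene factors shared by all cells: within-category ranks are
    # then reproducible across cells instead of pure noise
    gene_factors = rng.lognormal(0.0, 0.2, size=n_genes)
    rows = {}
    truth = {}
    for stage, n in n_cells_per_stage.items():
        arch = _STAGE_ARCHETYPES[stage]
        base = np.array(
            [arch.get(cat, 1.0) for cat in panel_df["category"]], dtype=float
        ) * gene_factors
        for i in range(n):
            cid = f"{stage}_{i}"
            rows[cid] = base * rng.lognormal(0.0, noise_sd, size=base.size)
            truth[cid] = stage
    expr = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(panel_df["gene"])
    )
    return expr, pd.Series(truth, name="stage")


def profiles_frame(profiles: list[CellSimProfile]) -> pd.DataFrame:
    """Tabular view of a list of cell profiles."""
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])
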
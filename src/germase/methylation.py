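"""CpG methylation summaries over imprinting-control-region windows.

Input is a post-extraction call table (one row per read per CpG with a 0/1
methylation state), e.g. from a bisulfite aligner's methylation extractor.
Operations: average methylation rate over a genomic window (1-based
inclusive coordinates, matching printed hg19 ICR coordinates), per-read
methylation-pattern counting, and splitting reads by the allele observed at
a SNP (alleles below a 5% frequency threshold pooled as "other") for
allele-specific methylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicWindow:
    """A named 1-based inclusive genomic interval."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window {self.name}: start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position) -> np.ndarray:
        position = np.asarray(position)
        return (position >= self.start) & (position <= self.end)


#: ICR and control-promoter windows (hg19, 1-based inclusive)
ICR_WINDOWS: dict[str, GenomicWindow] = {
    w.name: w
    for w in [
        GenomicWindow("H19/IGF2", "chr11", 2_021_070, 2_021_302),
        GenomicWindow("KCNQ1/KCNQ1OT1", "chr11", 2_721_173, 2_721_297),
        GenomicWindow("DLK1-DIO3/MEG3", "chr14", 101_292_152, 101_292_376),
        GenomicWindow("SNURF-SNRPN/UBE3A", "chr15", 25_200_010, 25_200_249),
        GenomicWindow("PEG3", "chr19", 57_351_942, 57_352_097),
        GenomicWindow("DDX4-promoter", "chr5", 55_029_104, 55_029_220),
        GenomicWindow("DPPA5-promoter", "chr6", 74_063_525, 74_063_669),
    ]
}


@dataclass
class MethylationSummary:
    """Average CpG methylation over one window."""

    window: str
    n_cpg_calls: int
    mean_rate: float  # NaN when no calls fall in the window
    sd: float  # dispersion across sample groups; NaN without grouping
    per_allele_rates: dict[str, float] | None = None


def read_windows_tsv(path: str) -> list[GenomicWindow]:
    """Read windows from a BED-like TSV (name, chromosome, start, end).

    Files ending in ``.bed`` are interpreted as standard 0-based half-open
    BED (columns chromosome, start, end, name) and converted to the 1-based
    inclusive convention used internally.
    """
    if str(path).endswith(".bed"):
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chromosome", "start", "end", "name"], comment="#",
        )
        return [
            GenomicWindow(r.name, r.chromosome, int(r.start) + 1, int(r.end))
            for r in df.itertuples(index=False)
        ]
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["name", "chromosome", "start", "end"], comment="#",
    )
    return [
        GenomicWindow(r.name, r.chromosome, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def region_methylation_rate(
    calls: pd.DataFrame,
    window: GenomicWindow,
    group_column: str | None = None,
) -> MethylationSummary:
    """Average methylation rate of CpG calls inside a window.

    ``calls`` needs columns ``position`` and ``call`` (0/1); rows outside
    the window (1-based inclusive) are ignored. With ``group_column`` the
    standard deviation of per-group rates is reported; per-allele rates are
    added when an ``allele`` column is present.
    """
    if "chromosome" in calls.columns:
        calls = calls[calls["chromosome"].astype(str) == window.chromosome]
    inside = calls[window.contains(calls["position"].to_numpy())]
    n = len(inside)
    if n == 0:
        return MethylationSummary(window.name, 0, float("nan"), float("nan"))
    mean_rate = float(inside["call"].mean())
    sd = float("nan")
    if group_column is not None and group_column in inside.columns:
        per_group = inside.groupby(group_column)["call"].mean()
        sd = float(per_group.std(ddof=1)) if len(per_group) > 1 else 0.0
    per_allele = None
    if "allele" in inside.columns:
        per_allele = inside.groupby("allele")["call"].mean().to_dict()
    return MethylationSummary(window.name, n, mean_rate, sd, per_allele)


def pattern_counts(
    reads: pd.DataFrame, missing_symbol: str = "."
) -> dict[str, int]:
    """Count reads per distinct methylation pattern.

    ``reads`` is a long table with columns ``read_id``, ``call`` and a CpG
    coordinate column (``cpg_index`` or ``position``). The pattern string
    lists each read's 0/1 calls over the window's CpG sites in coordinate
    order; sites a read does not cover keep a placeholder so that pattern
    counting is total. Counts sum to the number of reads.
    """
    if reads.empty:
        return {}
    coord = "cpg_index" if "cpg_index" in reads.columns else "position"
    wide = reads.pivot_table(
        index="read_id", columns=coord, values="call", aggfunc="first"
    ).sort_index(axis=1)
    patterns = wide.apply(
        lambda row: "".join(
            missing_symbol if pd.isna(v) else str(int(v)) for v in row
        ),
        axis=1,
    )
    return patterns.value_counts().to_dict()


def split_by_snp_allele(
    reads: pd.DataFrame,
    snp_position: int | None = None,
    min_allele_freq: float = 0.05,
) -> dict[str, set]:
    """Split reads into per-allele subsets at a covering SNP.

    The allele of each read is taken from an ``allele`` column, or from
    ``base`` at rows with ``position == snp_position`` when a long per-base
    table is given. Alleles with frequency strictly above
    ``min_allele_freq`` get their own subset; rarer ones are pooled under
    ``"other"``. Subsets are disjoint and cover every read with an observed
    allele.
    """
    if snp_position is not None and "base" in reads.columns:
        at_snp = reads[reads["position"] == snp_position]
        allele_of = at_snp.drop_duplicates("read_id").set_index("read_id")["base"]
    elif "allele" in reads.columns:
        allele_of = reads.drop_duplicates("read_id").set_index("read_id")["allele"]
    else:
        raise ValueError("need an 'allele' column or a 'base'/'position' table")
    if allele_of.empty:
        warnings.warn("no read covers the SNP; empty split")
        return {}
    freqs = allele_of.value_counts(normalize=True)
    major = set(freqs.index[freqs > min_allele_freq])
    out: dict[str, set] = {}
    for read_id, allele in allele_of.items():
        key = allele if allele in major else "other"
        out.setdefault(key, set()).add(read_id)
    return out
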
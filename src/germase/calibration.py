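"""Held-out calibration of the binned autosomal empirical nulls.

Simulates fully biallelic autosomal data, builds the binned interval on one
half and measures the fraction of the other half's autosome points falling
inside their bin's interval. For a well-calibrated empirical null that
fraction matches the interval's confidence level.
"""

from __future__ import annotations

import numpy as np

from .synthetic import simulate_biallelic_counts
from .xreactivation import (
    BinnedNull,
    build_binned_null,
    chromosome_allelic_sums,
    gm_chromosome_stats,
)


def coverage_of(null: BinnedNull, summaries, statistic: str = "bias") -> float:
    """Fraction of points whose statistic falls inside its bin's interval."""
    inside = 0
    values = summaries[[statistic, "total"]].dropna()
    for stat, total in values.itertuples(index=False):
        lo, hi = null.intervals[null.locate(total)]
        inside += lo <= stat <= hi
    return inside / len(values)


def held_out_null_coverage(
    n_cells: int = 400,
    n_bins: int = 4,
    level: float = 0.95,
    gm_level: float = 0.99,
    chrom_total_mean: float = 200.0,
    dispersion: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Split-half calibration of the bias-scalar and GM nulls.

    Returns held-out coverage fractions (keys ``bias`` and ``gm``) together
    with the number of held-out points per statistic.
    """
    matrix, annotation = simulate_biallelic_counts(
        n_cells,
        chrom_total_mean=chrom_total_mean,
        dispersion=dispersion,
        seed=seed,
    )
    half = [f"cell{i}" for i in range(n_cells // 2)]
    train = matrix.subset_cells(half)
    test = matrix.subset_cells(
        set(matrix.data["cell_id"].unique()) - set(half)
    )

    sums_train = chromosome_allelic_sums(train, annotation)
    sums_test = chromosome_allelic_sums(test, annotation)
    null = build_binned_null(sums_train, n_bins=n_bins, level=level)

    gm_train = gm_chromosome_stats(train, annotation)
    gm_test = gm_chromosome_stats(test, annotation)
    gm_null = build_binned_null(
        gm_train, n_bins=n_bins, level=gm_level, statistic="gm_bias"
    )

    return {
        "bias": coverage_of(null, sums_test),
        "gm": coverage_of(gm_null, gm_test, statistic="gm_bias"),
        "n_bias": len(sums_test),
        "n_gm": len(gm_test),
    }
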
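"""Minimal VCF reading/writing for single-sample variant tables.

Variant tables are plain DataFrames with columns
``chromosome, position, ref, alt, gt, filter`` (positions 1-based, genotypes
as unphased strings like ``0/1``). Reading uses cyvcf2; multi-allelic records
keep their full ALT list joined with commas so downstream selection can
discard them.
"""

from __future__ import annotations

import pandas as pd

VARIANT_COLUMNS = ["chromosome", "position", "ref", "alt", "gt", "filter"]

_GT_CODE = {0: "0", 1: "1", -1: "."}


def read_vcf(path: str) -> pd.DataFrame:
    """Read a single-sample VCF into a variant table."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for v in vcf:
        gts = v.genotypes[0]  # [a0, a1, phased]
        gt = f"{_GT_CODE.get(gts[0], str(gts[0]))}/{_GT_CODE.get(gts[1], str(gts[1]))}"
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                ",".join(v.ALT) if v.ALT else ".",
                gt,
                v.FILTER or "PASS",  # cyvcf2 reports PASS as None
            )
        )
    vcf.close()
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_vcf(variants: pd.DataFrame, path: str, sample: str = "SAMPLE") -> None:
    """Write a variant table as minimal VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.position}\t.\t{row.ref}\t{row.alt}"
                f"\t.\t{row.filter}\t.\tGT\t{row.gt}\n"
            )
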
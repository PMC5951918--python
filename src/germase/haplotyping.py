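"""Trio-lite haplotype construction from fetal and maternal variant calls.

A site is *informative* when the fetus is heterozygous and the mother
homozygous: the maternal allele of the fetus must be the one the mother
carries, so the other allele is paternal. Maternally heterozygous sites,
indels, multi-allelic records and low-quality (non-PASS) calls are discarded.
The selected sites define the two parental haplotypes, which can be
substituted into a reference sequence to produce individualized parental
references for allele-specific alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_HET = {"0/1", "1/0"}
_HOM_REF = {"0/0"}
_HOM_ALT = {"1/1"}


@dataclass(frozen=True)
class PhasedSNP:
    """One fetal heterozygous site with its parental allele assignment."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    paternal_allele: str
    maternal_allele: str
    informative_class: str  # mother_hom_ref or mother_hom_alt

    def __post_init__(self) -> None:
        if {self.paternal_allele, self.maternal_allele} != {
            self.ref_allele,
            self.alt_allele,
        }:
            raise ValueError(
                "parental alleles must partition {ref, alt} at "
                f"{self.chromosome}:{self.position}"
            )


@dataclass
class HaplotypeSummary:
    """Bookkeeping of informative vs discarded sites for one trio."""

    n_paternal_informative: int = 0  # mother 0/0, fetus 0/1
    n_maternal_informative: int = 0  # mother 1/1, fetus 0/1
    n_discarded_maternal_het: int = 0
    n_discarded_lowq_or_indel: int = 0
    n_discarded_missing_in_mother: int = 0

    @property
    def n_informative(self) -> int:
        return self.n_paternal_informative + self.n_maternal_informative

    @property
    def n_fetal_het_total(self) -> int:
        """All fetal-het sites considered (informative + every discard)."""
        return (
            self.n_informative
            + self.n_discarded_maternal_het
            + self.n_discarded_lowq_or_indel
            + self.n_discarded_missing_in_mother
        )


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and "," not in alt and alt != "."


def select_informative_snps(
    fetal_variants: pd.DataFrame,
    maternal_variants: pd.DataFrame,
) -> tuple[list[PhasedSNP], HaplotypeSummary]:
    """Select informative SNPs and assign each fetal allele a parent.

    Keeps exactly the sites that are PASS biallelic SNPs in both individuals,
    heterozygous in the fetus and homozygous in the mother. Mother 0/0 means
    the fetal ALT allele is paternal; mother 1/1 means the fetal ALT allele
    is maternal. Maternal-het sites, indels/multi-allelic records, non-PASS
    calls and sites absent from the maternal table are counted in the
    respective discard categories; contradictory genotypes (mother homozygous
    for an allele the fetus lacks) are excluded and logged.
    """
    mat = maternal_variants.set_index(["chromosome", "position"])
    if mat.index.has_duplicates:
        raise ValueError("duplicate sites in maternal variant table")

    phased: list[PhasedSNP] = []
    summary = HaplotypeSummary()
    for row in fetal_variants.itertuples(index=False):
        if row.gt not in _HET:
            # contradictory-genotype check on fetal hom sites
            key = (row.chromosome, row.position)
            if key in mat.index:
                mrow = mat.loc[key]
                if (row.gt in _HOM_REF and mrow["gt"] in _HOM_ALT) or (
                    row.gt in _HOM_ALT and mrow["gt"] in _HOM_REF
                ):
                    logger.warning(
                        "contradictory genotypes at %s:%d (fetus %s, mother %s)"
                        " — excluded",
                        row.chromosome, row.position, row.gt, mrow["gt"],
                    )
            continue
        if row.filter != "PASS" or not _is_snp(row.ref, row.alt):
            summary.n_discarded_lowq_or_indel += 1
            continue
        key = (row.chromosome, row.position)
        if key not in mat.index:
            summary.n_discarded_missing_in_mother += 1
            continue
        mrow = mat.loc[key]
        if mrow["filter"] != "PASS" or not _is_snp(mrow["ref"], mrow["alt"]):
            summary.n_discarded_lowq_or_indel += 1
            continue
        if mrow["gt"] in _HET:
            summary.n_discarded_maternal_het += 1
            continue
        if mrow["gt"] in _HOM_REF:
            paternal, maternal = row.alt, row.ref
            klass = "mother_hom_ref"
            summary.n_paternal_informative += 1
        elif mrow["gt"] in _HOM_ALT:
            paternal, maternal = row.ref, row.alt
            klass = "mother_hom_alt"
            summary.n_maternal_informative += 1
        else:  # missing/other genotype: non-informative
            summary.n_discarded_missing_in_mother += 1
            continue
        phased.append(
            PhasedSNP(
                chromosome=row.chromosome,
                position=int(row.position),
                ref_allele=row.ref,
                alt_allele=row.alt,
                paternal_allele=paternal,
                maternal_allele=maternal,
                informative_class=klass,
            )
        )
    return phased, summary


def phased_to_frame(phased: list[PhasedSNP]) -> pd.DataFrame:
    """Tabular view of a phased SNP list."""
    return pd.DataFrame(
        [
            (
                p.chromosome,
                p.position,
                p.ref_allele,
                p.alt_allele,
                p.paternal_allele,
                p.maternal_allele,
                p.informative_class,
            )
            for p in phased
        ],
        columns=[
            "chromosome",
            "position",
            "ref",
            "alt",
            "paternal_allele",
            "maternal_allele",
            "informative_class",
        ],
    )


def build_parental_sequences(
    reference_sequence: str,
    phased: list[PhasedSNP],
) -> tuple[str, str]:
    """Substitute phased alleles into a reference sequence.

    Returns ``(paternal, maternal)`` sequences: the reference with
    single-base substitutions at the phased positions (1-based), lengths
    unchanged.
    """
    positions = [p.position for p in phased]
    if len(set(positions)) != len(positions):
        raise ValueError("phased positions must be unique")
    pat = list(reference_sequence)
    mat = list(reference_sequence)
    for snp in phased:
        i = snp.position - 1
        if not 0 <= i < len(reference_sequence):
            raise ValueError(
                f"position {snp.position} outside reference of length "
                f"{len(reference_sequence)}"
            )
        if reference_sequence[i] != snp.ref_allele:
            raise ValueError(
                f"reference mismatch at {snp.chromosome}:{snp.position}: "
                f"expected {snp.ref_allele}, found {reference_sequence[i]}"
            )
        pat[i] = snp.paternal_allele
        mat[i] = snp.maternal_allele
    return "".join(pat), "".join(mat)


def phase_recovery_check(
    truth_phase: pd.DataFrame,
    phased: list[PhasedSNP] | pd.DataFrame,
) -> float:
    """Fraction of truth-informative sites whose paternal allele matches.

    Computed over the intersection of site sets; a warning is emitted (and
    NaN returned) when the intersection is empty.
    """
    obs = phased if isinstance(phased, pd.DataFrame) else phased_to_frame(phased)
    merged = truth_phase.merge(
        obs,
        on=["chromosome", "position"],
        suffixes=("_truth", "_obs"),
    )
    if merged.empty:
        warnings.warn("no overlapping sites between truth and phased tables")
        return float("nan")
    if len(merged) < len(truth_phase):
        warnings.warn(
            f"accuracy computed over {len(merged)} of {len(truth_phase)} "
            "truth sites (disjoint remainder)"
        )
    match = merged["paternal_allele_truth"] == merged["paternal_allele_obs"]
    return float(np.mean(match))
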
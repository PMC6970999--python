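"""The variant-level filtering funnel.

Stages, in pipeline order: trio relatedness sanity check (SNP concordance),
site-quality hard filters on the five standard metrics, inheritance-mode
partition (X-linked / autosomal-recessive / de novo, evaluated through the
pedigree), SO-impact selection, and population-panel allele-frequency
exclusions.  All threshold comparisons are *strict*, so a value sitting
exactly on a threshold survives.

Absent-annotation semantics are conservative per stage: an absent QC metric
cannot fail the quality filter, an absent panel frequency cannot fail a
frequency exclusion (novel alleles survive), but an absent consequence drops
the variant at impact selection because it cannot be classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .impact import ImpactClass, ImpactTable
from .models import AnnotatedVariant, InheritanceMode, Role, Sex, TrioPedigree

logger = logging.getLogger(__name__)

__all__ = [
    "QualityThresholds",
    "FrequencyThresholds",
    "trio_concordance",
    "apply_quality_filters",
    "assign_inheritance_modes",
    "partition_by_inheritance",
    "select_by_impact",
    "apply_frequency_exclusions",
    "select_rare_aj",
]


@dataclass(frozen=True)
class QualityThresholds:
    """Site-level hard-filter cutoffs (GATK-style).

    A variant fails when any *present* metric crosses its cutoff strictly:
    QD < qd_min, FS > fs_max, MQ < mq_min, MQRankSum < mqranksum_min,
    ReadPosRankSum < readposranksum_min.
    """

    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0


@dataclass(frozen=True)
class FrequencyThresholds:
    """Population-panel allele-frequency cutoffs.

    The common-variant exclusions drop anything strictly above a panel
    maximum; the rare-variant workflow additionally requires the Ashkenazi
    Jewish frequency to be strictly below ``aj_rare_max``.
    """

    dbsnp_gmaf_max: float = 0.05
    kgp_gmaf_max: float = 0.02
    exac_maf_max: float = 0.05
    aj_maf_max: float = 0.05
    aj_rare_max: float = 0.001

    def __post_init__(self) -> None:
        if not self.aj_rare_max < self.aj_maf_max:
            raise ValueError("aj_rare_max must be below aj_maf_max")


def trio_concordance(
    variants: Iterable[AnnotatedVariant],
    pedigree: TrioPedigree,
    min_sites: int = 100,
    flag_threshold: float = 0.5,
) -> dict[tuple[Role, Role], float]:
    """SNP concordance per trio sample pair, as a relatedness sanity check.

    Uses autosomal SNVs with all three genotypes called.  For each pair the
    concordance is the fraction of sites where the two samples share at
    least one allele index.  A parent-proband value below ``flag_threshold``
    emits a warning, never a failure: the check flags sample swaps, it does
    not gate the pipeline.
    """
    usable = [
        v
        for v in variants
        if v.is_autosomal
        and v.is_snv
        and all(not v.genotypes[r].is_missing for r in Role)
    ]
    if len(usable) < min_sites:
        raise ValueError(
            f"only {len(usable)} usable autosomal SNV sites, need at least {min_sites}"
        )
    result: dict[tuple[Role, Role], float] = {}
    for a, b in combinations([Role.PROBAND, Role.MOTHER, Role.FATHER], 2):
        shared = sum(
            1
            for v in usable
            if set(v.genotypes[a].alleles) & set(v.genotypes[b].alleles)
        )
        result[(a, b)] = shared / len(usable)
    for (a, b), conc in result.items():
        if Role.PROBAND in (a, b) and conc < flag_threshold:
            logger.warning(
                "low %s-%s concordance %.3f (< %.2f): check sample identity",
                a.value, b.value, conc, flag_threshold,
            )
    return result


def apply_quality_filters(
    variants: Iterable[AnnotatedVariant],
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition variants into (passed, failed) by the five hard filters.

    Absent metrics never fail a variant.  Every variant's provenance records
    the decision and, on failure, which metrics violated.
    """
    checks = [
        ("QD", lambda x: x < thresholds.qd_min),
        ("FS", lambda x: x > thresholds.fs_max),
        ("MQ", lambda x: x < thresholds.mq_min),
        ("MQRankSum", lambda x: x < thresholds.mqranksum_min),
        ("ReadPosRankSum", lambda x: x < thresholds.readposranksum_min),
    ]
    passed: list[AnnotatedVariant] = []
    failed: list[AnnotatedVariant] = []
    for v in variants:
        violated = [name for name, bad in checks if name in v.qc and bad(v.qc[name])]
        if violated:
            v.tag("QC_FAIL:" + "+".join(violated))
            failed.append(v)
        else:
            v.tag("QC_PASS")
            passed.append(v)
    return passed, failed


# hg19 chrX pseudoautosomal regions (1-based, inclusive); only consulted
# when par_exclude is enabled — by default all of chrX counts as hemizygous
# territory for a male proband
PAR_X = ((60_001, 2_699_520), (154_931_044, 155_260_560))


def _in_par(variant: AnnotatedVariant) -> bool:
    return variant.is_x and any(lo <= variant.pos <= hi for lo, hi in PAR_X)


def assign_inheritance_modes(
    variant: AnnotatedVariant,
    pedigree: TrioPedigree,
    recessive_model: str = "strict",
    par_exclude: bool = False,
) -> set[InheritanceMode]:
    """Inheritance modes a variant's trio genotypes satisfy.

    "Present" means a non-missing genotype carrying >=1 alt allele.

    * X_LINKED: on chrX, present in proband and mother but not father.
    * DE_NOVO: present only in the proband.
    * AUTOSOMAL_RECESSIVE: autosomal, proband homozygous-alt; under the
      default ``strict`` model both parents are heterozygous, under
      ``relaxed`` each parent carries >=1 alt without being homozygous-alt.

    A variant with any missing trio genotype receives no modes and a
    MISSING_GENOTYPE provenance tag.  Modes can co-occur (a chrX variant
    absent in both parents is both X-absent and de novo territory), except
    that DE_NOVO and AUTOSOMAL_RECESSIVE are mutually exclusive by
    construction.
    """
    gts = variant.genotypes
    if any(gts[r].is_missing for r in Role):
        variant.tag("MISSING_GENOTYPE")
        return set()

    proband, mother, father = gts[Role.PROBAND], gts[Role.MOTHER], gts[Role.FATHER]
    modes: set[InheritanceMode] = set()

    if (
        variant.is_x
        and not (par_exclude and _in_par(variant))
        and proband.has_alt
        and mother.has_alt
        and not father.has_alt
    ):
        modes.add(InheritanceMode.X_LINKED)
        if (
            pedigree.proband_sex is Sex.MALE
            and proband.is_het
        ):
            # diploid het call on male chrX: callers disagree on X ploidy;
            # counted as present but flagged
            variant.tag("XHET_MALE")

    if proband.has_alt and not mother.has_alt and not father.has_alt:
        modes.add(InheritanceMode.DE_NOVO)

    if variant.is_autosomal and proband.is_hom_alt:
        if recessive_model == "strict":
            parental_ok = mother.is_het and father.is_het
        elif recessive_model == "relaxed":
            parental_ok = (
                mother.has_alt
                and father.has_alt
                and not mother.is_hom_alt
                and not father.is_hom_alt
            )
        else:
            raise ValueError(f"unknown recessive model {recessive_model!r}")
        if parental_ok:
            modes.add(InheritanceMode.AUTOSOMAL_RECESSIVE)

    return modes


def partition_by_inheritance(
    variants: Iterable[AnnotatedVariant],
    pedigree: TrioPedigree,
    recessive_model: str = "strict",
    par_exclude: bool = False,
) -> dict[InheritanceMode, list[AnnotatedVariant]]:
    """Assign modes to every variant and bucket those that carry >=1 mode.

    A variant satisfying several modes appears in each bucket; variants with
    no mode fall out of the funnel here (their provenance records NO_MODE).
    """
    buckets: dict[InheritanceMode, list[AnnotatedVariant]] = {m: [] for m in InheritanceMode}
    for v in variants:
        modes = assign_inheritance_modes(
            v, pedigree, recessive_model=recessive_model, par_exclude=par_exclude
        )
        if modes:
            for m in sorted(modes, key=lambda m: m.value):
                v.tag(f"MODE:{m.value}")
                buckets[m].append(v)
        elif "MISSING_GENOTYPE" not in v.provenance:
            v.tag("NO_MODE")
    return buckets


def select_by_impact(
    variants: Iterable[AnnotatedVariant],
    table: ImpactTable,
    allowed: set[ImpactClass] | None = None,
) -> list[AnnotatedVariant]:
    """Keep variants whose SO consequence maps to an allowed impact class.

    Defaults to HIGH and MODERATE (missense, nonsense, splice-disrupting...).
    Unknown terms are retained conservatively with an UNKNOWN_CONSEQUENCE
    tag; variants without any consequence annotation are dropped — they
    cannot be classified as functionally important.
    """
    if allowed is None:
        allowed = {ImpactClass.HIGH, ImpactClass.MODERATE}
    retained: list[AnnotatedVariant] = []
    for v in variants:
        if v.consequence is None:
            v.tag("NO_ANNOTATION")
            continue
        impact = table.impact_of(v.consequence)
        if impact is None:
            logger.warning("unknown SO consequence term %r retained", v.consequence)
            v.tag("UNKNOWN_CONSEQUENCE")
            retained.append(v)
        elif impact in allowed:
            v.tag(f"IMPACT:{impact.value}")
            retained.append(v)
        else:
            v.tag(f"IMPACT_DROP:{impact.value}")
    return retained


def apply_frequency_exclusions(
    variants: Iterable[AnnotatedVariant],
    thresholds: FrequencyThresholds = FrequencyThresholds(),
) -> list[AnnotatedVariant]:
    """Drop variants common in any population panel.

    A variant is excluded iff any *present* panel frequency strictly exceeds
    that panel's maximum; absent frequencies never exclude (novel alleles
    survive).
    """
    limits = {
        "dbSNP_GMAF": thresholds.dbsnp_gmaf_max,
        "KGP_GMAF": thresholds.kgp_gmaf_max,
        "ExAC_MAF": thresholds.exac_maf_max,
        "gnomAD_AJ_MAF": thresholds.aj_maf_max,
    }
    retained: list[AnnotatedVariant] = []
    for v in variants:
        offending = [p for p, lim in limits.items() if p in v.freqs and v.freqs[p] > lim]
        if offending:
            v.tag("COMMON:" + "+".join(offending))
        else:
            v.tag("FREQ_PASS")
            retained.append(v)
    return retained


def select_rare_aj(
    variants: Iterable[AnnotatedVariant],
    thresholds: FrequencyThresholds = FrequencyThresholds(),
) -> list[AnnotatedVariant]:
    """Workflow-1 entry gate: keep only Ashkenazi-rare variants.

    Retained iff the gnomAD AJ frequency is absent or strictly below
    ``aj_rare_max`` (default 0.1%).  This is the gate the headline-case
    variant fails (AJ frequency ~2%), which is why the pathogenicity-score
    workflow runs in parallel.
    """
    retained: list[AnnotatedVariant] = []
    for v in variants:
        aj = v.freqs.get("gnomAD_AJ_MAF")
        if aj is None or aj < thresholds.aj_rare_max:
            v.tag("AJ_RARE")
            retained.append(v)
        else:
            v.tag("AJ_NOT_RARE")
    return retained
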
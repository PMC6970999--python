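"""Workflow 2 (pathogenicity scores), workflow merge, and finalization.

The two parallel prioritization routes meet here.  Workflow 2 extracts
"possibly damaging SNVs" — variants crossing both predictor thresholds
(SIFT low = damaging, PolyPhen-2 high = damaging) — and keeps the top-k by a
combined pathogenic score.  The union of the network-supported set and the
pathogenicity set, minus a user-supplied exclusion list (modeling manual
disease-relevance review), is then finalized against orthogonal genotyping
(zygosity) observations: wild-type observations expose false positives, a
heterozygous observation contradicts a recessive or male-X candidate, and
consistent observations confirm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .models import (
    AnnotatedVariant,
    GeneScore,
    InheritanceMode,
    Outcome,
    Role,
    Sex,
    TrioPedigree,
    VariantKey,
    Workflow,
    Zygosity,
    ZygosityObservation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PathogenicityCall",
    "Candidate",
    "CandidateReport",
    "call_pds",
    "select_top_pathogenic",
    "merge_workflows",
    "apply_exclusion_list",
    "finalize_by_zygosity",
    "write_report",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class PathogenicityCall:
    """SIFT/PolyPhen-2 evaluation of one variant.

    ``is_pds`` (possibly damaging SNV) requires both scores present and both
    crossing their damaging thresholds.  ``combined`` = polyphen + (1 - sift)
    when both scores are present — monotone in each predictor's damaging
    direction, in [0, 2].
    """

    variant_key: VariantKey
    sift: float | None
    polyphen: float | None
    is_pds: bool
    combined: float | None


@dataclass
class Candidate:
    """One merged candidate variant with its evidence trail."""

    variant: AnnotatedVariant
    modes: set[InheritanceMode]
    workflow: Workflow
    gene_score: GeneScore | None = None
    path_call: PathogenicityCall | None = None
    outcome: Outcome = Outcome.UNTESTED
    exclusion_reason: str | None = None

    @property
    def gene(self) -> str | None:
        return self.variant.gene

    @property
    def key(self) -> VariantKey:
        return self.variant.key


@dataclass
class CandidateReport:
    """Final ranked candidates with per-stage provenance.

    ``rows`` holds every merged candidate (including dropped ones, with
    their outcome); ``final_rank`` is assigned only to retained rows
    (CONFIRMED, then UNTESTED).
    """

    rows: list[Candidate] = field(default_factory=list)
    final_ranks: dict[VariantKey, int] = field(default_factory=dict)


def call_pds(
    variants: Iterable[AnnotatedVariant],
    sift_max: float = 0.05,
    polyphen_min: float = 0.447,
) -> list[PathogenicityCall]:
    """Evaluate each variant's predictor scores into a PathogenicityCall."""
    calls = []
    for v in variants:
        is_pds = (
            v.sift is not None
            and v.sift <= sift_max
            and v.polyphen is not None
            and v.polyphen >= polyphen_min
        )
        combined = (
            v.polyphen + (1.0 - v.sift)
            if v.sift is not None and v.polyphen is not None
            else None
        )
        if is_pds:
            v.tag("PDS")
        calls.append(
            PathogenicityCall(
                variant_key=v.key,
                sift=v.sift,
                polyphen=v.polyphen,
                is_pds=is_pds,
                combined=combined,
            )
        )
    return calls


def select_top_pathogenic(
    calls: Sequence[PathogenicityCall],
    variants_by_key: Mapping[VariantKey, AnnotatedVariant],
    k: int = 2,
) -> list[PathogenicityCall]:
    """Top-k PDS calls by combined score, descending.

    Ties break by lower SIFT, then by gene symbol.  If fewer than k PDS
    calls exist, all are returned with a warning.
    """
    eligible = [c for c in calls if c.is_pds]
    if len(eligible) < k:
        logger.warning("only %d PDS variant(s) available for top-%d selection", len(eligible), k)

    def sort_key(c: PathogenicityCall):
        gene = variants_by_key[c.variant_key].gene or ""
        return (-(c.combined if c.combined is not None else float("-inf")), c.sift, gene)

    return sorted(eligible, key=sort_key)[:k]


def merge_workflows(
    network_set: Sequence[AnnotatedVariant],
    pathogenicity_set: Sequence[AnnotatedVariant],
    modes_by_key: Mapping[VariantKey, set[InheritanceMode]],
    gene_scores: Mapping[str, GeneScore] | None = None,
    path_calls: Mapping[VariantKey, PathogenicityCall] | None = None,
) -> list[Candidate]:
    """Union of the two workflows' outputs with provenance tagging.

    A variant present in both sets is tagged BOTH; the union size obeys
    inclusion-exclusion by construction.
    """
    net_keys = {v.key for v in network_set}
    path_keys = {v.key for v in pathogenicity_set}
    by_key: dict[VariantKey, AnnotatedVariant] = {}
    for v in list(network_set) + list(pathogenicity_set):
        by_key.setdefault(v.key, v)

    candidates = []
    for key in sorted(by_key):
        v = by_key[key]
        if key in net_keys and key in path_keys:
            wf = Workflow.BOTH
        elif key in net_keys:
            wf = Workflow.NETWORK
        else:
            wf = Workflow.PATHOGENICITY
        v.tag(f"WORKFLOW:{wf.value}")
        candidates.append(
            Candidate(
                variant=v,
                modes=set(modes_by_key.get(key, set())),
                workflow=wf,
                gene_score=(gene_scores or {}).get(v.gene) if v.gene else None,
                path_call=(path_calls or {}).get(key),
            )
        )
    return candidates


def apply_exclusion_list(
    candidates: Sequence[Candidate], exclusions: Mapping[str, str]
) -> list[Candidate]:
    """Remove candidates whose gene appears in the manual-review exclusion
    list, carrying the stated reason into the report."""
    candidate_genes = {c.gene for c in candidates}
    for gene in exclusions:
        if gene not in candidate_genes:
            logger.warning("excluded gene %s is not among the candidates", gene)
    retained = []
    for c in candidates:
        if c.gene is not None and c.gene in exclusions:
            c.exclusion_reason = exclusions[c.gene]
            c.variant.tag(f"EXCLUDED:{c.gene}")
        else:
            c.variant.tag("REVIEW_PASS")
            retained.append(c)
    return retained


def _zygosity_outcome(
    candidate: Candidate, observed: Zygosity, pedigree: TrioPedigree
) -> Outcome:
    male_x = (
        pedigree.proband_sex is Sex.MALE and InheritanceMode.X_LINKED in candidate.modes
    )
    if observed is Zygosity.WILD_TYPE:
        return Outcome.FALSE_POSITIVE
    if observed is Zygosity.HETEROZYGOUS and (
        InheritanceMode.AUTOSOMAL_RECESSIVE in candidate.modes or male_x
    ):
        # one wild-type allele contradicts a recessive or hemizygous model
        return Outcome.ZYGOSITY_INCONSISTENT
    return Outcome.CONFIRMED


_WORKFLOW_ORDER = {Workflow.BOTH: 0, Workflow.NETWORK: 1, Workflow.PATHOGENICITY: 1}


def finalize_by_zygosity(
    candidates: Sequence[Candidate],
    observations: Sequence[ZygosityObservation],
    pedigree: TrioPedigree,
) -> CandidateReport:
    """Resolve each candidate against orthogonal genotyping and rank.

    Outcomes: a WILD_TYPE observation marks a false positive (dropped); a
    HETEROZYGOUS observation contradicts an autosomal-recessive or
    male-proband X-linked candidate (dropped); consistent observations
    confirm; candidates without an observation stay UNTESTED and retained —
    absence of genotyping is not evidence against.

    Ranking: CONFIRMED above UNTESTED; within a group, BOTH-workflow rows
    first, then descending combined pathogenic score (absent sorts last),
    then descending diffusion score, then gene symbol.
    """
    obs_by_key = {o.variant_key: o for o in observations}
    matched_keys = set()
    for c in candidates:
        o = obs_by_key.get(c.key)
        if o is None:
            c.outcome = Outcome.UNTESTED
            c.variant.tag("ZYGOSITY:UNTESTED")
        else:
            matched_keys.add(c.key)
            c.outcome = _zygosity_outcome(c, o.observed, pedigree)
            c.variant.tag(f"ZYGOSITY:{c.outcome.value}")
    for o in observations:
        if o.variant_key not in matched_keys:
            logger.warning(
                "zygosity observation for %s %s does not match any candidate",
                o.gene, o.variant_key,
            )

    retained = [c for c in candidates if c.outcome in (Outcome.CONFIRMED, Outcome.UNTESTED)]

    def rank_key(c: Candidate):
        combined = (
            c.path_call.combined
            if c.path_call is not None and c.path_call.combined is not None
            else float("-inf")
        )
        diffusion = c.gene_score.diffusion if c.gene_score is not None else float("-inf")
        return (
            0 if c.outcome is Outcome.CONFIRMED else 1,
            _WORKFLOW_ORDER[c.workflow],
            -combined,
            -diffusion,
            c.gene or "",
            c.key,
        )

    ordered = sorted(retained, key=rank_key)
    final_ranks = {c.key: i + 1 for i, c in enumerate(ordered)}
    dropped = [c for c in candidates if c.key not in final_ranks]
    rows = ordered + sorted(dropped, key=lambda c: (c.gene or "", c.key))
    return CandidateReport(rows=rows, final_ranks=final_ranks)


_TSV_COLUMNS = [
    "rank",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "modes",
    "workflow",
    "direct_score",
    "diffusion_score",
    "sift",
    "polyphen",
    "combined_score",
    "outcome",
    "exclusion_reason",
    "provenance",
]


def _row_record(report: CandidateReport, c: Candidate) -> dict:
    chrom, pos, ref, alt = c.key
    return {
        "rank": report.final_ranks.get(c.key),
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": c.gene,
        "modes": ",".join(sorted(m.value for m in c.modes)),
        "workflow": c.workflow.value,
        "direct_score": c.gene_score.direct if c.gene_score else None,
        "diffusion_score": c.gene_score.diffusion if c.gene_score else None,
        "sift": c.path_call.sift if c.path_call else None,
        "polyphen": c.path_call.polyphen if c.path_call else None,
        "combined_score": c.path_call.combined if c.path_call else None,
        "outcome": c.outcome.value,
        "exclusion_reason": c.exclusion_reason,
        "provenance": ";".join(c.variant.provenance),
    }


def write_report(report: CandidateReport, path: str | Path, format: str = "TSV") -> None:
    """Serialize a CandidateReport as TSV or JSON, deterministically."""
    records = [_row_record(report, c) for c in report.rows]
    path = Path(path)
    if format.upper() == "TSV":
        lines = [
            f"# candidate report (schema {REPORT_SCHEMA_VERSION})",
            "# columns: " + ", ".join(_TSV_COLUMNS),
            "\t".join(_TSV_COLUMNS),
        ]
        for r in records:
            lines.append(
                "\t".join("." if r[col] is None else str(r[col]) for col in _TSV_COLUMNS)
            )
        path.write_text("\n".join(lines) + "\n")
    elif format.upper() == "JSON":
        payload = {"schema_version": REPORT_SCHEMA_VERSION, "candidates": records}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
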
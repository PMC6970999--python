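"""Readers and writers for every external format the pipeline touches.

VCF 4.2 (trio genotypes + INFO annotations, read via cyvcf2, written as
deterministic text), 6-column PED, STRING-style weighted network TSV, plain
seed-gene lists, and orthogonal-genotyping (zygosity) tables.

Annotation INFO keys vary between annotators, so they are configurable
through :class:`VcfDialect`; the defaults match the flat-key style this
package's own writer and simulator emit.  Chromosome names are normalized at
ingest: a ``chr`` prefix is stripped and names are uppercased, so ``chrx``
and ``X`` compare equal.  Absent annotations stay absent — they are never
silently defaulted to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .models import (
    PANELS,
    QC_METRICS,
    AnnotatedVariant,
    GeneNetwork,
    GenotypeCall,
    Role,
    Sex,
    TrioPedigree,
    Zygosity,
    ZygosityObservation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VcfDialect",
    "read_trio_vcf",
    "write_trio_vcf",
    "read_pedigree",
    "read_network",
    "read_seed_genes",
    "read_zygosity_table",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix (case-insensitive) and uppercase."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


@dataclass(frozen=True)
class VcfDialect:
    """Which INFO keys hold each annotation."""

    gene_key: str = "GENE"
    consequence_key: str = "CONSEQUENCE"
    freq_keys: dict[str, str] = field(
        default_factory=lambda: {
            "dbSNP_GMAF": "DBSNP_GMAF",
            "KGP_GMAF": "KGP_GMAF",
            "ExAC_MAF": "EXAC_MAF",
            "gnomAD_AJ_MAF": "AJ_MAF",
        }
    )
    sift_key: str = "SIFT"
    polyphen_key: str = "POLYPHEN"
    provenance_key: str = "PROV"


DEFAULT_DIALECT = VcfDialect()


def _call_from_cyvcf2(raw: list, alt_index: int) -> GenotypeCall:
    """Map a cyvcf2 genotype list to a GenotypeCall for one split alt.

    cyvcf2 yields ``[a, phased]`` for haploid and ``[a, b, phased]`` for
    diploid calls; ``-1`` marks a missing allele.  Alleles equal to
    ``alt_index`` become 1; the reference and any *other* alt become 0.
    """
    *alleles, phased = raw
    if any(a < 0 for a in alleles) or not alleles:
        return GenotypeCall.missing()
    mapped = tuple(1 if a == alt_index else 0 for a in alleles)
    if len(mapped) not in (1, 2):
        logger.warning("unparseable genotype ploidy %d; treating as missing", len(mapped))
        return GenotypeCall.missing()
    return GenotypeCall(alleles=mapped, phased=bool(phased))


def read_trio_vcf(
    path: str | Path,
    pedigree: TrioPedigree,
    dialect: VcfDialect = DEFAULT_DIALECT,
) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF into AnnotatedVariants bound to trio roles.

    Multi-allelic records are split into one variant per alt allele; QC
    metrics are site-level and copied to each split record.  Record order is
    preserved.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    role_cols: dict[Role, int] = {}
    for role, sample_id in pedigree.sample_ids.items():
        if sample_id not in samples:
            raise ValueError(f"pedigree sample {sample_id!r} ({role.value}) absent from VCF header")
        role_cols[role] = samples.index(sample_id)

    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        qc = {}
        for metric in QC_METRICS:
            val = rec.INFO.get(metric)
            if val is not None:
                qc[metric] = float(val)
        gene = rec.INFO.get(dialect.gene_key)
        consequence = rec.INFO.get(dialect.consequence_key)
        freqs = {}
        for panel, key in dialect.freq_keys.items():
            val = rec.INFO.get(key)
            if val is not None:
                freqs[panel] = float(val)
        sift = rec.INFO.get(dialect.sift_key)
        polyphen = rec.INFO.get(dialect.polyphen_key)
        prov_raw = rec.INFO.get(dialect.provenance_key)
        provenance = list(str(prov_raw).split(",")) if prov_raw else []

        for alt_index, alt in enumerate(rec.ALT, start=1):
            genotypes = {
                role: _call_from_cyvcf2(rec.genotypes[col], alt_index)
                for role, col in role_cols.items()
            }
            variants.append(
                AnnotatedVariant(
                    chrom=normalize_chrom(rec.CHROM),
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    genotypes=genotypes,
                    qc=dict(qc),
                    gene=gene,
                    consequence=consequence,
                    freqs=dict(freqs),
                    sift=float(sift) if sift is not None else None,
                    polyphen=float(polyphen) if polyphen is not None else None,
                    provenance=list(provenance),
                )
            )
    vcf.close()
    return variants


_VCF_HEADER_INFO = [
    ("QD", "Float", "Variant confidence normalized by depth"),
    ("FS", "Float", "Phred-scaled Fisher strand-bias p-value"),
    ("MQ", "Float", "RMS mapping quality"),
    ("MQRankSum", "Float", "Rank-sum Z of alt vs ref mapping qualities"),
    ("ReadPosRankSum", "Float", "Rank-sum Z of alt vs ref read positions"),
]


def _fmt_float(x: float) -> str:
    # repr round-trips doubles exactly; integral floats still get a dot
    return repr(float(x))


def write_trio_vcf(
    variants: Sequence[AnnotatedVariant],
    pedigree: TrioPedigree,
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
) -> None:
    """Write AnnotatedVariants as a VCF 4.2 file with byte-stable output.

    Sample columns are emitted in proband, mother, father order; every INFO
    key written is declared in the header; provenance tags are serialized
    into a dedicated INFO field.
    """
    lines = ["##fileformat=VCFv4.2"]
    contigs = sorted(
        {v.chrom for v in variants},
        key=lambda c: (0, int(c)) if c.isdigit() else (1, c),
    )
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for key, typ, desc in _VCF_HEADER_INFO:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    lines.append(f'##INFO=<ID={dialect.gene_key},Number=1,Type=String,Description="Gene symbol">')
    lines.append(
        f'##INFO=<ID={dialect.consequence_key},Number=1,Type=String,'
        'Description="SO consequence term">'
    )
    for panel, key in dialect.freq_keys.items():
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="Allele frequency ({panel})">'
        )
    lines.append(f'##INFO=<ID={dialect.sift_key},Number=1,Type=Float,Description="SIFT score">')
    lines.append(
        f'##INFO=<ID={dialect.polyphen_key},Number=1,Type=Float,'
        'Description="PolyPhen-2 score">'
    )
    lines.append(
        f'##INFO=<ID={dialect.provenance_key},Number=.,Type=String,'
        'Description="Pipeline stage provenance tags">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{pedigree.proband_id}\t{pedigree.mother_id}\t{pedigree.father_id}"
    )

    for v in variants:
        info_parts = []
        for metric in QC_METRICS:
            if metric in v.qc:
                info_parts.append(f"{metric}={_fmt_float(v.qc[metric])}")
        if v.gene is not None:
            info_parts.append(f"{dialect.gene_key}={v.gene}")
        if v.consequence is not None:
            info_parts.append(f"{dialect.consequence_key}={v.consequence}")
        for panel, key in dialect.freq_keys.items():
            if panel in v.freqs:
                info_parts.append(f"{key}={_fmt_float(v.freqs[panel])}")
        if v.sift is not None:
            info_parts.append(f"{dialect.sift_key}={_fmt_float(v.sift)}")
        if v.polyphen is not None:
            info_parts.append(f"{dialect.polyphen_key}={_fmt_float(v.polyphen)}")
        if v.provenance:
            info_parts.append(f"{dialect.provenance_key}={','.join(v.provenance)}")
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(
            v.genotypes[r].gt_string() for r in (Role.PROBAND, Role.MOTHER, Role.FATHER)
        )
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t{gts}")

    Path(path).write_text("\n".join(lines) + "\n")


def read_pedigree(path: str | Path) -> TrioPedigree:
    """Parse a 6-column PED file into a TrioPedigree.

    Exactly one affected child with both declared parents present is
    required; sex codes 1/2 map to MALE/FEMALE and 0/unknown is fatal
    (X-linked logic needs the proband's sex).
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has {len(fields)} columns, expected 6: {line!r}")
        rows.append(fields[:6])

    individuals = {r[1] for r in rows}
    trios = [
        r
        for r in rows
        if r[5] == "2"
        and r[2] in individuals
        and r[3] in individuals
        and r[2] != "0"
        and r[3] != "0"
    ]
    if len(trios) != 1:
        raise ValueError(f"expected exactly one affected child with both parents, found {len(trios)}")
    fam, child, father, mother, sex_code, _pheno = trios[0]
    if sex_code == "1":
        sex = Sex.MALE
    elif sex_code == "2":
        sex = Sex.FEMALE
    else:
        raise ValueError(f"proband sex code {sex_code!r} is unknown; X-linked analysis needs it")

    by_id = {r[1]: r for r in rows}
    affected = {
        Role.PROBAND: True,
        Role.MOTHER: by_id[mother][5] == "2",
        Role.FATHER: by_id[father][5] == "2",
    }
    if affected[Role.MOTHER] or affected[Role.FATHER]:
        logger.warning("a parent is marked affected; this analysis assumes unaffected parents")
    return TrioPedigree(
        proband_id=child,
        mother_id=mother,
        father_id=father,
        proband_sex=sex,
        affected=affected,
    )


def write_pedigree(pedigree: TrioPedigree, path: str | Path, family_id: str = "FAM1") -> None:
    sex_code = "1" if pedigree.proband_sex is Sex.MALE else "2"
    lines = [
        f"{family_id}\t{pedigree.father_id}\t0\t0\t1\t1",
        f"{family_id}\t{pedigree.mother_id}\t0\t0\t2\t1",
        f"{family_id}\t{pedigree.proband_id}\t{pedigree.father_id}\t{pedigree.mother_id}\t{sex_code}\t2",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path, weight_threshold: float = 0.7) -> GeneNetwork:
    """Read a STRING-style gene1/gene2/score TSV into a GeneNetwork.

    Scores are auto-scaled: if any score exceeds 1 the column is taken to be
    STRING's 0-1000 convention and divided by 1000.  Edges are kept only when
    weight is *strictly* above ``weight_threshold``; duplicate pairs collapse
    to the maximum weight; self-loops are dropped (count logged).  Seeds are
    left empty — attach them with :func:`read_seed_genes`.
    """
    records: list[tuple[str, str, float]] = []
    n_bad = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            parts = line.split()
        if len(parts) < 3:
            logger.warning("skipping malformed network line %d: %r", lineno, line)
            n_bad += 1
            continue
        try:
            score = float(parts[2])
        except ValueError:
            logger.warning("skipping network line %d with non-numeric score: %r", lineno, line)
            n_bad += 1
            continue
        records.append((parts[0], parts[1], score))
    if n_bad:
        logger.warning("%d malformed network lines skipped", n_bad)

    if records and max(s for _, _, s in records) > 1.0:
        records = [(a, b, s / 1000.0) for a, b, s in records]

    edges: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, w in records:
        if a == b:
            n_self += 1
            continue
        if w <= weight_threshold:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in edges or w > edges[key]:
            edges[key] = w
    if n_self:
        logger.info("dropped %d self-loop(s)", n_self)
    if not edges:
        raise ValueError(
            f"no network edges above confidence threshold {weight_threshold}; cannot build network"
        )
    nodes = {g for pair in edges for g in pair}
    return GeneNetwork(nodes=nodes, edges=edges, seeds=set())


def read_seed_genes(
    path: str | Path, network: GeneNetwork, case_insensitive: bool = False
) -> GeneNetwork:
    """Attach a seed-gene list (one symbol per line, '#' comments) to a network.

    Seeds are the intersection of the listed symbols with the network nodes;
    unmatched symbols are counted and logged.  An empty intersection is fatal
    because propagation is undefined without seeds.
    """
    listed: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#")[0].strip()
        if sym:
            listed.add(sym)
    if case_insensitive:
        by_lower = {n.lower(): n for n in network.nodes}
        matched = {by_lower[s.lower()] for s in listed if s.lower() in by_lower}
    else:
        matched = listed & network.nodes
    unmatched = len(listed) - len(matched)
    if unmatched:
        logger.warning("%d seed symbol(s) not found in the network", unmatched)
    if not matched:
        raise ValueError("no seed gene matches any network node; propagation is undefined")
    return network.with_seeds(matched)


def read_zygosity_table(path: str | Path) -> list[ZygosityObservation]:
    """Read a gene/chrom/pos/ref/alt/observed TSV of genotyping outcomes."""
    obs: list[ZygosityObservation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"zygosity table line {lineno}: expected 6 columns, got {len(parts)}")
        gene, chrom, pos, ref, alt, observed = parts
        try:
            zyg = Zygosity(observed)
        except ValueError:
            raise ValueError(
                f"zygosity table line {lineno}: unknown category {observed!r} "
                f"(expected one of {[z.value for z in Zygosity]})"
            ) from None
        obs.append(
            ZygosityObservation(
                gene=gene,
                variant_key=(normalize_chrom(chrom), int(pos), ref, alt),
                observed=zyg,
            )
        )
    return obs


def write_zygosity_table(observations: Iterable[ZygosityObservation], path: str | Path) -> None:
    lines = ["gene\tchrom\tpos\tref\talt\tobserved"]
    for o in observations:
        chrom, pos, ref, alt = o.variant_key
        lines.append(f"{o.gene}\t{chrom}\t{pos}\t{ref}\t{alt}\t{o.observed.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_network(network: GeneNetwork, path: str | Path) -> None:
    """Write a GeneNetwork as a gene1/gene2/weight TSV (weights in [0, 1])."""
    lines = [f"{a}\t{b}\t{_fmt_float(w)}" for (a, b), w in sorted(network.edges.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def write_seed_list(seeds: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(seeds)) + "\n")
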
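"""Domain types shared across the prioritization pipeline.

The pipeline's unit of work is a single bi-allelic variant record carrying
trio genotypes, site-level QC metrics, and functional annotations
(:class:`AnnotatedVariant`).  Genotypes are evaluated through the lens of a
:class:`TrioPedigree` (who is the affected proband, who are the parents, and
what sex is the proband — chrX logic depends on it).  Network-based gene
ranking operates on a :class:`GeneNetwork`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Role",
    "Sex",
    "Zygosity",
    "InheritanceMode",
    "Workflow",
    "Outcome",
    "GenotypeCall",
    "AnnotatedVariant",
    "TrioPedigree",
    "GeneNetwork",
    "GeneScore",
    "ZygosityObservation",
    "VariantKey",
    "AUTOSOMES",
    "PANELS",
    "QC_METRICS",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: canonical population-panel names for the frequency annotations
PANELS = ("dbSNP_GMAF", "KGP_GMAF", "ExAC_MAF", "gnomAD_AJ_MAF")

#: the five site-level hard-filter metrics
QC_METRICS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

VariantKey = tuple[str, int, str, str]


class Role(str, enum.Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Zygosity(str, enum.Enum):
    WILD_TYPE = "WILD_TYPE"
    HETEROZYGOUS = "HETEROZYGOUS"
    HOMOZYGOUS_ALT = "HOMOZYGOUS_ALT"
    HEMIZYGOUS_ALT = "HEMIZYGOUS_ALT"


class InheritanceMode(str, enum.Enum):
    X_LINKED = "X_LINKED"
    AUTOSOMAL_RECESSIVE = "AUTOSOMAL_RECESSIVE"
    DE_NOVO = "DE_NOVO"


class Workflow(str, enum.Enum):
    NETWORK = "NETWORK"
    PATHOGENICITY = "PATHOGENICITY"
    BOTH = "BOTH"


class Outcome(str, enum.Enum):
    CONFIRMED = "CONFIRMED"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    ZYGOSITY_INCONSISTENT = "ZYGOSITY_INCONSISTENT"
    UNTESTED = "UNTESTED"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's called genotype at one site.

    ``alleles`` is an ordered tuple of allele indices (0 = ref, 1 = alt) of
    length 1 (haploid) or 2 (diploid), or ``None`` for a missing call.
    """

    alleles: tuple[int, ...] | None
    phased: bool = False

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) not in (1, 2):
                raise ValueError(f"genotype ploidy must be 1 or 2, got {self.alleles}")
            if any(a not in (0, 1) for a in self.alleles):
                raise ValueError(f"allele indices must be 0 or 1, got {self.alleles}")

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(alleles=None)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def has_alt(self) -> bool:
        """True iff the call is non-missing and carries >=1 alt allele."""
        return self.alleles is not None and any(a == 1 for a in self.alleles)

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles is not None and len(self.alleles) == 2 and all(
            a == 1 for a in self.alleles
        )

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and len(self.alleles) == 2 and sorted(
            self.alleles
        ) == [0, 1]

    @property
    def is_haploid_alt(self) -> bool:
        return self.alleles == (1,)

    def gt_string(self) -> str:
        if self.alleles is None:
            return "."
        sep = "|" if self.phased else "/"
        return sep.join(str(a) for a in self.alleles)


_VALID_BASES = set("ACGTN")


@dataclass
class AnnotatedVariant:
    """A single bi-allelic variant record with trio genotypes and annotations.

    Multi-allelic VCF records are split at ingest, so ``alt`` is always a
    single allele.  ``provenance`` is an append-only trail of stage decisions;
    no pipeline stage ever removes tags.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[Role, GenotypeCall]
    qc: dict[str, float] = field(default_factory=dict)
    gene: str | None = None
    consequence: str | None = None
    freqs: dict[str, float] = field(default_factory=dict)
    sift: float | None = None
    polyphen: float | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} must be a nonempty A/C/G/T/N string: {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for panel, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {panel}={f} outside [0, 1]")
        for name, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name}={score} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    @property
    def is_x(self) -> bool:
        return self.chrom == "X"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def tag(self, label: str) -> None:
        """Append a provenance tag (tags only accumulate)."""
        self.provenance.append(label)


@dataclass(frozen=True)
class TrioPedigree:
    """The proband-mother-father trio with sexes and affected status."""

    proband_id: str
    mother_id: str
    father_id: str
    proband_sex: Sex
    affected: Mapping[Role, bool] = field(
        default_factory=lambda: {Role.PROBAND: True, Role.MOTHER: False, Role.FATHER: False}
    )

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError("pedigree requires three distinct sample identifiers")

    @property
    def sample_ids(self) -> dict[Role, str]:
        return {
            Role.PROBAND: self.proband_id,
            Role.MOTHER: self.mother_id,
            Role.FATHER: self.father_id,
        }


@dataclass
class GeneNetwork:
    """Weighted undirected gene-interaction graph with a seed-gene subset.

    Edges are stored once per unordered pair (keys are lexicographically
    sorted 2-tuples); weights lie in (0, 1].
    """

    nodes: set[str]
    edges: dict[tuple[str, str], float]
    seeds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a > b:
                raise ValueError(f"edge key ({a}, {b}) not sorted")
            if not 0.0 < w <= 1.0:
                raise ValueError(f"edge weight {w} outside (0, 1]")
        if not self.seeds <= self.nodes:
            raise ValueError("seeds must be a subset of nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbors(self, gene: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == gene:
                out[b] = w
            elif b == gene:
                out[a] = w
        return out

    def with_seeds(self, seeds: Iterable[str]) -> "GeneNetwork":
        return GeneNetwork(nodes=set(self.nodes), edges=dict(self.edges), seeds=set(seeds))


@dataclass
class GeneScore:
    """Per-gene propagation scores and ranks among non-seed genes.

    ``direct`` is the seed-adjacent edge-weight sum (one-hop evidence);
    ``diffusion`` the Gaussian-smoothing score.  Ranks are competition ranks
    over non-seed genes only (1 = best, ties share the smallest rank); seeds
    carry rank ``None``.
    """

    gene: str
    direct: float
    diffusion: float
    direct_rank: int | None = None
    diffusion_rank: int | None = None
    is_seed: bool = False


@dataclass(frozen=True)
class ZygosityObservation:
    """One orthogonal-genotyping (Sanger-style) observation of a candidate."""

    gene: str
    variant_key: VariantKey
    observed: Zygosity
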
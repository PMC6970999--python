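"""Sequence Ontology consequence -> impact-class table.

Variants are selected for "functional importance" by the impact class of
their SO consequence term (HIGH and MODERATE by default: nonsense, frameshift,
splice-disrupting, missense, ...).  The packaged table follows the common
annotator convention and is user-overridable with any TSV of the same shape.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["ImpactClass", "ImpactTable", "load_default_impact_table"]

IMPACT_TABLE_VERSION = "1.0"


class ImpactClass(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


_CLASS_ORDER = {
    ImpactClass.HIGH: 0,
    ImpactClass.MODERATE: 1,
    ImpactClass.LOW: 2,
    ImpactClass.MODIFIER: 3,
}


@dataclass(frozen=True)
class ImpactTable:
    """Total severity order over SO terms plus the term -> class mapping."""

    classes: dict[str, ImpactClass]
    ranks: dict[str, int]
    version: str = IMPACT_TABLE_VERSION

    def __post_init__(self) -> None:
        # the severity order must respect class order: every HIGH term ranks
        # above (smaller rank than) every MODERATE term, and so on
        for term, rank in self.ranks.items():
            for other, other_rank in self.ranks.items():
                if _CLASS_ORDER[self.classes[term]] < _CLASS_ORDER[self.classes[other]]:
                    if rank >= other_rank:
                        raise ValueError(
                            f"severity order violated: {term} ({self.classes[term].value}) "
                            f"ranked below {other} ({self.classes[other].value})"
                        )

    def impact_of(self, term: str) -> ImpactClass | None:
        """Impact class of an SO term, or None for an unknown term."""
        return self.classes.get(term)

    def rank_of(self, term: str) -> int | None:
        return self.ranks.get(term)

    @classmethod
    def from_tsv(cls, path: str | Path, version: str = "custom") -> "ImpactTable":
        classes: dict[str, ImpactClass] = {}
        ranks: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, impact, rank = line.split("\t")
            classes[term] = ImpactClass(impact)
            ranks[term] = int(rank)
        return cls(classes=classes, ranks=ranks, version=version)


def load_default_impact_table() -> ImpactTable:
    """Load the packaged SO impact table."""
    ref = resources.files("trioprio.data").joinpath("so_impact.tsv")
    with resources.as_file(ref) as path:
        return ImpactTable.from_tsv(path, version=IMPACT_TABLE_VERSION)
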
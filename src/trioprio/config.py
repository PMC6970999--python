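"""Pipeline configuration: nested defaults, YAML loading, dotted overrides.

Every tunable documented by the stage modules is reachable under a dotted
key (``quality.qd_min``, ``propagation.alpha``, ...).  Unknown keys are
rejected rather than ignored, and every run writes the fully resolved
config (defaults included) beside its outputs so a run is reproducible from
that artifact alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class InputsSection:
    vcf: str | None = None
    ped: str | None = None
    network: str | None = None
    seeds: str | None = None
    zygosity: str | None = None
    exclusions: str | None = None


@dataclass
class RelatednessSection:
    min_sites: int = 100
    flag_threshold: float = 0.5


@dataclass
class QualitySection:
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0


@dataclass
class FrequencySection:
    dbsnp_gmaf_max: float = 0.05
    kgp_gmaf_max: float = 0.02
    exac_maf_max: float = 0.05
    aj_maf_max: float = 0.05
    aj_rare_max: float = 0.001


@dataclass
class InheritanceSection:
    recessive_model: str = "strict"
    par_exclude: bool = False


@dataclass
class NetworkSection:
    threshold: float = 0.7
    case_insensitive_seeds: bool = False


@dataclass
class PropagationSection:
    alpha: float = 0.8
    tol: float = 1e-10
    max_iter: int = 10000
    normalization: str = "SYMMETRIC_DEGREE"


@dataclass
class SelectionSection:
    q: float = 0.10
    require_direct: bool = False


@dataclass
class PathogenicitySection:
    sift_max: float = 0.05
    polyphen_min: float = 0.447
    k: int = 2


@dataclass
class ReportSection:
    format: str = "TSV"


@dataclass
class SimulateSection:
    seed: int = 1
    n_autosomal_sites: int = 400
    n_x_sites: int = 120
    qc_fail_fraction: float = 0.10
    denovo_count: int = 2
    network_nodes: int = 200
    network_seeds: int = 20
    network_distractors: int = 4


@dataclass
class PipelineConfig:
    inputs: InputsSection = field(default_factory=InputsSection)
    output_dir: str = "trioprio_out"
    relatedness: RelatednessSection = field(default_factory=RelatednessSection)
    quality: QualitySection = field(default_factory=QualitySection)
    frequency: FrequencySection = field(default_factory=FrequencySection)
    inheritance: InheritanceSection = field(default_factory=InheritanceSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    propagation: PropagationSection = field(default_factory=PropagationSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    pathogenicity: PathogenicitySection = field(default_factory=PathogenicitySection)
    report: ReportSection = field(default_factory=ReportSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)

    def resolved_dict(self) -> dict:
        return asdict(self)

    def override(self, dotted_key: str, value: Any) -> None:
        """Set one dotted-key option (``quality.qd_min=1.5``), with type
        coercion to the default's type."""
        parts = dotted_key.split(".")
        obj: Any = self
        for p in parts[:-1]:
            if not hasattr(obj, p):
                raise KeyError(f"unknown config section {p!r} in {dotted_key!r}")
            obj = getattr(obj, p)
        leaf = parts[-1]
        if not is_dataclass(obj) or leaf not in {f.name for f in fields(obj)}:
            raise KeyError(f"unknown config key {dotted_key!r}")
        current = getattr(obj, leaf)
        if isinstance(current, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
        setattr(obj, leaf, value)


def _apply_section(section: Any, data: dict, path: str) -> None:
    valid = {f.name: f for f in fields(section)}
    for key, value in data.items():
        if key not in valid:
            raise KeyError(f"unknown config key {path}{key!r}")
        current = getattr(section, key)
        if is_dataclass(current):
            if not isinstance(value, dict):
                raise TypeError(f"config section {path}{key} must be a mapping")
            _apply_section(current, value, f"{path}{key}.")
        else:
            setattr(section, key, value)


def load_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or dict, rejecting unknown keys."""
    cfg = PipelineConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if data:
        _apply_section(cfg, data, "")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved config (all defaults expanded) as YAML."""
    Path(path).write_text(
        yaml.safe_dump(cfg.resolved_dict(), sort_keys=True, default_flow_style=False)
    )
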
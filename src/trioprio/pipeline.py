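"""End-to-end orchestration of the prioritization funnel.

Stage order (mirroring the two-branch filtering workflow): relatedness
check -> quality hard filters -> inheritance-mode partition -> SO-impact
selection -> panel frequency exclusions, then in parallel

* branch 1: rare-AJ selection -> network propagation and gene selection,
* branch 2: PDS calling -> top-k by combined pathogenic score,

followed by the workflow merge, the manual-review exclusion list, and
zygosity finalization into the ranked candidate report.  Every stage emits
a funnel record (input count, output count, thresholds used), and every run
echoes its fully resolved configuration next to the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import candidate_prioritization as cp
from . import io_formats, network_propagation as netprop, trio_filtering as tf
from .config import PipelineConfig, dump_config
from .impact import load_default_impact_table
from .models import AnnotatedVariant, InheritanceMode, VariantKey

logger = logging.getLogger(__name__)

__all__ = ["StageRecord", "FunnelSummary", "run_pipeline", "summarize_funnel", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)


@dataclass
class FunnelSummary:
    records: list[StageRecord] = field(default_factory=list)
    complete: bool = False

    def add(self, stage: str, n_in: int, n_out: int, **params) -> None:
        self.records.append(StageRecord(stage, n_in, n_out, params))


def _read_exclusions(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t", 1)
        out[parts[0]] = parts[1] if len(parts) > 1 else "manual review"
    return out


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> tuple[cp.CandidateReport, FunnelSummary]:
    """Execute the full funnel per the configuration.

    Writes report, funnel summary, and resolved config under
    ``config.output_dir`` (or ``outdir``).  Raises :class:`PipelineError`
    naming the failing stage; on failure the partial funnel summary is still
    written, flagged INCOMPLETE, and no final-looking report is left behind.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel = FunnelSummary()
    try:
        report = _run_stages(config, funnel)
        funnel.complete = True
    finally:
        summarize_funnel(funnel, outdir / "funnel")
        dump_config(config, outdir / "resolved_config.yaml")

    fmt = config.report.format.upper()
    cp.write_report(report, outdir / f"report.{fmt.lower()}", format=fmt)
    # the machine-readable twin is always written as well
    other = "JSON" if fmt == "TSV" else "TSV"
    cp.write_report(report, outdir / f"report.{other.lower()}", format=other)
    return report, funnel


def _stage(funnel: FunnelSummary, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def _run_stages(config: PipelineConfig, funnel: FunnelSummary) -> cp.CandidateReport:
    inp = config.inputs
    for req in ("vcf", "ped", "network", "seeds"):
        if getattr(inp, req) is None:
            raise PipelineError("inputs", ValueError(f"inputs.{req} is required"))

    with _stage(funnel, "ingest"):
        pedigree = io_formats.read_pedigree(inp.ped)
        variants = io_formats.read_trio_vcf(inp.vcf, pedigree)
        funnel.add("ingest", len(variants), len(variants), vcf=Path(inp.vcf).name)

    with _stage(funnel, "relatedness"):
        conc = tf.trio_concordance(
            variants,
            pedigree,
            min_sites=config.relatedness.min_sites,
            flag_threshold=config.relatedness.flag_threshold,
        )
        funnel.add(
            "relatedness",
            len(variants),
            len(variants),
            **{f"{a.value}-{b.value}": round(v, 4) for (a, b), v in conc.items()},
        )

    with _stage(funnel, "quality_filter"):
        qt = tf.QualityThresholds(
            mqranksum_min=config.quality.mqranksum_min,
            readposranksum_min=config.quality.readposranksum_min,
            qd_min=config.quality.qd_min,
            fs_max=config.quality.fs_max,
            mq_min=config.quality.mq_min,
        )
        passed, _failed = tf.apply_quality_filters(variants, qt)
        funnel.add("quality_filter", len(variants), len(passed), **vars(qt))

    with _stage(funnel, "inheritance_partition"):
        buckets = tf.partition_by_inheritance(
            passed,
            pedigree,
            recessive_model=config.inheritance.recessive_model,
            par_exclude=config.inheritance.par_exclude,
        )
        modes_by_key: dict[VariantKey, set[InheritanceMode]] = {}
        moded: list[AnnotatedVariant] = []
        seen: set[VariantKey] = set()
        for mode, vs in buckets.items():
            for v in vs:
                modes_by_key.setdefault(v.key, set()).add(mode)
                if v.key not in seen:
                    seen.add(v.key)
                    moded.append(v)
        funnel.add(
            "inheritance_partition",
            len(passed),
            len(moded),
            **{m.value: len(vs) for m, vs in buckets.items()},
        )

    with _stage(funnel, "impact_selection"):
        table = load_default_impact_table()
        impactful = tf.select_by_impact(moded, table)
        funnel.add("impact_selection", len(moded), len(impactful), allowed="HIGH,MODERATE")

    with _stage(funnel, "frequency_exclusion"):
        ft = tf.FrequencyThresholds(
            dbsnp_gmaf_max=config.frequency.dbsnp_gmaf_max,
            kgp_gmaf_max=config.frequency.kgp_gmaf_max,
            exac_maf_max=config.frequency.exac_maf_max,
            aj_maf_max=config.frequency.aj_maf_max,
            aj_rare_max=config.frequency.aj_rare_max,
        )
        rare = tf.apply_frequency_exclusions(impactful, ft)
        funnel.add("frequency_exclusion", len(impactful), len(rare), **vars(ft))

    # ---- branch 1: rare-AJ selection -> network support ----
    with _stage(funnel, "w1_rare_aj"):
        w1_input = tf.select_rare_aj(rare, ft)
        funnel.add("w1_rare_aj", len(rare), len(w1_input), aj_rare_max=ft.aj_rare_max)

    with _stage(funnel, "w1_network_selection"):
        network = io_formats.read_network(inp.network, weight_threshold=config.network.threshold)
        network = io_formats.read_seed_genes(
            inp.seeds, network, case_insensitive=config.network.case_insensitive_seeds
        )
        params = netprop.PropagationParams(
            alpha=config.propagation.alpha,
            tol=config.propagation.tol,
            max_iter=config.propagation.max_iter,
            normalization=netprop.Normalization(config.propagation.normalization),
        )
        gene_scores = netprop.compute_gene_scores(network, params)
        candidate_genes = {v.gene for v in w1_input if v.gene is not None}
        rule = netprop.SelectionRule(
            q=config.selection.q, require_direct=config.selection.require_direct
        )
        selected_genes, gene_flags = netprop.rank_candidate_genes(
            gene_scores, candidate_genes, rule
        )
        network_set = [v for v in w1_input if v.gene in selected_genes]
        for v in network_set:
            v.tag("NETWORK_SELECTED")
        funnel.add(
            "w1_network_selection",
            len(w1_input),
            len(network_set),
            q=rule.q,
            alpha=params.alpha,
            n_candidate_genes=len(candidate_genes),
            n_selected_genes=len(selected_genes),
        )

    # ---- branch 2: PDS calling -> top-k by combined pathogenic score ----
    with _stage(funnel, "w2_pds"):
        calls = cp.call_pds(
            rare,
            sift_max=config.pathogenicity.sift_max,
            polyphen_min=config.pathogenicity.polyphen_min,
        )
        by_key = {v.key: v for v in rare}
        n_pds = sum(1 for c in calls if c.is_pds)
        funnel.add(
            "w2_pds",
            len(rare),
            n_pds,
            sift_max=config.pathogenicity.sift_max,
            polyphen_min=config.pathogenicity.polyphen_min,
        )

    with _stage(funnel, "w2_top_k"):
        top = cp.select_top_pathogenic(calls, by_key, k=config.pathogenicity.k)
        pathogenicity_set = [by_key[c.variant_key] for c in top]
        funnel.add("w2_top_k", n_pds, len(pathogenicity_set), k=config.pathogenicity.k)

    with _stage(funnel, "merge"):
        candidates = cp.merge_workflows(
            network_set,
            pathogenicity_set,
            modes_by_key,
            gene_scores=gene_scores,
            path_calls={c.variant_key: c for c in calls},
        )
        funnel.add(
            "merge",
            len(network_set) + len(pathogenicity_set),
            len(candidates),
            network=len(network_set),
            pathogenicity=len(pathogenicity_set),
        )

    with _stage(funnel, "exclusion_list"):
        exclusions = _read_exclusions(inp.exclusions) if inp.exclusions else {}
        reviewed = cp.apply_exclusion_list(candidates, exclusions)
        funnel.add("exclusion_list", len(candidates), len(reviewed), n_listed=len(exclusions))

    with _stage(funnel, "zygosity_finalization"):
        observations = io_formats.read_zygosity_table(inp.zygosity) if inp.zygosity else []
        report = cp.finalize_by_zygosity(reviewed, observations, pedigree)
        funnel.add(
            "zygosity_finalization",
            len(reviewed),
            len(report.final_ranks),
            n_observations=len(observations),
        )
    return report


def summarize_funnel(funnel: FunnelSummary, basepath: str | Path) -> None:
    """Write the funnel summary as TSV and JSON (``<basepath>.tsv/.json``)."""
    basepath = Path(basepath)
    status = "COMPLETE" if funnel.complete else "INCOMPLETE"
    lines = [f"# funnel summary ({status})", "stage\tn_in\tn_out\tparams"]
    for r in funnel.records:
        params = ";".join(f"{k}={v}" for k, v in sorted(r.params.items()))
        lines.append(f"{r.stage}\t{r.n_in}\t{r.n_out}\t{params}")
    basepath.with_suffix(".tsv").write_text("\n".join(lines) + "\n")
    payload = {
        "status": status,
        "stages": [
            {"stage": r.stage, "n_in": r.n_in, "n_out": r.n_out, "params": r.params}
            for r in funnel.records
        ],
    }
    basepath.with_suffix(".json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
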
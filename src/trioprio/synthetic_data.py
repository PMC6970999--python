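"""Synthetic trio, network, and genotyping inputs with recorded ground truth.

The study whose workflow this package reimplements analyzed a single
male-proband trio whose raw WGS is not publicly deposited, so every pipeline
stage is exercised on simulated data instead: Mendelian-consistent trio
genotypes (Hardy-Weinberg parents, allele transmission to the proband,
haploid maternal X for a male proband), correlated per-panel allele
frequencies, QC-metric draws with a controlled violation fraction, SO
consequence labels, predictor scores, and a scale-free-ish weighted
interaction network with a designated seed set.

A causal variant is *planted* to mirror the headline case: X-linked,
hemizygous in the proband with a carrier mother, in a gene wired directly to
seed genes, with strongly damaging predictor scores but an Ashkenazi
frequency around 2% — common enough to fail the rare-variant workflow, so
recovery must come through the pathogenicity workflow.  Distractor genes are
placed at graph distance >= 3 from every seed.

All randomness flows from one seeded :class:`numpy.random.Generator` per
top-level call (sub-streams derive from ``(config.seed, domain-tag)``), so a
fixed config yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import write_network, write_pedigree, write_seed_list, write_trio_vcf, write_zygosity_table
from .models import (
    AnnotatedVariant,
    GeneNetwork,
    GenotypeCall,
    Role,
    Sex,
    TrioPedigree,
    Zygosity,
    ZygosityObservation,
)

__all__ = [
    "PlantedConfig",
    "NetworkSimConfig",
    "SimulationConfig",
    "simulate_network",
    "simulate_trio",
    "simulate_zygosity_table",
    "write_simulation",
    "check_mendelian",
]

_BASES = "ACGT"

# consequence vocabulary with draw weights; a deliberate mix of impact classes
_CONSEQUENCES = [
    ("missense_variant", 0.30),
    ("synonymous_variant", 0.22),
    ("intron_variant", 0.18),
    ("5_prime_UTR_variant", 0.10),
    ("splice_region_variant", 0.08),
    ("stop_gained", 0.05),
    ("splice_donor_variant", 0.04),
    ("frameshift_variant", 0.03),
]


@dataclass(frozen=True)
class PlantedConfig:
    """The injected causal variant, defaulting to the headline-case profile:
    X-linked hemizygous, carrier mother, AJ frequency ~2% (not rare),
    damaging predictor scores, gene adjacent to seeds."""

    gene: str = "PLANTED1"
    pos: int = 7_700_001
    aj_maf: float = 0.02
    other_maf: float = 0.0003
    sift: float = 0.01
    polyphen: float = 0.95
    consequence: str = "missense_variant"


@dataclass(frozen=True)
class NetworkSimConfig:
    """Scale-free network layout: a preferential-attachment core plus the
    planted gene (wired to seeds) and distractor genes hung on 2-filler
    chains so they sit >= 3 hops from every seed."""

    n_nodes: int = 200
    attachment_m: int = 2
    n_seeds: int = 20
    n_distractors: int = 4
    planted_seed_links: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_autosomal_sites: int = 400
    n_x_sites: int = 120
    af_shape: tuple[float, float] = (0.3, 2.5)
    qc_fail_fraction: float = 0.10
    denovo_count: int = 2
    planted: PlantedConfig = field(default_factory=PlantedConfig)
    network: NetworkSimConfig = field(default_factory=NetworkSimConfig)

    def __post_init__(self) -> None:
        if self.denovo_count > self.n_autosomal_sites:
            raise ValueError("denovo_count exceeds n_autosomal_sites")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        if self.network.n_nodes < self.network.n_seeds + self.network.n_distractors + 1:
            raise ValueError("network too small for seeds + distractors + planted gene")


def _rng(config: SimulationConfig, domain: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, domain])


def simulate_network(config: SimulationConfig) -> tuple[GeneNetwork, dict]:
    """Build the weighted network, seed set, and planted-gene map.

    Edge weights are drawn in (0.7, 1.0] so every simulated edge survives
    the default confidence threshold.  Returns the network (seeds attached)
    and a map recording the planted gene's seed links and the distractors.
    """
    rng = _rng(config, 1)
    net = config.network
    n_chain = 3 * net.n_distractors  # 2 fillers + 1 distractor each
    core_n = net.n_nodes - n_chain - 1  # minus planted gene
    if core_n < max(net.n_seeds + 1, net.attachment_m + 1):
        raise ValueError("network core too small for the requested seed set")

    g = nx.barabasi_albert_graph(core_n, net.attachment_m, seed=int(rng.integers(2**31)))
    name = {i: f"GN{i:04d}" for i in g.nodes}

    edges: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str) -> float:
        w = float(rng.uniform(0.701, 1.0))
        key = (a, b) if a < b else (b, a)
        edges[key] = w
        return w

    for u, v in sorted(g.edges):
        add_edge(name[u], name[v])

    core_names = [name[i] for i in sorted(g.nodes)]
    seeds = sorted(rng.choice(core_names, size=net.n_seeds, replace=False).tolist())
    nonseed_core = [n for n in core_names if n not in seeds]

    planted = config.planted.gene
    linked = rng.choice(seeds, size=net.planted_seed_links, replace=False).tolist()
    seed_links = {s: add_edge(planted, s) for s in sorted(linked)}

    distractors = [f"DIST{i:02d}" for i in range(net.n_distractors)]
    anchors = rng.choice(nonseed_core, size=net.n_distractors, replace=False).tolist()
    for i, (dist, anchor) in enumerate(zip(distractors, anchors)):
        f1, f2 = f"FILL{2 * i:02d}", f"FILL{2 * i + 1:02d}"
        add_edge(anchor, f1)
        add_edge(f1, f2)
        add_edge(f2, dist)

    nodes = {gnode for pair in edges for gnode in pair}
    network = GeneNetwork(nodes=nodes, edges=edges, seeds=set(seeds))

    # contract check: every distractor is >= 3 unweighted hops from all seeds
    gx = nx.Graph(list(edges))
    for dist in distractors:
        for s in seeds:
            try:
                d = nx.shortest_path_length(gx, dist, s)
            except nx.NetworkXNoPath:
                continue
            if d < 3:
                raise RuntimeError(f"distractor {dist} is {d} hops from seed {s}")

    planted_map = {
        "planted_gene": planted,
        "seed_links": seed_links,
        "distractors": distractors,
        "seeds": seeds,
    }
    return network, planted_map


def _draw_genotypes(
    rng: np.random.Generator, p: float, chrom: str
) -> dict[Role, GenotypeCall]:
    """HWE parents + Mendelian transmission; male proband is haploid on X."""
    mother = tuple(int(rng.random() < p) for _ in range(2))
    if chrom == "X":
        father = (int(rng.random() < p),)
        proband = (mother[int(rng.integers(2))],)
    else:
        father = tuple(int(rng.random() < p) for _ in range(2))
        proband = (mother[int(rng.integers(2))], father[int(rng.integers(2))])
    return {
        Role.PROBAND: GenotypeCall(alleles=proband),
        Role.MOTHER: GenotypeCall(alleles=mother),
        Role.FATHER: GenotypeCall(alleles=father),
    }


# passing draws are inclusive of the threshold (strict comparisons pass
# equality); violating draws sit strictly beyond it
_QC_PASS = {
    "QD": (2.0, 35.0),
    "FS": (0.0, 60.0),
    "MQ": (40.0, 60.0),
    "MQRankSum": (-12.5, 4.0),
    "ReadPosRankSum": (-8.0, 4.0),
}
_QC_FAIL = {
    "QD": (0.0, 1.999),
    "FS": (60.001, 400.0),
    "MQ": (10.0, 39.999),
    "MQRankSum": (-25.0, -12.501),
    "ReadPosRankSum": (-20.0, -8.001),
}


def _draw_qc(rng: np.random.Generator, fail: bool) -> tuple[dict[str, float], list[str]]:
    metrics = list(_QC_PASS)
    violated: list[str] = []
    if fail:
        k = int(rng.integers(1, 3))
        violated = sorted(rng.choice(metrics, size=k, replace=False).tolist())
    qc: dict[str, float] = {}
    for m in metrics:
        if m in violated:
            lo, hi = _QC_FAIL[m]
            qc[m] = round(float(rng.uniform(lo, hi)), 4)
        elif rng.random() < 0.05 and not violated:
            continue  # occasional absent metric, only at passing sites
        else:
            lo, hi = _QC_PASS[m]
            qc[m] = round(float(rng.uniform(lo, hi)), 4)
    return qc, violated


def _expected_modes(chrom: str, gts: dict[Role, GenotypeCall]) -> list[str]:
    """Generator-side mode expectation (kept independent of trio_filtering)."""
    pb, mo, fa = gts[Role.PROBAND], gts[Role.MOTHER], gts[Role.FATHER]
    modes = []
    if chrom == "X" and pb.has_alt and mo.has_alt and not fa.has_alt:
        modes.append("X_LINKED")
    if pb.has_alt and not mo.has_alt and not fa.has_alt:
        modes.append("DE_NOVO")
    if chrom != "X" and pb.is_hom_alt and mo.is_het and fa.is_het:
        modes.append("AUTOSOMAL_RECESSIVE")
    return modes


def simulate_trio(
    config: SimulationConfig,
) -> tuple[list[AnnotatedVariant], TrioPedigree, pd.DataFrame]:
    """Simulate the annotated trio VCF contents plus a per-site truth table.

    The truth table records, for every site, the drawn genotypes, whether a
    QC violation was injected (and which metrics), whether the site is an
    injected de novo, the generator's own mode expectation, and the
    planted/distractor labels — everything a test needs to recount a filter
    decision independently.
    """
    rng = _rng(config, 0)
    network, planted_map = simulate_network(config)
    pedigree = TrioPedigree(
        proband_id="PROBAND", mother_id="MOTHER", father_id="FATHER", proband_sex=Sex.MALE
    )

    background_genes = sorted(
        network.nodes
        - network.seeds
        - {config.planted.gene}
        - set(planted_map["distractors"])
    )
    offnet_genes = [f"OFFNET{i:02d}" for i in range(30)]

    chroms = [str(int(c)) for c in rng.integers(1, 23, size=config.n_autosomal_sites)]
    chroms += ["X"] * config.n_x_sites
    n_bg = len(chroms)

    denovo_idx = set(
        rng.choice(config.n_autosomal_sites, size=config.denovo_count, replace=False).tolist()
    ) if config.denovo_count else set()
    n_fail = int(round(config.qc_fail_fraction * n_bg))
    fail_idx = set(rng.choice(n_bg, size=n_fail, replace=False).tolist())

    cons_terms = [t for t, _ in _CONSEQUENCES]
    cons_w = np.array([w for _, w in _CONSEQUENCES])
    cons_w = cons_w / cons_w.sum()

    used_pos: dict[str, set[int]] = {}
    variants: list[AnnotatedVariant] = []
    truth_rows: list[dict] = []

    def fresh_pos(chrom: str) -> int:
        taken = used_pos.setdefault(chrom, set())
        while True:
            pos = int(rng.integers(10_000, 50_000_000))
            if pos not in taken:
                taken.add(pos)
                return pos

    def draw_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        return str(ref), str(alt)

    def panel_freqs(p: float) -> dict[str, float]:
        freqs = {}
        for panel in ("dbSNP_GMAF", "KGP_GMAF", "ExAC_MAF", "gnomAD_AJ_MAF"):
            if rng.random() < 0.10:
                continue  # panel has no record of this allele
            noisy = p * float(np.exp(rng.normal(0.0, 0.3)))
            freqs[panel] = round(min(max(noisy, 1e-06), 0.999), 6)
        return freqs

    for i, chrom in enumerate(chroms):
        p = float(rng.beta(*config.af_shape))
        p = min(max(p, 0.001), 0.999)
        gts = _draw_genotypes(rng, p, chrom)
        is_denovo = i in denovo_idx
        if is_denovo:
            gts = {
                Role.PROBAND: GenotypeCall(alleles=(0, 1)),
                Role.MOTHER: GenotypeCall(alleles=(0, 0)),
                Role.FATHER: GenotypeCall(alleles=(0, 0)),
            }
        qc, violated = _draw_qc(rng, i in fail_idx)
        ref, alt = draw_alleles()
        pos = fresh_pos(chrom)

        if rng.random() < 0.85:
            if rng.random() < 0.9:
                gene = background_genes[int(rng.integers(len(background_genes)))]
            else:
                gene = offnet_genes[int(rng.integers(len(offnet_genes)))]
        else:
            gene = None
        consequence = (
            str(rng.choice(cons_terms, p=cons_w)) if rng.random() < 0.95 else None
        )
        sift = round(float(rng.beta(2.0, 1.0)), 4) if rng.random() < 0.9 else None
        polyphen = round(float(rng.beta(1.0, 4.0)), 4) if rng.random() < 0.9 else None

        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=gts, qc=qc,
                gene=gene, consequence=consequence, freqs=panel_freqs(p),
                sift=sift, polyphen=polyphen,
            )
        )
        truth_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                "latent_af": round(p, 6),
                "gt_proband": gts[Role.PROBAND].gt_string(),
                "gt_mother": gts[Role.MOTHER].gt_string(),
                "gt_father": gts[Role.FATHER].gt_string(),
                "qc_fail": i in fail_idx,
                "qc_violated": "+".join(violated),
                "injected_denovo": is_denovo,
                "expected_modes": "+".join(_expected_modes(chrom, gts)),
                "label": "background",
            }
        )

    def inject(gene: str, *, aj: float, other: float, sift: float, polyphen: float,
               consequence: str, pos: int, label: str) -> None:
        gts = {
            Role.PROBAND: GenotypeCall(alleles=(1,)),
            Role.MOTHER: GenotypeCall(alleles=(0, 1)),
            Role.FATHER: GenotypeCall(alleles=(0,)),
        }
        qc, _ = _draw_qc(rng, False)
        ref, alt = draw_alleles()
        used_pos.setdefault("X", set()).add(pos)
        variants.append(
            AnnotatedVariant(
                chrom="X", pos=pos, ref=ref, alt=alt, genotypes=gts, qc=qc,
                gene=gene, consequence=consequence,
                freqs={
                    "dbSNP_GMAF": other, "KGP_GMAF": other,
                    "ExAC_MAF": other, "gnomAD_AJ_MAF": aj,
                },
                sift=sift, polyphen=polyphen,
            )
        )
        truth_rows.append(
            {
                "chrom": "X", "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                "latent_af": aj,
                "gt_proband": "1", "gt_mother": "0/1", "gt_father": "0",
                "qc_fail": False, "qc_violated": "",
                "injected_denovo": False,
                "expected_modes": "X_LINKED",
                "label": label,
            }
        )

    inject(
        config.planted.gene,
        aj=config.planted.aj_maf, other=config.planted.other_maf,
        sift=config.planted.sift, polyphen=config.planted.polyphen,
        consequence=config.planted.consequence,
        pos=config.planted.pos, label="planted",
    )
    for j, dist in enumerate(planted_map["distractors"]):
        inject(
            dist,
            aj=0.0001, other=0.0001,
            sift=round(float(rng.uniform(0.4, 0.9)), 4),
            polyphen=round(float(rng.uniform(0.0, 0.2)), 4),
            consequence="missense_variant",
            pos=config.planted.pos + 10_000 * (j + 1), label="distractor",
        )

    # stable VCF order: chromosome then position
    order = sorted(
        range(len(variants)),
        key=lambda k: (
            (0, int(variants[k].chrom)) if variants[k].chrom.isdigit() else (1, variants[k].chrom),
            variants[k].pos,
        ),
    )
    variants = [variants[k] for k in order]
    truth = pd.DataFrame([truth_rows[k] for k in order])
    return variants, pedigree, truth


def check_mendelian(truth: pd.DataFrame) -> int:
    """Independent Mendelian checker over a truth table.

    Returns the number of non-injected sites where a proband allele is not
    traceable to a parent (0 for a sound simulation).  Autosomes: one
    proband allele must come from each parent's allele set.  chrX (male):
    the single proband allele must appear in the mother's.
    """
    bad = 0
    for row in truth.itertuples():
        if row.injected_denovo:
            continue
        pb = [int(a) for a in str(row.gt_proband).replace("|", "/").split("/")]
        mo = {int(a) for a in str(row.gt_mother).replace("|", "/").split("/")}
        fa = {int(a) for a in str(row.gt_father).replace("|", "/").split("/")}
        if row.chrom == "X":
            if pb[0] not in mo:
                bad += 1
        else:
            a, b = pb
            if not ((a in mo and b in fa) or (a in fa and b in mo)):
                bad += 1
    return bad


def simulate_zygosity_table(
    truth: pd.DataFrame, false_positive_genes: set[str] | None = None
) -> list[ZygosityObservation]:
    """Orthogonal-genotyping observations consistent with the simulated
    genotypes, except genes listed as false positives read out WILD_TYPE."""
    false_positive_genes = false_positive_genes or set()
    known_genes = {g for g in truth["gene"] if isinstance(g, str)}
    unknown = false_positive_genes - known_genes
    if unknown:
        raise ValueError(f"false-positive genes not in simulation: {sorted(unknown)}")

    obs: list[ZygosityObservation] = []
    for row in truth.itertuples():
        gene = row.gene
        if not isinstance(gene, str):
            continue
        if gene in false_positive_genes:
            z = Zygosity.WILD_TYPE
        else:
            alleles = [int(a) for a in str(row.gt_proband).replace("|", "/").split("/")]
            if len(alleles) == 1:
                z = Zygosity.HEMIZYGOUS_ALT if alleles[0] == 1 else Zygosity.WILD_TYPE
            elif alleles == [1, 1]:
                z = Zygosity.HOMOZYGOUS_ALT
            elif 1 in alleles:
                z = Zygosity.HETEROZYGOUS
            else:
                z = Zygosity.WILD_TYPE
        obs.append(
            ZygosityObservation(
                gene=gene,
                variant_key=(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                observed=z,
            )
        )
    return obs


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    false_positive_genes: set[str] | None = None,
) -> dict[str, Path]:
    """Write the full simulated input bundle; returns the path map.

    Emits trio.vcf, trio.ped, network.tsv, seeds.txt, zygosity.tsv,
    truth.tsv (+ truth.json), and planted.json.  Byte-identical for a fixed
    config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, pedigree, truth = simulate_trio(config)
    network, planted_map = simulate_network(config)
    paths = {
        "vcf": outdir / "trio.vcf",
        "ped": outdir / "trio.ped",
        "network": outdir / "network.tsv",
        "seeds": outdir / "seeds.txt",
        "zygosity": outdir / "zygosity.tsv",
        "truth_tsv": outdir / "truth.tsv",
        "truth_json": outdir / "truth.json",
        "planted": outdir / "planted.json",
    }
    write_trio_vcf(variants, pedigree, paths["vcf"])
    write_pedigree(pedigree, paths["ped"])
    write_network(network, paths["network"])
    write_seed_list(network.seeds, paths["seeds"])
    write_zygosity_table(simulate_zygosity_table(truth, false_positive_genes), paths["zygosity"])
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    paths["truth_json"].write_text(
        json.dumps(truth.to_dict(orient="records"), indent=1, sort_keys=True) + "\n"
    )
    paths["planted"].write_text(json.dumps(planted_map, indent=1, sort_keys=True) + "\n")
    return paths
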
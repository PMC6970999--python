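from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pytest

from trioprio.models import (
    AnnotatedVariant,
    GeneNetwork,
    GenotypeCall,
    Role,
    Sex,
    TrioPedigree,
)

DATA_DIR = Path(__file__).parent / "data"

logging.getLogger("trioprio").setLevel(logging.ERROR)


def gt(spec: str) -> GenotypeCall:
    """Build a GenotypeCall from a compact string: '0/1', '1|0', '1', '.'."""
    if spec == ".":
        return GenotypeCall.missing()
    phased = "|" in spec
    alleles = tuple(int(a) for a in spec.replace("|", "/").split("/"))
    return GenotypeCall(alleles=alleles, phased=phased)


def make_variant(
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    proband="0/1",
    mother="0/0",
    father="0/0",
    **kwargs,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={
            Role.PROBAND: gt(proband),
            Role.MOTHER: gt(mother),
            Role.FATHER: gt(father),
        },
        **kwargs,
    )


@pytest.fixture
def pedigree() -> TrioPedigree:
    return TrioPedigree(
        proband_id="PROBAND",
        mother_id="MOTHER",
        father_id="FATHER",
        proband_sex=Sex.MALE,
    )


def random_network(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.2,
    n_seeds: int | None = None,
) -> GeneNetwork:
    """A random weighted graph with a nonempty random seed set."""
    names = [f"G{i:03d}" for i in range(n_nodes)]
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges[(names[i], names[j])] = float(rng.uniform(0.05, 1.0))
    if n_seeds is None:
        n_seeds = int(rng.integers(1, max(2, n_nodes // 4)))
    seeds = set(rng.choice(names, size=n_seeds, replace=False).tolist())
    return GeneNetwork(nodes=set(names), edges=edges, seeds=seeds)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One seeded end-to-end simulation bundle shared across tests."""
    from trioprio.synthetic_data import SimulationConfig, write_simulation

    outdir = tmp_path_factory.mktemp("demo")
    config = SimulationConfig(seed=11)
    paths = write_simulation(config, outdir)
    return config, paths


def pipeline_config_for(paths, output_dir) -> "PipelineConfig":
    from trioprio.config import load_config

    return load_config(
        data={
            "inputs": {
                "vcf": str(paths["vcf"]),
                "ped": str(paths["ped"]),
                "network": str(paths["network"]),
                "seeds": str(paths["seeds"]),
                "zygosity": str(paths["zygosity"]),
            },
            "output_dir": str(output_dir),
        }
    )
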
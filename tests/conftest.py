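import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from exocapkit.genome import GenomeAssembly
from exocapkit.simulate import SimConfig, make_annotation, make_genome
from exocapkit.targets import (
    build_target_set,
    merge_annotations,
    remove_contained_exons,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    genome, truth = make_genome(sim_config)
    return genome, truth


@pytest.fixture(scope="session")
def sim_annotation(sim_config, sim_genome):
    genome, truth = sim_genome
    refseq, ensembl, patched = make_annotation(
        sim_config, genome, np.random.default_rng(sim_config.seed + 1), truth
    )
    return refseq, ensembl, patched, truth


@pytest.fixture(scope="session")
def sim_target_set(sim_annotation):
    refseq, ensembl, genome, _ = sim_annotation
    exons = remove_contained_exons(merge_annotations(refseq, ensembl))
    return build_target_set(exons, genome=genome)


@pytest.fixture
def flat_genome():
    """A tiny handmade genome for coordinate-level tests."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return GenomeAssembly(name="flat", chromosomes={"chr1": seq, "chr2": seq[:3000]})
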
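"""Shared fixtures: crafted mini-genomes and a session-scoped default simulation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolsweep.io_formats import GeneModel, ReferenceGenome, reverse_complement
from poolsweep.synthetic_data import SimConfig, generate

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# 10 codons incl. start, Leu/Phe repeats (synonymous-rich third positions) and a stop
CDS_10 = "ATGAAACTTTTTGGATGCCGAGATAAATAA"


@pytest.fixture
def ref_small() -> ReferenceGenome:
    """120-bp chromosome with a plus-strand CDS at 11..40 and its reverse
    complement at 51..80, so the same codons can be read from either strand."""
    filler = "ACGTACGTAC"
    seq = filler + CDS_10 + filler + reverse_complement(CDS_10) + filler * 4
    assert len(seq) == 120
    return ReferenceGenome({"2L": seq})


@pytest.fixture
def gene_plus() -> GeneModel:
    return GeneModel("gplus", "2L", "+", [(11, 40)])


@pytest.fixture
def gene_minus() -> GeneModel:
    return GeneModel("gminus", "2L", "-", [(51, 80)])


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (5-Mbp arms, 200-fold sweep,
    implanted selected genes); shared across the slower statistical tests."""
    return generate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small on-disk simulation exercising the text formats end to end."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(
        seed=5,
        chrom_lengths={"2L": 150_000, "2R": 150_000},
        sweeps=[("2L", 40_000, 110_000, 200.0)],
    )
    return generate(cfg, outdir=outdir)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
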
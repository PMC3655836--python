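import numpy as np
import pytest

from chromotif.dcsr import DCSRPair
from chromotif.diploid_io import HetSNP

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_pair(
    seq_inaccessible: str,
    seq_accessible: str,
    center: int | None = None,
    chrom: str = "chr1",
    pos: int = 1000,
    kind: str = "DCSR",
    region: str = "intergenic",
    depth_high: int = 20,
    depth_low: int = 5,
) -> DCSRPair:
    """Build a DCSRPair from two windows differing at the center base."""
    if center is None:
        center = len(seq_accessible) // 2
    a, b = seq_accessible[center], seq_inaccessible[center]
    if a == b:  # HetSNP requires distinct alleles; pick any distinct pair
        a, b = "A", "C"
    return DCSRPair(
        snp=HetSNP(chrom, pos, a, b),
        seq_accessible=seq_accessible,
        seq_inaccessible=seq_inaccessible,
        accessible_allele="paternal",
        depth_high=depth_high,
        depth_low=depth_low,
        fold_change=depth_high / depth_low,
        region=region,
        kind=kind,
    )


def planted_pairs(rng, n_pairs=12, motif="CACGTG", flank=20):
    """Pairs whose accessible window contains the motif completed by the
    focal allele while the inaccessible allele breaks it."""
    pairs = []
    L = len(motif)
    width = 2 * flank + 1
    for i in range(n_pairs):
        base = list(random_dna(rng, width))
        offset = int(rng.integers(L))  # SNP at motif[offset]
        start = flank - offset
        acc = base.copy()
        for j, b in enumerate(motif):
            acc[start + j] = b
        inacc = acc.copy()
        broken = [b for b in BASES if b != motif[offset]][int(rng.integers(3))]
        inacc[flank] = broken
        pairs.append(
            make_pair("".join(inacc), "".join(acc), center=flank, pos=1000 + 100 * i)
        )
    return pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130508)


@pytest.fixture(scope="session")
def sim_null(tmp_path_factory):
    """Null simulated dataset: no planted motif, no depth effect."""
    from chromotif.simulate import SimConfig, simulate_dataset

    out = tmp_path_factory.mktemp("sim_null")
    cfg = SimConfig(seed=101, n_het_snps=600, planted_fraction=0.0, effect_fold=1.0)
    return cfg, simulate_dataset(cfg, out)


@pytest.fixture(scope="session")
def sim_planted(tmp_path_factory):
    """Simulated dataset with a strong planted CACGTG effect."""
    from chromotif.simulate import SimConfig, simulate_dataset

    out = tmp_path_factory.mktemp("sim_planted")
    cfg = SimConfig(
        seed=7, n_het_snps=800, planted_fraction=0.3, effect_fold=5.0
    )
    return cfg, simulate_dataset(cfg, out)


@pytest.fixture(scope="session")
def tfbs_fixture(tmp_path_factory):
    from chromotif.simulate import simulate_tfbs_fixture

    return simulate_tfbs_fixture(out_dir=tmp_path_factory.mktemp("tfbs"))
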
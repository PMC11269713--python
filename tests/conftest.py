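import numpy as np
import pytest

from hapsel.io_qc import GenotypeMatrix, HaplotypePanel, VariantSite


def make_sites(positions, chrom="1", ancestral="ref", info=None):
    return [
        VariantSite(
            chrom=chrom,
            pos=int(p),
            id=f"snp{i}",
            ref="A",
            alt="G",
            ancestral=ancestral,
            info=dict(info or {}),
        )
        for i, p in enumerate(positions)
    ]


def make_panel(haps, positions=None, ancestral="ref", population="TBP"):
    """Haplotype panel from a 2-D array; rows are haplotypes."""
    haps = np.asarray(haps, dtype=np.uint8)
    if positions is None:
        positions = 1000 * (1 + np.arange(haps.shape[1]))
    n = haps.shape[0] // 2
    samples = [f"s{i}" for i in range(n) for _ in range(2)]
    return HaplotypePanel(
        haplotypes=haps,
        sites=make_sites(positions, ancestral=ancestral),
        sample_of_haplotype=samples,
        population=population,
    )


def make_matrix(calls, positions=None):
    calls = np.asarray(calls, dtype=np.int8)
    if positions is None:
        positions = 1000 * (1 + np.arange(calls.shape[1]))
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(calls.shape[0])],
        sites=make_sites(positions),
        calls=calls,
    )


def random_panel(rng, n_hap=12, n_sites=10, ancestral="ref"):
    haps = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 500_000), size=n_sites, replace=False))
    return make_panel(haps, positions=positions, ancestral=ancestral)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
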
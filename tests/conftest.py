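import numpy as np
import pytest

from admixscan import genome_io, simulate
from admixscan.haplotypes import HaplotypeSet


def make_hapset(matrix, positions=None, chrom="toy"):
    """HaplotypeSet from a plain 0/1/-1 array (helper for hand-built cases)."""
    matrix = np.asarray(matrix, dtype=np.int8)
    if positions is None:
        positions = np.arange(matrix.shape[1]) * 1000
    ids = [f"h{i // 2}_{i % 2}" for i in range(matrix.shape[0])]
    return HaplotypeSet(chrom=chrom, positions=np.asarray(positions),
                        matrix=matrix, haplotype_ids=ids)


@pytest.fixture(scope="session")
def constant_model():
    return simulate.build_demography("constant", constant_size=10_000)


@pytest.fixture(scope="session")
def afro_model():
    return simulate.build_demography("afroasiatic")


@pytest.fixture(scope="session")
def gumuz_model():
    return simulate.build_demography("gumuz")


@pytest.fixture(scope="session")
def afro_sim_20mb(afro_model):
    """20 Mb admixed simulation with reference panels and truth tracts."""
    haps, tracts = simulate.simulate_neutral(
        afro_model, 48, 20_000_000, seed=907,
        extra_samples={"AFR": 24, "EUR": 24},
    )
    return haps, tracts


def split_panels(haps):
    """Split a joint simulation into (query, ref_afr, ref_wea) by prefix."""
    ids = np.array(haps.haplotype_ids)
    take = lambda p: haps.take_haplotypes(
        np.where(np.char.startswith(ids, p))[0])
    return take("ADM"), take("AFR_"), take("EUR_")


@pytest.fixture(scope="session")
def neutral_haps_5mb(gumuz_model):
    """One MAF-filtered neutral 5 Mb replicate of the unadmixed preset."""
    haps, _ = simulate.simulate_neutral(gumuz_model, 46, 5_000_000, seed=411)
    return genome_io.maf_filter(haps, 0.05)
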
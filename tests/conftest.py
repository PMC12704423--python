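import pytest

from oocyte_multiomics import datasets, methylome as me, proteomics as pr
from oocyte_multiomics import synthetic as sy


@pytest.fixture(scope="session")
def scmc_log():
    return pr.log2_transform(datasets.load_scmc_abundance())


@pytest.fixture(scope="session")
def epimod_log():
    return pr.log2_transform(datasets.load_epimod_abundance())


def small_methylome_spec(**overrides) -> sy.MethylomeSimSpec:
    """Desk-scale methylome spec: 2 autosomes + X, 4,000 CpGs each."""
    kw = dict(
        n_autosomes=2,
        cpg_per_chromosome=4_000,
        coverage_rate=6_000,
        n_cells_per_group=3,
        seed=11,
    )
    kw.update(overrides)
    return sy.MethylomeSimSpec(**kw)


@pytest.fixture(scope="session")
def meth_sim():
    """One shared default-condition simulation: cells, regions, tiles, truth."""
    spec = small_methylome_spec()
    cells, regions, truth = sy.simulate_methylomes(spec)
    tiles = me.build_tiles(spec.cpg_positions())
    return spec, cells, regions, tiles, truth
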
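import numpy as np
import pandas as pd
import pytest

from aipqtl.simulate import (
    FounderPanel,
    GeneticMap,
    PhenotypeModel,
    advance_generations,
    diallel_base_population,
    make_founder_panel,
)

ONE_CHROM = {"2L": (23_000_000, 55.0)}


@pytest.fixture(scope="session")
def small_panel() -> FounderPanel:
    """Six founders, 60 sites on one chromosome arm."""
    return make_founder_panel(6, 60, private_fraction=0.3, seed=11, chromosomes=ONE_CHROM)


@pytest.fixture(scope="session")
def aip(small_panel):
    """A small advanced intercross population: 25 generations at N=120."""
    base = diallel_base_population(small_panel, 120, seed=5)
    return advance_generations(base, 25, small_panel, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def manual_panel(genotypes: np.ndarray, positions=None, chrom="2L") -> FounderPanel:
    """Hand-built panel from an explicit (n_sites, n_lines) 0/1 matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_lines = genotypes.shape
    if positions is None:
        positions = (np.arange(n_sites) + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    gmap = GeneticMap(lengths_cm={chrom: 55.0}, lengths_bp={chrom: 23_000_000})
    return FounderPanel(
        line_ids=[f"L{i + 1:03d}" for i in range(n_lines)],
        sites=sites,
        genotypes=genotypes,
        genetic_map=gmap,
    )
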
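import numpy as np
import pandas as pd
import pytest

from beescape import Grid
from beescape.synthetic_data import ColonyTruth, ErrorModel, allele_frequencies, simulate_genotypes


@pytest.fixture(scope="session")
def grid3x3() -> Grid:
    return Grid(3, 3, 2000.0)


@pytest.fixture(scope="session")
def panel_freqs():
    """Allele frequencies for the 12-locus study-calibrated panel."""
    return allele_frequencies(seed=7)


def make_colonies(grid: Grid, n_colonies: int, workers_each: int = 5, kernel_m: float = 300.0):
    """Colonies at cell centers, cycling over the grid."""
    out = []
    for i in range(n_colonies):
        cell = i % grid.n_cells
        lon, lat = grid.cell_center_lonlat(cell)
        out.append(
            ColonyTruth(
                colony_id=f"c{i:05d}",
                true_lonlat=(float(lon), float(lat)),
                cell_id=cell,
                n_workers=workers_each,
                kernel_scale_m=kernel_m,
            )
        )
    return out


@pytest.fixture(scope="session")
def twenty_family_genotypes(grid3x3, panel_freqs):
    """20 full-sib families x 5 workers, 12 loci, 1% mistyping."""
    colonies = make_colonies(grid3x3, 20)
    geno = simulate_genotypes(colonies, panel_freqs, ErrorModel(0.0, 0.01), seed=11)
    truth = {f"c{i:05d}_w{j:02d}": i for i in range(20) for j in range(5)}
    return geno, truth


def labels_from_partition(partition, workers):
    of = {}
    for ci, cl in enumerate(partition.clusters):
        for w in cl:
            of[w] = ci
    return [of[w] for w in workers]


@pytest.fixture(scope="session")
def uniform_locus():
    """One locus, 4 equifrequent alleles."""
    return {"L1": pd.Series(np.full(4, 0.25), index=[100, 102, 104, 106])}


def genotype_frame(records):
    """records: list of (worker_id, locus, a1, a2)."""
    return pd.DataFrame(records, columns=["worker_id", "locus", "allele1_bp", "allele2_bp"])
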
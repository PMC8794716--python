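import numpy as np
import pandas as pd
import pytest

from gnis.dataset import MISSING, SnpDataset


def make_dataset(
    genotypes,
    coords=None,
    contigs=None,
    positions=None,
    repro=None,
    sexes=None,
) -> SnpDataset:
    """Small-dataset builder with sensible metadata defaults."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, L = geno.shape
    if coords is None:
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    coords = np.asarray(coords, dtype=float)
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j}" for j in range(L)],
            "contig_id": contigs if contigs is not None else [f"c{j}" for j in range(L)],
            "position_in_contig": positions if positions is not None else [1] * L,
            "reproducibility": repro if repro is not None else [0.99] * L,
        }
    )
    individuals = pd.DataFrame(
        {
            "individual_id": [f"i{i}" for i in range(n)],
            "sex": sexes if sexes is not None else ["unknown"] * n,
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
    return SnpDataset(geno, loci, individuals)


def random_dataset(rng, n=20, n_loci=50, missing_rate=0.1) -> SnpDataset:
    """Random dataset with missingness, guaranteed at least one call per locus."""
    geno = rng.integers(0, 3, size=(n, n_loci)).astype(np.int8)
    mask = rng.random((n, n_loci)) < missing_rate
    mask[0] = False  # keep every locus observed at least once
    geno[mask] = MISSING
    coords = rng.uniform(0, 1000, size=(n, 2))
    return make_dataset(geno, coords=coords)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ibd_population():
    """Spatially structured population reused by the heavier tests."""
    from gnis.synthetic import PopulationSpec, generate_population

    spec = PopulationSpec(
        n_individuals=150,
        n_loci=600,
        n_contigs=450,
        target_he=0.28,
        target_fis=0.125,
        spatial_extent=2000.0,
        ibd_range=250.0,
        ibd_sigma=0.8,
        seed=11,
    )
    return generate_population(spec)
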
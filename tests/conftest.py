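import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from landgen import genotype as gt
from landgen import synthetic as syn
from landgen.core import PairwiseMatrix


def random_pairwise(n: int, rng, kind: str = "distance") -> PairwiseMatrix:
    """Random symmetric zero-diagonal matrix with distinct labels."""
    return PairwiseMatrix(
        labels=[f"P{i:02d}" for i in range(n)],
        values=squareform(rng.random(n * (n - 1) // 2)),
        kind=kind,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset reused across read-only tests.

    8 populations x 5 individuals x 400 loci on a 30x30 grid — enough
    structure for every downstream stage without slowing the suite.
    """
    cfg = syn.SyntheticConfig(
        n_pops=8, n_ind_per_pop=5, n_loci=400, grid_shape=(30, 30), seed=42
    )
    env_rasters, suit = syn.generate_env_rasters(cfg)
    pops = syn.place_populations(cfg, suit)
    env_values = syn.extract_env_values(pops, env_rasters)
    truth = syn.simulate_allele_frequencies(pops, env_values, cfg)
    gm = syn.simulate_genotypes(truth, cfg)
    assignment = syn.population_assignment(truth, cfg)
    return {
        "config": cfg,
        "env_rasters": env_rasters,
        "suitability": suit,
        "pop_table": pops,
        "env_values": env_values,
        "truth": truth,
        "genotypes": gm,
        "assignment": assignment,
    }


@pytest.fixture(scope="session")
def small_fst(small_dataset):
    gmf = gt.filter_snps(small_dataset["genotypes"])
    return gt.fst_matrix(gmf, small_dataset["assignment"])


def toy_genotypes(dosage, quals=None, positions=None) -> gt.GenotypeMatrix:
    """GenotypeMatrix from a plain (n_ind, n_loci) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_loci = dosage.shape
    loci = pd.DataFrame({
        "chrom": ["1"] * n_loci,
        "pos": positions if positions is not None else np.arange(1, n_loci + 1),
        "qual": quals if quals is not None else [50.0] * n_loci,
        "ref": ["A"] * n_loci,
        "alt": ["G"] * n_loci,
    })
    return gt.GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(n_ind)], loci=loci, dosage=dosage
    )
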
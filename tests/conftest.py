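import numpy as np
import pandas as pd
import pytest

from methylinta import synthetic_data as sd
from methylinta.methylation_diff import MethylTable


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(
        seed=42,
        n_chroms=2,
        chrom_length_bp=120_000,
        n_genes=8,
        n_samples=3,
        planted_dmrs=[
            sd.PlantedDmr(
                context="CG", feature="exon", delta=0.35,
                affected_samples=("Root",),
            )
        ],
        planted_dem=[
            sd.PlantedDem(
                n_genes=2, logfc=2.0, methyl_delta=0.3,
                context="CG", feature="exon",
                affected_samples=("Root",),
            )
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """A complete simulated dataset on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    paths = sd.simulate_all(small_config, str(outdir))
    return small_config, paths


@pytest.fixture(scope="session")
def gene_models(small_config):
    seqs, models, truth = sd.simulate_genome(small_config)
    return seqs, models, truth


def make_methyl_table(positions, meth, total, context="CG", chrom="chr1",
                      samples=None):
    """Hand-built MethylTable for targeted tests."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    if meth.shape[0] != len(positions):
        meth, total = meth.T, total.T
    n_samp = meth.shape[1]
    samples = samples or [chr(ord("A") + i) for i in range(n_samp)]
    ctx = [context] * len(positions) if isinstance(context, str) else context
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "strand": "+", "context": ctx}
    )
    return MethylTable(sites, samples, meth.astype(np.int64),
                       total.astype(np.int64))
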
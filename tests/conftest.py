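import pandas as pd
import pytest

from dmrpipe.io import MethylomeSample
from dmrpipe.simulate import (
    SimConfig,
    simulate_genome,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete synthetic study shared across test modules."""
    config = SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length_bp=400_000,
        n_genes=40,
        n_te_genes=12,
        n_planted_dmrs={"CG": 12, "CHG": 8, "CHH": 8},
        n_callus_hyper=10,
    )
    genome, genes, chrom_sizes, organelle = simulate_genome(config)
    samples, truth = simulate_methylomes(genome, genes, chrom_sizes, config)
    nuclear = {c: s for c, s in chrom_sizes.items() if c not in organelle}
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "nuclear": nuclear,
        "organelle": organelle,
        "samples": samples,
        "truth": truth,
    }


def make_sample(rows, sample_id="s", organelle=()):
    """MethylomeSample from (chrom, pos, strand, context, n_meth, n_total) rows."""
    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return MethylomeSample(sample_id, calls, frozenset(organelle))


@pytest.fixture
def sample_factory():
    return make_sample
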
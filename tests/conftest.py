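import numpy as np
import pytest

from pascape import pipeline, synthetic


@pytest.fixture(scope="session")
def sim_bundle():
    """A small simulated genome with ground truth (8 genes, both strands)."""
    genome, genes, truth = synthetic.simulate_genome(n_genes=8, seed=11)
    return genome, genes, truth


@pytest.fixture(scope="session")
def mace_libraries(sim_bundle):
    """Two conditions x two replicates of MACE-like libraries with 30%
    internal-priming reads and PCR duplicates."""
    genome, genes, truth = sim_bundle
    rng = np.random.default_rng(11)
    libs, cmap = {}, {}
    for cond in ("control", "knockdown"):
        for rep in (1, 2):
            sample = f"{cond}_{rep}"
            libs[sample] = synthetic.simulate_mace_reads(
                genome,
                truth,
                reads_per_pas=30,
                cleavage_jitter_sd=1.0,
                internal_priming_fraction=0.3,
                duplicate_rate=0.1,
                sample_id=sample,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            cmap[sample] = cond
    return libs, cmap


@pytest.fixture(scope="session")
def call_result(sim_bundle, mace_libraries):
    """Full PAS calling on the simulated libraries."""
    genome, genes, truth = sim_bundle
    libs, cmap = mace_libraries
    return pipeline.call_pas_from_libraries(genome, genes, libs, cmap)
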
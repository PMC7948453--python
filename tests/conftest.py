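import numpy as np
import pytest

from polwave.io import GenomeAssembly, StrandedCoverage
from polwave.simulate import SimConfig, build_genome, simulate_fp_washout


@pytest.fixture
def assembly():
    return GenomeAssembly({"chrS": 100_000})


@pytest.fixture
def coverage(assembly):
    return StrandedCoverage.zeros(assembly, bin_size=50)


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale study conditions for fast pipeline-level tests."""
    return SimConfig(
        n_genes=160,
        n_chroms=2,
        chrom_length=2_000_000,
        gene_length_log_mean=np.log(12_000.0),
        n_enhancers=40,
        n_se_clusters=2,
        n_intragenic_enhancers=8,
        n_perturbed_enhancers=12,
    )


@pytest.fixture(scope="session")
def washout_study():
    """The reference washout experiment at default study conditions:
    duplicate simulated experiments on one genome, seed-fixed."""
    config = SimConfig()
    genome = build_genome(config, seed=1)
    replicates = []
    for rep in range(2):
        tracks, _ = simulate_fp_washout(genome, config, seed=100 + rep,
                                        conditions=("wt",))
        replicates.append(tracks)
    return {"config": config, "genome": genome, "replicates": replicates}
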
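import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clonalsig.genio import GenotypeMatrix
from clonalsig.synthpop import SimConfig, simulate

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_matrix(dosage, contig="c1", start=100, step=100):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, S = dosage.shape
    sites = pd.DataFrame({
        "contig": contig,
        "pos": start + step * np.arange(S),
        "ref": ["A"] * S, "alt": ["T"] * S})
    return GenotypeMatrix(samples=[f"s{i + 1}" for i in range(n)],
                          sites=sites, dosage=dosage)


@pytest.fixture(scope="session")
def hybrid_sim():
    """Shared small hybrid-origin, mostly-clonal simulation with coding genes."""
    cfg = SimConfig(seed=1, genome_length=150_000, n_contigs=10,
                    generations=20)
    return simulate(cfg)


@pytest.fixture(scope="session")
def panmictic_sim():
    """Shared small sexual panmictic simulation (single deme, labels only)."""
    cfg = SimConfig(seed=2, founder_mode="panmictic", clonality=0.0,
                    rec_rate=1e-6, n_groups=1, pops_per_group=(4,),
                    individuals_per_pop=6, genome_length=150_000,
                    n_contigs=10, founder_diversity=0.005, generations=10,
                    pop_split_gen=0, cds_fraction=0.2)
    return simulate(cfg)
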
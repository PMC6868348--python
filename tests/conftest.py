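import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinseq import (GeneticMapConfig, gene_drop, make_panel, pedigree_preset,
                    simulate_founder_haplotypes)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_GENOME = {"chr1": 20_000_000, "chr2": 20_000_000}


@pytest.fixture(scope="session")
def small_panel():
    """120-site two-chromosome panel with a uniform MAF spectrum."""
    return make_panel(30, 4, SMALL_GENOME, maf_law=("uniform", 0.1, 0.5), seed=7)


@pytest.fixture(scope="session")
def trio_haps(small_panel):
    ped = pedigree_preset("trio")
    founders = simulate_founder_haplotypes(small_panel, ped.founders, seed=11)
    gmap = GeneticMapConfig(1.0, small_panel.chrom_lengths)
    return ped, gene_drop(ped, founders, gmap, small_panel, seed=13)
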
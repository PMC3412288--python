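import numpy as np
import pytest

import lassogene as lg
from lassogene.simulate import gene_map_rows


@pytest.fixture(scope="session")
def small_cohort():
    """200 subjects, 3 genes of 8 SNPs, one gene with two causal SNPs."""
    cfg = lg.SimConfig(
        seed=42,
        n_subjects=200,
        genes=[("G01", 8), ("G02", 8), ("G03", 8)],
        causal=[("G01", 0, 0.5), ("G01", 3, 0.4)],
    )
    G = lg.simulate_genotypes(cfg)
    P, _ = lg.simulate_phenotype(G, cfg)
    gm = lg.GeneMap(assignments=gene_map_rows(cfg))
    return cfg, G, gm, P


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
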
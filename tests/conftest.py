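import numpy as np
import pandas as pd
import pytest

import halfsibgs as h


@pytest.fixture(scope="session")
def small_trial():
    """10 families x 2 sites x 6 trees, 600 SNPs, 30% missing."""
    cfg = h.SimConfig(
        n_families=10,
        n_offspring_per_family_site=6,
        n_sites=2,
        n_blocks_per_site=3,
        n_snps=600,
        n_qtl=60,
        h2_target=0.5,
        seed=11,
    )
    ped, geno, masked, mask, pheno, truth = h.simulate_trial(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "genotypes": geno,
        "masked": masked,
        "mask": mask,
        "phenotypes": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def family_panel():
    """Single-site half-sib panel with strong family structure, no missing."""
    cfg = h.SimConfig(
        n_families=20,
        n_offspring_per_family_site=25,
        n_sites=1,
        n_blocks_per_site=1,
        n_snps=1000,
        n_qtl=100,
        h2_target=0.5,
        block_var_fraction=0.0,
        missing_rate=0.0,
        seed=21,
    )
    ped = h.simulate_pedigree(cfg)
    geno = h.simulate_genotypes(ped, cfg)
    pheno, truth = h.simulate_phenotypes(geno, ped, cfg, traits=("HT",))
    return {"config": cfg, "pedigree": ped, "genotypes": geno,
            "phenotypes": pheno, "truth": truth}


@pytest.fixture
def toy_genotypes():
    values = np.array(
        [
            [-1.0, 0.0, 1.0, np.nan],
            [0.0, 0.0, -1.0, 1.0],
            [1.0, np.nan, 0.0, -1.0],
        ]
    )
    return h.GenotypeMatrix(
        values,
        ["a", "b", "c"],
        ["s1", "s2", "s3", "s4"],
        ["fam1", "fam1", "fam2"],
    )
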
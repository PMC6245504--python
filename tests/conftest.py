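import numpy as np
import pandas as pd
import pytest

import gxetwin as gx


@pytest.fixture(scope="session")
def lms_ref():
    return gx.synthetic_lms_reference()


@pytest.fixture(scope="session")
def small_model():
    """Desk-scale calibrated cohort: all zygosity groups, tiny SNP panel."""
    return gx.calibrated_model(seed=42, n_mz_pairs=60, n_dz_ss_pairs=50,
                               n_dz_os_pairs=40, n_unrelated=120,
                               n_snps=300, n_causal=30, ld_block_size=3)


@pytest.fixture(scope="session")
def small_cohort(small_model):
    tables, panel, geno = gx.simulate_cohort(small_model)
    return {"tables": tables, "panel": panel, "geno": geno,
            "model": small_model}


@pytest.fixture()
def toy_sumstats():
    """Five SNPs on two chromosomes with fixed effects for hand-checking."""
    return pd.DataFrame({
        "SNP": ["s1", "s2", "s3", "s4", "s5"],
        "CHR": [1, 1, 1, 2, 2],
        "BP": [1000, 2000, 300000, 1000, 2000],
        "A1": ["A", "C", "G", "T", "A"],
        "A2": ["G", "T", "A", "C", "G"],
        "FREQ": [0.3, 0.5, 0.2, 0.4, 0.6],
        "BETA": [0.1, -0.2, 0.05, 0.3, -0.1],
        "SE": [0.01, 0.01, 0.01, 0.01, 0.01],
        "P": [1e-8, 1e-4, 0.02, 0.2, 0.6],
    })


@pytest.fixture()
def toy_dosages():
    rng = np.random.default_rng(7)
    mat = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
    return pd.DataFrame(mat, columns=["s1", "s2", "s3", "s4", "s5"],
                        index=pd.Index([f"i{k}" for k in range(30)],
                                       name="individual_id"))
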
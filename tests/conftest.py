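import numpy as np
import pandas as pd
import pytest

import pleiopc as p


@pytest.fixture(scope="session")
def small_model():
    return p.generate_model(
        n_traits=6, n_snps=300, n_components=2, scales=(8.0, 6.0), seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_model):
    return p.generate_sumstats(small_model, noise_sd=1.0, seed=12)


@pytest.fixture(scope="session")
def small_decomposition(small_study):
    from pleiopc.synthetic import observed_zmatrix

    return p.svd_decompose(observed_zmatrix(small_study))


@pytest.fixture()
def panel3():
    """Tiny reference panel with three unambiguous SNPs."""
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "allele1": ["A", "T", "C"],
            "allele2": ["G", "C", "A"],
            "chrom": ["1", "1", "2"],
            "pos": [1000, 2000, 1500],
        }
    )


def make_records(rows):
    """Build a canonical sumstats frame from (snp_id, ea, oa, beta, se, p, eaf)."""
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "effect_allele", "other_allele", "beta", "se", "p_value", "eaf"],
    )
    df["chrom"] = "1"
    df["pos"] = np.arange(1, len(df) + 1) * 1000
    df["n_case"] = 1000
    df["n_control"] = 1000
    from pleiopc.sumstats import SUMSTATS_COLUMNS

    return df[SUMSTATS_COLUMNS]
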
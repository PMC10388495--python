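import numpy as np
import pandas as pd
import pytest

from mrkit.gwas_io import SCHEMA, SummaryDataset
from mrkit.instruments import HarmonizedSet


def make_dataset(
    snp_ids,
    beta,
    se,
    pvalue=None,
    chrom=None,
    pos=None,
    ea="A",
    oa="G",
    eaf=0.3,
    n=10_000,
    trait_name="trait",
    trait_type="quantitative",
):
    """Build a SummaryDataset from parallel arrays with sensible defaults."""
    j = len(snp_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pvalue is None:
        from scipy import stats

        pvalue = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    tab = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom if chrom is not None else ["1"] * j,
            "pos": pos if pos is not None else (np.arange(j) * 20_000_000 + 1),
            "effect_allele": ea if not isinstance(ea, str) else [ea] * j,
            "other_allele": oa if not isinstance(oa, str) else [oa] * j,
            "eaf": eaf if not isinstance(eaf, float) else [eaf] * j,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": float(n),
        }
    )[SCHEMA]
    return SummaryDataset(trait_name, trait_type, tab)


def make_harmonized(gamma, Gamma, se_gamma=None, se_Gamma=None, eaf=None):
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    j = len(gamma)
    return HarmonizedSet(
        snp_ids=np.array([f"rs{i}" for i in range(j)]),
        gamma=gamma,
        se_gamma=np.full(j, 0.01) if se_gamma is None else np.asarray(se_gamma, float),
        Gamma=Gamma,
        se_Gamma=np.full(j, 0.05) if se_Gamma is None else np.asarray(se_Gamma, float),
        eaf=np.full(j, 0.3) if eaf is None else np.asarray(eaf, float),
    )


def random_harmonized(rng, j=20):
    """A generic random harmonized set for oracle-equivalence checks."""
    return make_harmonized(
        gamma=rng.uniform(0.02, 0.2, j) * rng.choice([-1, 1], j),
        Gamma=rng.normal(0, 0.1, j),
        se_gamma=rng.uniform(0.005, 0.02, j),
        se_Gamma=rng.uniform(0.01, 0.08, j),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_harmonized():
    rng = np.random.default_rng(7)
    j = 30
    gamma = rng.uniform(0.05, 0.15, j)
    se_g = np.full(j, 0.005)
    se_G = np.full(j, 0.02)
    Gamma = 0.5 * gamma + se_G * rng.standard_normal(j)
    return make_harmonized(gamma, Gamma, se_g, se_G)
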
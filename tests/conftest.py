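import numpy as np
import pandas as pd
import pytest

from panmix.vcf_io import GenotypeMatrix


def make_gm(genotypes, chrom=None, ids=None, colony=None, lat=None, lon=None,
            age=None, year=None, gq=None, dp=None, biallelic=None):
    """GenotypeMatrix from a raw array with minimal plausible metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, s = genotypes.shape
    if chrom is None:
        chrom = [f"locus_{j:05d}" for j in range(s)]
    site = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, s + 1) if len(set(chrom)) == s else 1,
            "ref": "A",
            "alt": "T",
            "biallelic_snp": True if biallelic is None else biallelic,
        }
    )
    sample = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"ind_{i:04d}" for i in range(n)],
            "colony": colony if colony is not None else "colony_00",
            "lat": lat if lat is not None else 38.0,
            "lon": lon if lon is not None else -121.0,
            "age_class": age if age is not None else "adult",
            "year": year if year is not None else 2017,
        }
    )
    return GenotypeMatrix(genotypes, site, sample, gq=gq, dp=dp)


def hwe_genotypes(rng, n, s, p_low=0.05, p_high=0.5):
    """Independent Hardy-Weinberg genotypes (the panmictic null)."""
    p = rng.uniform(p_low, p_high, s)
    return rng.binomial(2, p, size=(n, s)).astype(np.int8)


@pytest.fixture(scope="session")
def panmictic_gm():
    """Constant-size coalescent dataset: 40 diploids, ~1.4k RAD SNPs."""
    from panmix.synthetic_data import SimConfig, simulate_coalescent_dataset

    cfg = SimConfig(
        epochs=((20_000, 0),), n_loci=8000, n_diploids=40, missing_rate=0.0,
        seed=11, n_colonies=6,
    )
    return simulate_coalescent_dataset(cfg)
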
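"""Contemporary effective population size from linkage disequilibrium.

Among physically unlinked loci, genetic drift in a finite population
generates a small excess of squared allele-frequency correlation (r^2)
over the pure sampling expectation; the excess is ~1/(3 Ne) under random
mating.  The estimator here is the standard large-sample LD method:
Burrows' composite disequilibrium from unphased genotypes, the sampling
component ``1/S + 3.19/S^2`` for S >= 30 individuals, and the
bias-corrected quadratic root

    Ne_hat = (1/3 + sqrt(1/9 - 2.76 r2_drift)) / (2 r2_drift).

Pairs of SNPs must lie on different loci/chromosome labels (the
"unlinked" proxy for scattered RAD loci); missing data are handled
per pair (pairwise-complete individuals), with S the harmonic mean of
per-pair sample sizes.  Confidence intervals are a delete-one-locus
jackknife on the mean r^2.  Samples with fewer than 30 individuals are
rejected: the small-S bias corrections are different and not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcf_io import GenotypeMatrix


@dataclass
class LDNeResult:
    ne_hat: float
    ci_low: float
    ci_high: float
    mean_r2: float
    r2_drift: float
    r2_sample_expectation: float
    s_harmonic: float
    n_snps: int
    n_pairs: int
    maf_cutoff: float


def select_adults(gm: GenotypeMatrix, years=(2017, 2018)) -> GenotypeMatrix:
    """Keep adults from the configured sampling years.

    Mixed-age, mixed-cohort samples bias LD-based Ne through overlapping
    generations, so nestlings and older collection years are excluded.
    """
    meta = gm.sample_meta
    keep = (meta["age_class"] == "adult") & meta["year"].isin(list(years))
    if not keep.any():
        raise ValueError("no adults in the requested years")
    return gm.take_individuals(np.flatnonzero(keep.to_numpy()))


def _waples_ne(r2_drift: float) -> float:
    if r2_drift <= 0:
        return np.inf
    disc = 1.0 / 9.0 - 2.76 * r2_drift
    if disc < 0:
        warnings.warn("negative discriminant in Ne estimator; reporting inf")
        return np.inf
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)


def ld_ne(
    gm: GenotypeMatrix,
    maf: float = 0.01,
    n_snps: int | None = None,
    seed: int = 0,
    min_pair_n: int = 10,
) -> LDNeResult:
    """LD-method Ne from unlinked-SNP pairs at a MAF cutoff.

    ``n_snps`` randomly subsamples the eligible SNPs first (the
    reduced-representation sensitivity analysis); pair weights are the
    per-pair called sample sizes.
    """
    if gm.n_individuals < 30:
        raise ValueError("LD-Ne large-sample branch requires >= 30 individuals")
    keep = np.nan_to_num(gm.minor_allele_freq(), nan=0.0) >= maf
    gm = gm.take_sites(np.flatnonzero(keep))
    if n_snps is not None:
        if n_snps > gm.n_sites:
            raise ValueError("requested more SNPs than available")
        rng = np.random.default_rng(seed)
        gm = gm.take_sites(np.sort(rng.permutation(gm.n_sites)[:n_snps]))
    L = gm.n_sites
    loci = pd.factorize(gm.site_meta["chrom"])[0]
    if len(np.unique(loci)) < 2:
        raise ValueError("need SNPs on at least two loci/chromosomes")

    G = gm.genotypes.astype(np.float64)
    V = gm.called.astype(np.float64)
    Gz = np.where(gm.called, G, 0.0)
    homalt = (gm.genotypes == 2).astype(np.float64)

    n_pair = V.T @ V
    sx = Gz.T @ V  # sum of X over individuals where the partner is called
    sxy = Gz.T @ Gz
    saa = homalt.T @ V  # hom-ALT count over pairwise-complete individuals

    with np.errstate(invalid="ignore", divide="ignore"):
        # Burrows composite Delta with the n/(n-1) sample-size adjustment,
        # normalized by Weir's p(1-p) + D_A terms (D_A the within-locus
        # Hardy-Weinberg departure), the composite-r^2 form whose null
        # sampling expectation the 1/S + 3.19/S^2 term was calibrated for
        cov = (sxy - sx * sx.T / n_pair) / (n_pair - 1)
        delta = cov / 2.0
        p = sx / (2.0 * n_pair)  # pairwise-complete ALT freq of row SNP
        varp = p * (1 - p) + (saa / n_pair - p**2)
        r2 = delta**2 / (varp * varp.T)

    unlinked = loci[:, None] != loci[None, :]
    ok = (
        unlinked
        & (n_pair >= min_pair_n)
        & np.isfinite(r2)
        & (varp > 0)
        & (varp.T > 0)
    )
    iu = np.triu_indices(L, k=1)
    sel = ok[iu]
    if sel.sum() < 1:
        raise ValueError("no eligible unlinked SNP pairs")
    r2_pairs = r2[iu][sel]
    w = n_pair[iu][sel]
    rows = iu[0][sel]
    cols = iu[1][sel]

    mean_r2 = float(np.sum(w * r2_pairs) / np.sum(w))
    s_harm = float(len(w) / np.sum(1.0 / w))
    expectation = 1.0 / s_harm + 3.19 / s_harm**2
    r2_drift = mean_r2 - expectation
    ne_hat = _waples_ne(r2_drift)

    # delete-one-locus jackknife on the weighted mean r^2
    num_tot = np.sum(w * r2_pairs)
    den_tot = np.sum(w)
    pair_locus_a = loci[rows]
    pair_locus_b = loci[cols]
    jack = []
    for locus in np.unique(loci):
        touch = (pair_locus_a == locus) | (pair_locus_b == locus)
        den = den_tot - np.sum(w[touch])
        if den <= 0:
            continue
        jack.append((num_tot - np.sum(w[touch] * r2_pairs[touch])) / den)
    jack = np.asarray(jack)
    if len(jack) > 1:
        g = len(jack)
        se = np.sqrt((g - 1) / g * np.sum((jack - jack.mean()) ** 2))
        lo, hi = mean_r2 - 1.96 * se, mean_r2 + 1.96 * se
        ci_high = _waples_ne(lo - expectation)  # smaller r2 -> larger Ne
        ci_low = _waples_ne(hi - expectation)
    else:
        ci_low, ci_high = np.nan, np.nan
    return LDNeResult(
        ne_hat,
        float(ci_low),
        float(ci_high),
        mean_r2,
        float(r2_drift),
        float(expectation),
        s_harm,
        L,
        int(sel.sum()),
        maf,
    )


def ne_vs_nsnps(
    gm: GenotypeMatrix, snp_counts, seed: int = 0, maf: float = 0.01
) -> pd.DataFrame:
    """Ne estimates over random SNP subsamples of varying size."""
    rng = np.random.default_rng(seed)
    rows = []
    for count in snp_counts:
        res = ld_ne(gm, maf=maf, n_snps=count, seed=int(rng.integers(2**31 - 1)))
        rows.append(
            {
                "n_snps": count,
                "ne_hat": res.ne_hat,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "mean_r2": res.mean_r2,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows)
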
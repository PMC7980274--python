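"""VCF reading/writing and the filter cascade."""

import subprocess

import numpy as np
import pytest

from panmix.vcf_io import (
    MISSING,
    FilterConfig,
    apply_filters,
    missingness_profile,
    read_vcf,
    write_sample_sheet,
    write_vcf,
)

from conftest import make_gm

TRICKY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
chr1\t200\t.\tC\tCT\t.\tPASS\t.\tGT\t0/1\t0/0
chr1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t1/2
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t1|1\t./.
"""

SHEET2 = "id,colony,lat,lon,age_class,year\ns1,c0,38,-121,adult,2017\ns2,c0,38,-121,adult,2017\n"


@pytest.fixture
def tricky(tmp_path):
    vcf = tmp_path / "in.vcf"
    vcf.write_text(TRICKY_VCF)
    sheet = tmp_path / "s.csv"
    sheet.write_text(SHEET2)
    return vcf, sheet


def test_roundtrip_identity(tmp_path, panmictic_gm):
    gm = panmictic_gm
    write_vcf(gm, tmp_path / "out.vcf")
    write_sample_sheet(gm, tmp_path / "out.csv")
    back = read_vcf(tmp_path / "out.vcf", tmp_path / "out.csv")
    assert np.array_equal(back.genotypes, gm.genotypes)
    assert (back.site_meta["pos"].to_numpy() == gm.site_meta["pos"].to_numpy()).all()
    assert (back.site_meta["ref"] == gm.site_meta["ref"]).all()
    assert (back.site_meta["alt"] == gm.site_meta["alt"]).all()


def test_missing_preserved_and_phase_normalized(tricky):
    gm = read_vcf(*tricky)
    assert gm.genotypes[1, 3] == MISSING  # "./." stays missing
    assert gm.genotypes[0, 3] == 2  # "1|1" read as unphased hom ALT


def test_indel_and_triallelic_flagged(tricky):
    gm = read_vcf(*tricky)
    assert list(gm.site_meta["biallelic_snp"]) == [True, False, False, True]


def test_unknown_sample_in_sheet_errors(tmp_path):
    vcf = tmp_path / "in.vcf"
    vcf.write_text(TRICKY_VCF)
    sheet = tmp_path / "s.csv"
    sheet.write_text(
        "id,colony,lat,lon,age_class,year\ns1,c0,38,-121,adult,2017\n"
        "sX,c0,38,-121,adult,2017\n"
    )
    with pytest.raises(ValueError, match="sX"):
        read_vcf(vcf, sheet)


def test_written_vcf_parses_under_bcftools(tmp_path, panmictic_gm):
    path = tmp_path / "out.vcf"
    write_vcf(panmictic_gm, path)
    res = subprocess.run(
        ["bcftools", "view", "-H", str(path)], capture_output=True, text=True
    )
    assert res.returncode == 0
    assert len(res.stdout.splitlines()) == panmictic_gm.n_sites


def test_filter_toy_enumeration():
    """One site at MAF 0.005 and one individual 50% missing are the only
    removals, and the report enumerates both."""
    rng = np.random.default_rng(0)
    n = 100
    geno = rng.binomial(2, 0.3, size=(n, 4)).astype(np.int8)
    geno[:, 0] = 0
    geno[0, 0] = 1  # site 0: 1/200 ALT alleles -> MAF 0.005
    geno[1, [1, 3]] = MISSING  # individual 1: 2/4 missing after site drop
    gm = make_gm(geno)
    out, report = apply_filters(gm, FilterConfig(min_gq=0, min_dp=0))
    assert report.sites_low_maf == 1
    assert report.individuals_high_missing == 1
    assert report.removed_individual_ids == ["ind_0001"]
    assert out.n_sites == 3 and out.n_individuals == n - 1


def test_filter_extremes_noop_except_nonbiallelic():
    rng = np.random.default_rng(1)
    geno = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    biallelic = [True, True, False, True, True, True]
    gm = make_gm(geno, biallelic=biallelic)
    cfg = FilterConfig(min_gq=0, min_dp=0, min_maf=0.0, max_site_missing=1.0,
                       max_indiv_missing=1.0)
    out, report = apply_filters(gm, cfg)
    assert out.n_sites == 5
    assert report.sites_non_biallelic == 1
    assert np.array_equal(out.genotypes, geno[:, np.array(biallelic)])


def test_gq_dp_masking_happens_first():
    geno = np.full((4, 2), 1, dtype=np.int8)
    gq = np.full((4, 2), 99.0)
    gq[0, 0] = 10.0  # below threshold -> masked to MISSING
    gm = make_gm(geno, gq=gq)
    out, report = apply_filters(
        gm,
        FilterConfig(min_gq=30, min_dp=0, min_maf=0.0, max_site_missing=1.0,
                     max_indiv_missing=1.0),
    )
    assert report.genotypes_masked_gq_dp == 1
    assert out.genotypes[0, 0] == MISSING


def test_filter_idempotent():
    rng = np.random.default_rng(2)
    geno = rng.binomial(2, rng.uniform(0.0, 0.5, 50), size=(30, 50)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.15] = MISSING
    gm = make_gm(geno)
    cfg = FilterConfig(min_gq=0, min_dp=0, min_maf=0.05, max_site_missing=0.2,
                       max_indiv_missing=0.3)
    once, r1 = apply_filters(gm, cfg)
    twice, r2 = apply_filters(once, cfg)
    assert np.array_equal(once.genotypes, twice.genotypes)
    assert r2.sites_low_maf == 0 and r2.individuals_high_missing == 0


def test_filter_report_sums_consistent():
    rng = np.random.default_rng(3)
    geno = rng.binomial(2, rng.uniform(0, 0.5, 80), size=(40, 80)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.08] = MISSING
    gm = make_gm(geno)
    out, rep = apply_filters(gm, FilterConfig(min_gq=0, min_dp=0))
    assert rep.input_shape[1] - (
        rep.sites_non_biallelic + rep.sites_low_maf + rep.sites_high_missing
    ) == rep.output_shape[1]
    assert rep.input_shape[0] - rep.individuals_high_missing == rep.output_shape[0]


def test_filter_error_when_emptied():
    geno = np.zeros((5, 3), dtype=np.int8)  # all monomorphic
    gm = make_gm(geno)
    with pytest.raises(ValueError, match="minor-allele"):
        apply_filters(gm, FilterConfig(min_gq=0, min_dp=0, min_maf=0.01))


def test_missingness_profile():
    geno = np.ones((4, 5), dtype=np.int8)
    gm = make_gm(geno)
    prof = missingness_profile(gm)
    assert (prof["per_site"]["missing_frac"] == 0).all()
    geno2 = geno.copy()
    geno2[2] = MISSING  # one individual fully missing
    prof2 = missingness_profile(make_gm(geno2))
    assert prof2["per_individual"]["missing_frac"].iloc[2] == 1.0
    assert (prof2["per_site"]["missing_frac"] == 0.25).all()
    # site and individual missing counts tally
    assert np.isclose(
        prof2["per_site"]["missing_frac"].sum() * 4,
        prof2["per_individual"]["missing_frac"].sum() * 5,
    )


def test_mcar_missingness_rate():
    """5% MCAR injection shows up as ~5% mean per-site missingness."""
    from panmix.synthetic_data import SimConfig, simulate_coalescent_dataset

    gm = simulate_coalescent_dataset(
        SimConfig(epochs=((20_000, 0),), n_loci=3000, n_diploids=30,
                  missing_rate=0.05, seed=7)
    )
    frac = missingness_profile(gm)["per_site"]["missing_frac"].mean()
    n_entries = gm.n_individuals * gm.n_sites
    se = np.sqrt(0.05 * 0.95 / n_entries)
    assert abs(frac - 0.05) < 3 * se


def test_no_individual_dropped_at_8pct_missingness(panmictic_gm):
    """8% genotype missingness stays under a 10% individual cut."""
    from dataclasses import replace

    rng = np.random.default_rng(5)
    geno = panmictic_gm.genotypes.copy()
    geno[rng.random(geno.shape) < 0.08] = MISSING
    gm = replace(panmictic_gm, genotypes=geno)
    out, rep = apply_filters(gm, FilterConfig(min_gq=0, min_dp=0, min_maf=0.0))
    assert rep.individuals_high_missing == 0


def test_write_empty_site_set(tmp_path):
    gm = make_gm(np.empty((3, 0), dtype=np.int8), chrom=[])
    write_vcf(gm, tmp_path / "empty.vcf")
    text = (tmp_path / "empty.vcf").read_text()
    assert text.startswith("##fileformat")
    assert len([l for l in text.splitlines() if not l.startswith("#")]) == 0
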
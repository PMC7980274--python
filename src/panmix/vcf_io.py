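"""Reading, filtering and writing multi-sample SNP genotype data.

The working container for the whole pipeline is :class:`GenotypeMatrix`:
an individuals x sites matrix of ALT-allele counts (0/1/2, ``MISSING`` = -1)
with per-site and per-sample metadata, and optional per-genotype quality
(GQ, phred) and read depth (DP).  VCF parsing is delegated to cyvcf2;
writing emits plain VCF 4.2 text so that ``read_vcf(write_vcf(gm))`` is the
identity on genotypes, positions and alleles.

Coordinates are 1-based inclusive (VCF convention) in ``site_meta``;
all internal arrays are 0-based.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SAMPLE_SHEET_COLUMNS = ["id", "colony", "lat", "lon", "age_class", "year"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of individuals.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` int8 array counting ALT alleles,
        values in ``{0, 1, 2, MISSING}``.
    site_meta
        Per-site table with columns ``chrom, pos, ref, alt, biallelic_snp``.
        ``chrom`` doubles as the RAD-locus label for synthetic data.
    sample_meta
        Per-individual table with columns ``id, colony, lat, lon,
        age_class, year``.
    gq, dp
        Optional per-genotype phred genotype quality and read depth,
        same shape as ``genotypes``; negative entries mean "not recorded".
    """

    genotypes: np.ndarray
    site_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        n, s = self.genotypes.shape
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match genotype rows")
        if len(self.site_meta) != s:
            raise ValueError("site_meta length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,MISSING}")
        if self.sample_meta["id"].duplicated().any():
            dup = self.sample_meta["id"][self.sample_meta["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.genotypes != MISSING

    def alt_counts(self) -> np.ndarray:
        """Per-site ALT allele count among called genotypes."""
        g = np.where(self.called, self.genotypes, 0)
        return g.sum(axis=0)

    def allele_numbers(self) -> np.ndarray:
        """Per-site number of called alleles (2 x called genotypes)."""
        return 2 * self.called.sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-site ALT allele frequency among called alleles (NaN if none)."""
        an = self.allele_numbers().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.alt_counts() / an, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            genotypes=self.genotypes[index],
            sample_meta=self.sample_meta.iloc[index].reset_index(drop=True),
            gq=None if self.gq is None else self.gq[index],
            dp=None if self.dp is None else self.dp[index],
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            site_meta=self.site_meta.iloc[index].reset_index(drop=True),
            gq=None if self.gq is None else self.gq[:, index],
            dp=None if self.dp is None else self.dp[:, index],
        )


@dataclass
class FilterConfig:
    """Thresholds for the variant/genotype filter cascade.

    Defaults follow common RAD-Seq practice for a songbird SNP panel:
    genotype calls below GQ 30 or depth 8 are unreliable, singletor-poor
    sites below MAF 0.01 are mostly genotyping error, and sites or
    individuals missing more than 10% of calls are dropped.
    """

    min_gq: float = 30.0
    min_dp: float = 8.0
    min_maf: float = 0.01
    max_site_missing: float = 0.10
    max_indiv_missing: float = 0.10
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_site_missing", "max_indiv_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("GQ/DP thresholds must be non-negative")


@dataclass
class FilterReport:
    """Removal counts per rule, in the order the rules were applied."""

    genotypes_masked_gq_dp: int = 0
    sites_non_biallelic: int = 0
    sites_low_maf: int = 0
    sites_high_missing: int = 0
    individuals_high_missing: int = 0
    removed_individual_ids: list = field(default_factory=list)
    input_shape: tuple = (0, 0)
    output_shape: tuple = (0, 0)

    def as_dict(self) -> dict:
        return {
            "genotypes_masked_gq_dp": self.genotypes_masked_gq_dp,
            "sites_non_biallelic": self.sites_non_biallelic,
            "sites_low_maf": self.sites_low_maf,
            "sites_high_missing": self.sites_high_missing,
            "individuals_high_missing": self.individuals_high_missing,
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape),
        }


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {missing_cols}")
    sheet["id"] = sheet["id"].astype(str)
    return sheet[SAMPLE_SHEET_COLUMNS]


def read_vcf(path, sample_sheet) -> GenotypeMatrix:
    """Load a VCF 4.x file (optionally gzipped) plus its sample sheet.

    All records are returned; multiallelic or indel records are retained
    but flagged ``biallelic_snp=False`` for ``apply_filters`` to drop.
    Uncalled genotypes ("./.") become ``MISSING``.
    """
    from cyvcf2 import VCF

    sheet = read_sample_sheet(sample_sheet) if not isinstance(
        sample_sheet, pd.DataFrame
    ) else sample_sheet

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    sheet_ids = list(sheet["id"])
    unknown = sorted(set(sheet_ids) - set(vcf_samples))
    if unknown:
        raise ValueError(f"sample sheet names unknown sample(s): {unknown}")
    absent = sorted(set(vcf_samples) - set(sheet_ids))
    if absent:
        raise ValueError(f"VCF sample(s) missing from sheet: {absent}")
    # order sheet rows to match VCF column order
    sheet = sheet.set_index("id").loc[vcf_samples].reset_index()

    geno_cols, gq_cols, dp_cols, meta = [], [], [], []
    has_gq = has_dp = False
    for i, var in enumerate(vcf):
        try:
            is_snp = var.is_snp and not var.is_indel
            biallelic = is_snp and len(var.ALT) == 1
            gt = np.asarray(var.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            geno_cols.append(gt)
            gq = np.asarray(var.gt_quals, dtype=np.float32)
            if np.any(gq >= 0):
                has_gq = True
            gq_cols.append(gq)
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                dp = np.asarray(dp, dtype=np.float32).reshape(-1)
                has_dp = True
            else:
                dp = np.full(len(vcf_samples), -1.0, dtype=np.float32)
            dp_cols.append(dp)
            meta.append(
                (
                    var.CHROM,
                    var.POS,
                    var.REF,
                    ",".join(var.ALT) if var.ALT else ".",
                    bool(biallelic),
                )
            )
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{i + 1}: {exc}") from exc

    site_meta = pd.DataFrame(
        meta, columns=["chrom", "pos", "ref", "alt", "biallelic_snp"]
    )
    n_sites = len(site_meta)
    genotypes = (
        np.stack(geno_cols, axis=1)
        if n_sites
        else np.empty((len(vcf_samples), 0), dtype=np.int8)
    )
    gq_arr = np.stack(gq_cols, axis=1) if (n_sites and has_gq) else None
    dp_arr = np.stack(dp_cols, axis=1) if (n_sites and has_dp) else None
    return GenotypeMatrix(genotypes, site_meta, sheet, gq=gq_arr, dp=dp_arr)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 file with GT (and GQ/DP when present)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    fmt_keys = ["GT"]
    if gm.gq is not None:
        fmt_keys.append("GQ")
    if gm.dp is not None:
        fmt_keys.append("DP")
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.gq is not None:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                'Description="Genotype Quality">\n'
            )
        if gm.dp is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n'
            )
        for chrom in pd.unique(gm.site_meta["chrom"]):
            n = int((gm.site_meta["chrom"] == chrom).sum())
            fh.write(f"##contig=<ID={chrom}>\n")
        header = [
            "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
            "FORMAT",
        ]
        header += list(gm.sample_meta["id"].astype(str))
        fh.write("\t".join(header) + "\n")
        fmt = ":".join(fmt_keys)
        for j in range(gm.n_sites):
            row = gm.site_meta.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(gm.n_individuals):
                cell = [_GT_STR[int(gm.genotypes[i, j])]]
                if gm.gq is not None:
                    v = gm.gq[i, j]
                    cell.append("." if v < 0 else str(int(round(float(v)))))
                if gm.dp is not None:
                    v = gm.dp[i, j]
                    cell.append("." if v < 0 else str(int(round(float(v)))))
                fields.append(":".join(cell))
            fh.write("\t".join(fields) + "\n")


def write_sample_sheet(gm: GenotypeMatrix, path) -> None:
    gm.sample_meta.to_csv(path, index=False)


def missingness_profile(gm: GenotypeMatrix) -> dict:
    """Per-site and per-individual missing-call fractions.

    Returns a dict with DataFrames ``per_site`` (chrom, pos, missing_frac)
    and ``per_individual`` (id, missing_frac).
    """
    miss = ~gm.called
    per_site = pd.DataFrame(
        {
            "chrom": gm.site_meta["chrom"],
            "pos": gm.site_meta["pos"],
            "missing_frac": miss.mean(axis=0) if gm.n_individuals else 0.0,
        }
    )
    per_ind = pd.DataFrame(
        {
            "id": gm.sample_meta["id"],
            "missing_frac": miss.mean(axis=1) if gm.n_sites else 0.0,
        }
    )
    return {"per_site": per_site, "per_individual": per_ind}


def apply_filters(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the fixed filter cascade and report removals per rule.

    Order (fixed so removal counts are reproducible):

    1. genotype calls failing GQ or DP thresholds set to ``MISSING``;
    2. non-biallelic / indel sites dropped (if ``biallelic_only``);
    3. minor-allele frequency computed on called alleles, sites with
       MAF < ``min_maf`` dropped;
    4. sites with missing fraction > ``max_site_missing`` dropped;
    5. individuals with missing fraction > ``max_indiv_missing`` dropped.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(input_shape=gm.genotypes.shape)

    geno = gm.genotypes.copy()
    if gm.gq is not None and cfg.min_gq > 0:
        mask = (gm.gq >= 0) & (gm.gq < cfg.min_gq) & (geno != MISSING)
        report.genotypes_masked_gq_dp += int(mask.sum())
        geno[mask] = MISSING
    if gm.dp is not None and cfg.min_dp > 0:
        mask = (gm.dp >= 0) & (gm.dp < cfg.min_dp) & (geno != MISSING)
        report.genotypes_masked_gq_dp += int(mask.sum())
        geno[mask] = MISSING
    gm = replace(gm, genotypes=geno)

    if cfg.biallelic_only:
        keep = gm.site_meta["biallelic_snp"].to_numpy(dtype=bool)
        report.sites_non_biallelic = int((~keep).sum())
        gm = gm.take_sites(np.flatnonzero(keep))
        _check_nonempty(gm, "non-biallelic site removal", report)

    if cfg.min_maf > 0:
        maf = gm.minor_allele_freq()
        keep = np.nan_to_num(maf, nan=-1.0) >= cfg.min_maf
        report.sites_low_maf = int((~keep).sum())
        gm = gm.take_sites(np.flatnonzero(keep))
        _check_nonempty(gm, "minor-allele-frequency filter", report)

    site_miss = (~gm.called).mean(axis=0)
    keep = site_miss <= cfg.max_site_missing
    report.sites_high_missing = int((~keep).sum())
    gm = gm.take_sites(np.flatnonzero(keep))
    _check_nonempty(gm, "per-site missingness filter", report)

    ind_miss = (~gm.called).mean(axis=1)
    keep = ind_miss <= cfg.max_indiv_missing
    report.individuals_high_missing = int((~keep).sum())
    report.removed_individual_ids = list(gm.sample_meta["id"][~keep])
    gm = gm.take_individuals(np.flatnonzero(keep))
    _check_nonempty(gm, "per-individual missingness filter", report)

    report.output_shape = gm.genotypes.shape
    return gm, report


def _check_nonempty(gm: GenotypeMatrix, rule: str, report: FilterReport) -> None:
    if gm.n_sites == 0 or gm.n_individuals == 0:
        raise ValueError(f"filtering emptied the dataset at step: {rule}")
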
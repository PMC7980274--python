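"""Generators for every input the pipeline consumes.

Two simulators, both seeded and deterministic:

* a continuous-time single-population Kingman **coalescent** with
  piecewise-constant diploid size ``N(t)``, producing RAD-like data:
  unlinked short loci, infinite-sites mutations within each locus,
  haplotypes paired into diploids, MCAR genotype missingness, optional
  planted parent-offspring pairs, and a colony/age/year sample sheet with
  no geographic signal (panmixia is the ground truth);
* a discrete-generation forward **Wright-Fisher** population of unlinked
  biallelic loci (random mating with selfing), whose drift generates the
  linkage disequilibrium that the LD-based Ne estimator measures.

The coalescent uses time-rescaling: interval waits are standard
exponentials with rate ``C(k,2)`` mapped through the inverse cumulative
rate ``Lambda(t) = int dt / 2N(t)``, exact for piecewise-constant ``N``.
Within a locus all sites share one genealogy (no recombination), so
multi-SNP loci carry realistic within-locus LD for the per-locus ABC
statistics; loci are independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vcf_io import MISSING, GenotypeMatrix, write_sample_sheet, write_vcf

# study-like truth: ~50% contraction from the ancestral size, ~21k
# generations ago, songbird mutation rate, 100 bp RAD loci, 153 diploids
DEFAULT_EPOCHS = ((91_315, 0), (174_455, 21_317))


@dataclass
class SimConfig:
    """Piecewise-constant coalescent simulation recipe.

    ``epochs`` lists ``(diploid size, start generation ago)`` from the
    present backwards; the first entry must start at 0 and the last epoch
    extends to infinity.
    """

    epochs: tuple = DEFAULT_EPOCHS
    mu: float = 4.6e-9
    n_loci: int = 70_000
    locus_length: int = 100
    n_diploids: int = 153
    missing_rate: float = 0.0
    n_planted_parent_offspring_pairs: int = 0
    n_colonies: int = 12
    n_nestlings: int = 0
    n_old_samples: int = 0
    years: tuple = (2017, 2018)
    old_years: tuple = (2002, 2008)
    seed: int = 0

    def __post_init__(self) -> None:
        starts = [t for _, t in self.epochs]
        if starts[0] != 0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must begin at 0 and increase")
        if any(n <= 0 for n, _ in self.epochs):
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")


@dataclass
class WFConfig:
    """Forward Wright-Fisher recipe for drift-LD data."""

    ne: int = 3100
    n_loci: int = 2000
    generations: int = 60
    n_sampled: int = 132
    init_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_sampled > self.ne:
            raise ValueError("cannot sample more individuals than Ne")


# ---------------------------------------------------------------------------
# coalescent machinery
# ---------------------------------------------------------------------------


def _rescaling_knots(epochs) -> tuple[np.ndarray, np.ndarray, float]:
    """Knots of ``Lambda^{-1}`` (standard time -> generations)."""
    sizes = np.array([n for n, _ in epochs], float)
    starts = np.array([t for _, t in epochs], float)
    durs = np.diff(starts)
    s_knots = np.concatenate([[0.0], np.cumsum(durs / (2.0 * sizes[:-1]))])
    return s_knots, starts, 2.0 * sizes[-1]


def _coalescent_times(n: int, knots, rng) -> np.ndarray:
    """Merge times (generations ago) for one genealogy of ``n`` tips."""
    k = np.arange(n, 1, -1)
    waits = rng.exponential(1.0 / (k * (k - 1) / 2.0))
    s = np.cumsum(waits)
    s_knots, t_knots, tail_slope = knots
    t = np.interp(s, s_knots, t_knots)
    tail = s > s_knots[-1]
    if tail.any():
        t = np.where(tail, t_knots[-1] + (s - s_knots[-1]) * tail_slope, t)
    return t


def _simulate_locus(n, knots, theta_locus, rng, want_carriers):
    """One locus: returns a list of mutations as derived-allele counts,
    and (optionally) carrier index arrays for genotype construction."""
    times = _coalescent_times(n, knots, rng)
    active = list(range(n))
    leafsets = {i: (i,) for i in range(n)} if want_carriers else None
    sizes = {i: 1 for i in range(n)}
    birth = {i: 0.0 for i in range(n)}
    next_id = n
    counts, carriers = [], []
    for t in times:
        k = len(active)
        ia = rng.integers(k)
        ib = rng.integers(k - 1)
        if ib >= ia:
            ib += 1
        a, b = active[ia], active[ib]
        for node in (a, b):
            blen = t - birth[node]
            n_mut = rng.poisson(theta_locus * blen)
            for _ in range(n_mut):
                counts.append(sizes[node])
                if want_carriers:
                    carriers.append(leafsets[node])
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        birth[new] = t
        if want_carriers:
            leafsets[new] = leafsets[a] + leafsets[b]
            del leafsets[a], leafsets[b]
        del sizes[a], sizes[b], birth[a], birth[b]
        hi, lo = max(ia, ib), min(ia, ib)
        active.pop(hi)
        active.pop(lo)
        active.append(new)
    return counts, carriers


def simulate_locus_allele_counts(
    n_haplotypes: int, epochs, mu: float, locus_length: int, n_loci: int, rng
) -> list[np.ndarray]:
    """Derived-allele counts per segregating site, per locus (no genotype
    construction) — the fast path used by the ABC simulator."""
    knots = _rescaling_knots(epochs)
    theta_locus = mu * locus_length
    out = []
    for _ in range(n_loci):
        counts, _ = _simulate_locus(n_haplotypes, knots, theta_locus, rng, False)
        out.append(np.asarray(counts, dtype=int))
    return out


def simulate_coalescent_dataset(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate a RAD-like diploid SNP dataset under ``cfg``.

    Haplotypes are paired index-(2i, 2i+1) into diploids; planted
    parent-offspring pairs are created by Mendelian transmission (one
    random parental haplotype per locus) from one sampled and one spare
    simulated parent, the offspring replacing a sampled individual.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pairs = cfg.n_planted_parent_offspring_pairs
    n_total = cfg.n_diploids + n_pairs
    n_hap = 2 * n_total
    knots = _rescaling_knots(cfg.epochs)
    theta_locus = cfg.mu * cfg.locus_length

    hap_cols, meta = [], []
    for locus in range(cfg.n_loci):
        counts, carriers = _simulate_locus(n_hap, knots, theta_locus, rng, True)
        if not counts:
            continue
        pos = rng.choice(cfg.locus_length, size=min(len(counts), cfg.locus_length),
                         replace=False) + 1
        order = np.argsort(pos)
        for idx in order:
            if idx >= len(carriers):
                continue
            col = np.zeros(n_hap, dtype=np.int8)
            col[list(carriers[idx])] = 1
            hap_cols.append(col)
            meta.append((f"locus_{locus:06d}", int(pos[idx]), "A", "T", True))

    if hap_cols:
        H = np.stack(hap_cols, axis=1)  # (n_hap, n_sites)
    else:
        H = np.zeros((n_hap, 0), dtype=np.int8)
    geno = H[0::2] + H[1::2]  # (n_total, n_sites)

    # plant parent-offspring pairs: parent p, spare parent, child replaces
    # the individual at slot n_diploids-1-p
    loci = (
        pd.factorize(np.array([m[0] for m in meta]))[0]
        if meta
        else np.array([], int)
    )
    n_loci_seg = int(loci.max()) + 1 if len(loci) else 0
    for p in range(n_pairs):
        parent = p
        spare = cfg.n_diploids + p
        child_slot = cfg.n_diploids - 1 - p
        if child_slot <= parent:
            raise ValueError("too many planted pairs for the sample size")
        from_parent = rng.integers(2, size=n_loci_seg)[loci].astype(bool)
        from_spare = rng.integers(2, size=n_loci_seg)[loci].astype(bool)
        hp = np.where(from_parent, H[2 * parent], H[2 * parent + 1])
        hs = np.where(from_spare, H[2 * spare], H[2 * spare + 1])
        geno[child_slot] = hp + hs

    geno = geno[: cfg.n_diploids]

    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(mask, MISSING, geno).astype(np.int8)

    site_meta = pd.DataFrame(
        meta, columns=["chrom", "pos", "ref", "alt", "biallelic_snp"]
    )
    sample_meta = _sample_sheet(cfg, rng)
    return GenotypeMatrix(geno, site_meta, sample_meta)


def _sample_sheet(cfg: SimConfig, rng) -> pd.DataFrame:
    """Random colony/age/year assignment with no geographic signal."""
    n = cfg.n_diploids
    colony_lat = rng.uniform(33.0, 41.0, size=cfg.n_colonies)
    colony_lon = rng.uniform(-124.0, -115.0, size=cfg.n_colonies)
    colony = rng.integers(cfg.n_colonies, size=n)
    age = np.array(["adult"] * n, dtype=object)
    year = rng.choice(cfg.years, size=n)
    special = rng.permutation(n)[: cfg.n_nestlings + cfg.n_old_samples]
    for i in special[: cfg.n_nestlings]:
        age[i] = "nestling"
    for i in special[cfg.n_nestlings:]:
        year[i] = rng.choice(cfg.old_years)
    return pd.DataFrame(
        {
            "id": [f"ind_{i:04d}" for i in range(n)],
            "colony": [f"colony_{c:02d}" for c in colony],
            "lat": colony_lat[colony],
            "lon": colony_lon[colony],
            "age_class": age,
            "year": year.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# forward Wright-Fisher
# ---------------------------------------------------------------------------


def simulate_wright_fisher(cfg: WFConfig) -> GenotypeMatrix:
    """Neutral random-mating Wright-Fisher population of unlinked loci.

    Each generation every offspring draws two parents uniformly with
    replacement (selfing allowed) and one random allele per parent,
    independently across loci.  Initial allele frequencies follow a
    neutral-SFS-shaped (1/x) distribution unless given.  Loci fixed at
    sampling time are dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    ne, L = cfg.ne, cfg.n_loci
    if cfg.init_freqs is None:
        x = np.arange(1, 2 * ne)
        p0 = rng.choice(x, size=L, p=(1.0 / x) / np.sum(1.0 / x)) / (2.0 * ne)
    else:
        p0 = np.broadcast_to(np.asarray(cfg.init_freqs, float), (L,)).copy()
    A = (rng.random((ne, L)) < p0).astype(np.int8)
    B = (rng.random((ne, L)) < p0).astype(np.int8)
    for _ in range(cfg.generations):
        p1 = rng.integers(ne, size=ne)
        p2 = rng.integers(ne, size=ne)
        new_a = np.where(rng.random((ne, L)) < 0.5, A[p1], B[p1])
        new_b = np.where(rng.random((ne, L)) < 0.5, A[p2], B[p2])
        A, B = new_a, new_b
    freq = (A.sum(0) + B.sum(0)) / (2.0 * ne)
    seg = (freq > 0) & (freq < 1)
    take = rng.permutation(ne)[: cfg.n_sampled]
    geno = (A[take][:, seg] + B[take][:, seg]).astype(np.int8)
    site_meta = pd.DataFrame(
        {
            "chrom": [f"locus_{i:06d}" for i in np.flatnonzero(seg)],
            "pos": 1,
            "ref": "A",
            "alt": "T",
            "biallelic_snp": True,
        }
    )
    sample_meta = pd.DataFrame(
        {
            "id": [f"ind_{i:04d}" for i in range(cfg.n_sampled)],
            "colony": "colony_00",
            "lat": 38.0,
            "lon": -121.0,
            "age_class": "adult",
            "year": 2017,
        }
    )
    return GenotypeMatrix(geno, site_meta, sample_meta)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t./.
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
chr1\t500\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0
"""

TOY_SHEET = """id,colony,lat,lon,age_class,year
s1,colony_00,38.0,-121.0,adult,2017
s2,colony_00,38.0,-121.0,adult,2017
s3,colony_01,36.0,-119.5,nestling,2018
"""


def make_fixture_suite(out_dir, seed: int = 0, scale: str = "desk") -> dict:
    """Write the canonical test datasets and a truth manifest.

    ``scale='desk'`` keeps everything small enough for routine test runs;
    ``scale='study'`` generates study-sized data (~150 diploids, tens of
    thousands of SNPs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scale == "study":
        n_loci, n_dip, wf_loci = 70_000, 153, 2000
    else:
        n_loci, n_dip, wf_loci = 400, 40, 300
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31 - 1)) for k in
             ("panmictic", "two_epoch", "wf", "relatives")}
    manifest = {"seed": seed, "scale": scale, "datasets": {}}

    (out / "toy.vcf").write_text(TOY_VCF)
    (out / "toy_samples.csv").write_text(TOY_SHEET)
    manifest["datasets"]["toy"] = {"vcf": "toy.vcf", "samples": "toy_samples.csv"}

    recipes = {
        "panmictic": SimConfig(
            epochs=((100_000, 0),), n_loci=n_loci, n_diploids=n_dip,
            missing_rate=0.05, seed=seeds["panmictic"],
        ),
        "two_epoch": SimConfig(
            n_loci=n_loci, n_diploids=n_dip, missing_rate=0.08,
            seed=seeds["two_epoch"],
        ),
        "relatives": SimConfig(
            epochs=((100_000, 0),), n_loci=n_loci, n_diploids=n_dip,
            n_planted_parent_offspring_pairs=2, seed=seeds["relatives"],
        ),
    }
    for name, cfg in recipes.items():
        gm = simulate_coalescent_dataset(cfg)
        write_vcf(gm, out / f"{name}.vcf")
        write_sample_sheet(gm, out / f"{name}_samples.csv")
        truth = asdict(cfg)
        truth["init_freqs"] = None
        manifest["datasets"][name] = {
            "vcf": f"{name}.vcf",
            "samples": f"{name}_samples.csv",
            "truth": truth,
            "n_snps": gm.n_sites,
        }

    wf_cfg = WFConfig(ne=500, n_loci=wf_loci, n_sampled=132, seed=seeds["wf"])
    gm = simulate_wright_fisher(wf_cfg)
    write_vcf(gm, out / "wf.vcf")
    write_sample_sheet(gm, out / "wf_samples.csv")
    manifest["datasets"]["wf"] = {
        "vcf": "wf.vcf",
        "samples": "wf_samples.csv",
        "truth": {k: v for k, v in asdict(wf_cfg).items() if k != "init_freqs"},
        "n_snps": gm.n_sites,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
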
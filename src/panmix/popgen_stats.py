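"""The panmixia battery: kinship, PCA, diversity, F_ST, Tajima's D, Mantel.

These are the statistics used to ask whether a range-wide sample behaves
as one randomly mating population: no close relatives inflating
structure, no PCA clustering, uniform heterozygosity and near-zero
F_IS across colonies, small patternless pairwise F_ST, and no
isolation-by-distance signal in a Mantel test.  Tajima's D summarizes
the genome-wide allele-frequency skew, corrected for missing data by
evaluating its constants at per-site sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .vcf_io import GenotypeMatrix

FIRST_ORDER_KINSHIP = 0.177  # midpoint between 1st and 2nd degree, KING scale

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Pairwise KING-robust kinship; NaN where no jointly called sites."""

    phi: np.ndarray
    ids: list
    threshold_first_order: float = FIRST_ORDER_KINSHIP

    def flagged_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.phi[i, j]
                if np.isfinite(v) and v > self.threshold_first_order:
                    out.append((self.ids[i], self.ids[j], float(v)))
        return out


def king_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust between-family kinship estimator.

    For a pair (i, j), over sites called in both,
    ``phi = (N_het,het - 2 N_oppHom) / (N_het(i) + N_het(j))``.
    Self-pairs on the diagonal evaluate to 0.5 whenever the individual
    has at least one heterozygous site.
    """
    if gm.n_individuals < 2:
        raise ValueError("kinship needs at least two individuals")
    G = gm.genotypes
    het = (G == 1).astype(np.float32)
    hom0 = (G == 0).astype(np.float32)
    hom2 = (G == 2).astype(np.float32)
    valid = gm.called.astype(np.float32)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_in_joint = het @ valid.T  # het count of row-individual on joint sites
    denom = het_in_joint + het_in_joint.T
    joint = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(
            (denom > 0) & (joint > 0), (n_hethet - 2.0 * n_opp) / denom, np.nan
        )
    return KinshipMatrix(phi.astype(float), list(gm.sample_meta["id"]))


def prune_relatives(km: KinshipMatrix, gm: GenotypeMatrix) -> GenotypeMatrix:
    """Remove one member of every first-order pair (kinship > 0.177).

    The member with more missing genotypes is removed; ties break to the
    lexicographically larger id.  Repeats until no pair exceeds the
    threshold.
    """
    ids = list(gm.sample_meta["id"])
    if ids != km.ids:
        raise ValueError("kinship matrix was not computed on this matrix")
    missing = (~gm.called).sum(axis=1)
    keep = np.ones(len(ids), dtype=bool)
    phi = km.phi.copy()
    np.fill_diagonal(phi, np.nan)
    while True:
        masked = np.where(np.outer(keep, keep), phi, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            above = np.nan_to_num(masked, nan=-np.inf) > km.threshold_first_order
        if not above.any():
            break
        i, j = np.unravel_index(np.nanargmax(np.where(above, masked, -np.inf)),
                                phi.shape)
        if missing[i] != missing[j]:
            drop = i if missing[i] > missing[j] else j
        else:
            drop = i if ids[i] > ids[j] else j
        keep[drop] = False
    return gm.take_individuals(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# PCA with automated outlier removal
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # id + PC columns
    explained_var: np.ndarray
    removed_ids: list
    loadings: np.ndarray  # (n_pcs, n_sites)


def pca_with_outlier_removal(
    gm: GenotypeMatrix,
    sd_threshold: float = 6.0,
    max_rounds: int = 5,
    n_pcs: int = 10,
) -> PCAResult:
    """Genotype PCA with deterministic iterative outlier removal.

    Missing genotypes are mean-imputed per site; sites are centred and
    scaled by ``sqrt(p(1-p))``.  Individuals whose PC1 or PC2 score
    exceeds ``sd_threshold`` standard deviations are removed and the PCA
    recomputed, up to ``max_rounds`` times — an automated stand-in for
    removing visual outliers by eye.
    """
    if gm.n_individuals < 3:
        raise ValueError("PCA needs at least three individuals")
    removed: list = []
    current = gm
    for _ in range(max_rounds + 1):
        G = current.genotypes.astype(float)
        G[~current.called] = np.nan
        p = np.nanmean(G, axis=0) / 2.0
        poly = (p > 0) & (p < 1) & np.isfinite(p)
        if not poly.any():
            raise ValueError("no polymorphic sites; PCA undefined")
        Gp = G[:, poly]
        pp = p[poly]
        mu = 2.0 * pp
        X = (np.where(np.isnan(Gp), mu, Gp) - mu) / np.sqrt(pp * (1 - pp))
        X -= X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        k = min(n_pcs, len(s))
        scores = U[:, :k] * s[:k]
        ev = s**2 / np.sum(s**2)
        sd = scores[:, :2].std(axis=0, ddof=1)
        out = (np.abs(scores[:, :2]) > sd_threshold * sd).any(axis=1)
        if not out.any() or len(removed) >= max_rounds:
            df = pd.DataFrame(
                scores, columns=[f"PC{i + 1}" for i in range(k)]
            )
            df.insert(0, "id", list(current.sample_meta["id"]))
            return PCAResult(df, ev[:k], removed, Vt[:k])
        removed += list(current.sample_meta["id"][out])
        current = current.take_individuals(np.flatnonzero(~out))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def diversity(gm: GenotypeMatrix, groups=None) -> pd.DataFrame:
    """Per-group H_O, H_E (small-sample corrected) and F_IS.

    ``H_O`` is the mean per-site heterozygote fraction among called
    genotypes; ``H_E`` the mean of ``2 p (1-p) * 2n/(2n-1)``; ``F_IS``
    the global ratio ``1 - sum(H_O) / sum(H_E)`` over sites with
    ``H_E > 0``.
    """
    if groups is None:
        groups = gm.sample_meta["colony"]
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sub = gm.take_individuals(np.flatnonzero(groups == g))
        called = sub.called
        n = called.sum(axis=0)
        if n.sum() == 0:
            warnings.warn(f"group {g!r} has no called genotypes; excluded")
            continue
        het = (sub.genotypes == 1).sum(axis=0)
        ok = n > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = het[ok] / n[ok]
            p = np.where(ok, sub.alt_freq(), np.nan)[ok]
            he = 2.0 * p * (1 - p) * (2 * n[ok]) / (2 * n[ok] - 1)
        pos = he > 0
        fis = 1.0 - ho[pos].sum() / he[pos].sum() if pos.any() else np.nan
        rows.append(
            {
                "group": g,
                "n": int((groups == g).sum()),
                "H_O": float(ho.mean()),
                "H_E": float(he.mean()),
                "F_IS": float(fis),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    values: np.ndarray
    groups: list
    coords: pd.DataFrame | None = None  # group, lat, lon

    def linearized(self) -> np.ndarray:
        """Rousset's transform F_ST / (1 - F_ST)."""
        return self.values / (1.0 - self.values)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=self.groups)

    def mean_offdiag(self) -> float:
        n = len(self.groups)
        iu = np.triu_indices(n, k=1)
        return float(np.nanmean(self.values[iu]))


def _wc_theta_components(n1, p1, h1, n2, p2, h2):
    """Per-site Weir-Cockerham (1984) variance components for two demes.

    Arrays of per-site called sample sizes, ALT frequencies and observed
    heterozygote fractions per deme; returns (a, b, c) arrays.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    ok = (nbar > 1) & (n1 > 0) & (n2 > 0)
    n1, p1, h1, n2, p2, h2, nbar = (
        x[ok] for x in (n1, p1, h1, n2, p2, h2, nbar)
    )
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, groups=None, min_n: int = 3) -> FstMatrix:
    """Pairwise Weir-Cockerham theta (ratio of sums over sites) between
    groups with at least ``min_n`` individuals.  Slightly negative values
    are a known property of the estimator and are kept."""
    if groups is None:
        groups = gm.sample_meta["colony"]
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= min_n]
    if len(labels) < 2:
        raise ValueError("need at least two groups passing min_n")
    per_group = {}
    for g in labels:
        sub = gm.take_individuals(np.flatnonzero(groups == g))
        n = sub.called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, sub.alt_counts() / (2 * n), 0.0)
            h = np.where(n > 0, (sub.genotypes == 1).sum(axis=0) / n, 0.0)
        per_group[g] = (n, p, h)
    k = len(labels)
    fst = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c = _wc_theta_components(*per_group[labels[i]], *per_group[labels[j]])
            denom = (a + b + c).sum()
            fst[i, j] = fst[j, i] = a.sum() / denom if denom > 0 else np.nan
    coords = None
    if {"lat", "lon", "colony"} <= set(gm.sample_meta.columns):
        coords = (
            gm.sample_meta.groupby("colony")[["lat", "lon"]]
            .mean()
            .loc[labels]
            .reset_index()
            .rename(columns={"colony": "group"})
        )
    return FstMatrix(fst, labels, coords)


# ---------------------------------------------------------------------------
# Tajima's D with missing data
# ---------------------------------------------------------------------------


@dataclass
class TajimaResult:
    d: float
    ci_low: float
    ci_high: float
    p: float
    n_sims: int
    s: int


@lru_cache(maxsize=None)
def _tajima_constants(n: float):
    # allow non-integer harmonic-mean n by interpolating the a1/a2 sums
    def harm(power, x):
        ii = np.arange(1, int(np.floor(x)))
        s = np.sum(1.0 / ii**power)
        frac = x - np.floor(x)
        if frac > 0:
            s += frac / np.floor(x) ** power
        return s

    a1 = harm(1, n)
    a2 = harm(2, n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _a1_per_site(n_i: np.ndarray) -> np.ndarray:
    out = np.empty(len(n_i))
    for v in np.unique(n_i):
        out[n_i == v] = _tajima_constants(float(v))[0]
    return out


def _d_from_site_arrays(n_i: np.ndarray, k_i: np.ndarray) -> float:
    pi = (2.0 * k_i * (n_i - k_i)) / (n_i * (n_i - 1))
    theta_w = np.sum(1.0 / _a1_per_site(n_i))
    s = len(n_i)
    n_harm = len(n_i) / np.sum(1.0 / n_i)
    _, e1, e2 = _tajima_constants(n_harm)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi.sum() - theta_w) / np.sqrt(var))


def tajimas_d(
    gm: GenotypeMatrix,
    n_sims: int = 1000,
    seed: int = 0,
    n_boot: int = 1000,
) -> TajimaResult:
    """Global Tajima's D, bias-corrected for missing data.

    pi and Watterson's theta accumulate per site at the site's called
    allele count ``n_i``; the variance normalization uses the classical
    constants evaluated at the harmonic-mean ``n``, so with complete data
    the statistic reduces exactly to the textbook formula.  The CI is a
    bootstrap over sites; the p-value is the fraction of ``n_sims``
    neutral constant-size datasets (matched S, matched n profile, site
    frequencies from the 1/k law) with ``|D| >= |observed|``.
    """
    if gm.n_individuals < 2:
        raise ValueError("Tajima's D needs at least four sampled alleles")
    n_i = gm.allele_numbers().astype(float)
    k_i = gm.alt_counts().astype(float)
    seg = (k_i > 0) & (k_i < n_i) & (n_i >= 4)
    if not seg.any():
        raise ValueError("no segregating sites")
    n_i, k_i = n_i[seg], k_i[seg]
    d = _d_from_site_arrays(n_i, k_i)

    rng = np.random.default_rng(seed)
    s = len(n_i)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(s, size=s)
        boots[b] = _d_from_site_arrays(n_i[idx], k_i[idx])
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])

    # neutral null: per-site minor... derived allele count ~ P(k) prop. 1/k
    hits = 0
    for _ in range(n_sims):
        k_sim = np.empty(s)
        for n_val in np.unique(n_i):
            m = n_i == n_val
            kk = np.arange(1, int(n_val))
            pr = (1.0 / kk) / np.sum(1.0 / kk)
            k_sim[m] = rng.choice(kk, size=int(m.sum()), p=pr)
        if abs(_d_from_site_arrays(n_i, k_sim)) >= abs(d):
            hits += 1
    p = (hits + 1) / (n_sims + 1)
    return TajimaResult(d, float(ci_low), float(ci_high), p, n_sims, s)


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(coords: pd.DataFrame) -> np.ndarray:
    k = len(coords)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = haversine_km(
                coords["lat"].iloc[i],
                coords["lon"].iloc[i],
                coords["lat"].iloc[j],
                coords["lon"].iloc[j],
            )
    return d


def mantel_ibd(
    fst: FstMatrix,
    coords: pd.DataFrame | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    linearized: bool = False,
) -> tuple[float, float]:
    """One-sided (greater) Mantel test of genetic vs great-circle distance.

    Returns ``(r, p)``; ``linearized`` uses ``F_ST / (1 - F_ST)``.
    """
    if coords is None:
        coords = fst.coords
    if coords is None:
        raise ValueError("no coordinates available for the Mantel test")
    coords = coords.set_index("group").loc[fst.groups].reset_index()
    if len(fst.groups) < 4:
        raise ValueError("Mantel test needs at least four groups")
    gen = fst.linearized() if linearized else fst.values.copy()
    np.fill_diagonal(gen, 0.0)
    geo = geographic_distance_matrix(coords)
    iu = np.triu_indices(len(fst.groups), k=1)
    if np.allclose(gen[iu], gen[iu][0]) or np.allclose(geo[iu], geo[iu][0]):
        raise ValueError("degenerate (constant) distance matrix")
    r, p, _ = _skbio_mantel(
        DistanceMatrix(gen, ids=[str(g) for g in fst.groups]),
        DistanceMatrix(geo, ids=[str(g) for g in fst.groups]),
        method="pearson",
        permutations=n_perm,
        alternative="greater",
        seed=seed,
    )
    return float(r), float(p)
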
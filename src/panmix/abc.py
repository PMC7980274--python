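"""DIY-ABC-style sequential scenario comparison for one population.

Each scenario is a piecewise-constant demographic event structure with
priors (log-uniform on diploid sizes, uniform on event times within a
window).  Simulations run the same coalescent generator used elsewhere
in the package on RAD-like loci and are reduced to four summary
statistics: the proportion of monomorphic loci, Nei's unbiased gene
diversity (mean over polymorphic loci, variance over polymorphic loci,
and mean over all loci), each locus scored at its most variable site.

Scenario posterior probabilities come from simple rejection ("direct":
the scenario composition of the closest ``tolerance`` fraction of
simulations in standardized summary-statistic space) and from a
multinomial logistic regression of scenario labels on the statistics,
fitted on the retained set and evaluated at the observed point.  A PCA
of the simulated statistics with the observed point projected serves as
the visual "is the observation captured by any scenario" check.

The sequential ladder mirrors a hypothesis-testing workflow: first
contraction vs expansion, then one vs two contractions, then a single
contraction placed in four time windows (0-99, 100-999, 1,000-9,999,
10,000-99,999 generations ago).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .synthetic_data import simulate_locus_allele_counts

STAT_NAMES = ["prop_mono", "mean_gd_poly", "var_gd_poly", "mean_gd_all"]

TIME_WINDOWS = {
    "recent": (0, 99),
    "older": (100, 999),
    "historical": (1_000, 9_999),
    "deeply_historical": (10_000, 99_999),
}

DEFAULT_SIZE_BOUNDS = (1e2, 1e6)  # log-uniform prior on diploid sizes
DEEP_TIME_MAX = 99_999


@dataclass
class ABCScenario:
    """One demographic scenario with its priors.

    ``kind`` is ``expansion``, ``single_contraction`` or
    ``double_contraction``; ``t_window`` bounds the (most recent) event
    time Ta in generations; a second contraction time is drawn uniformly
    between Ta and ``t2_max``.
    """

    id: str
    kind: str
    t_window: tuple = (100, DEEP_TIME_MAX)
    size_bounds: tuple = DEFAULT_SIZE_BOUNDS
    t2_max: int = DEEP_TIME_MAX

    def __post_init__(self) -> None:
        if self.kind not in ("expansion", "single_contraction", "double_contraction"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        lo, hi = self.t_window
        if not lo < hi:
            raise ValueError("time window low must be < high")
        if min(self.size_bounds) <= 0:
            raise ValueError("size prior bounds must be positive")

    def draw(self, rng) -> dict:
        lo, hi = np.log10(self.size_bounds)
        ta = rng.uniform(max(self.t_window[0], 1), self.t_window[1])
        if self.kind == "double_contraction":
            n = np.sort(10.0 ** rng.uniform(lo, hi, size=3))  # n0 < n1 < n2
            ta2 = rng.uniform(ta, self.t2_max)
            return {"N0": n[0], "N1": n[1], "N2": n[2], "Ta": ta, "Ta2": ta2}
        a, b = np.sort(10.0 ** rng.uniform(lo, hi, size=2))
        if self.kind == "single_contraction":
            return {"N0": a, "N1": b, "Ta": ta}  # post < pre
        return {"N0": b, "N1": a, "Ta": ta}  # expansion: post > pre

    def epochs(self, params: dict):
        if self.kind == "double_contraction":
            return (
                (params["N0"], 0),
                (params["N1"], params["Ta"]),
                (params["N2"], params["Ta2"]),
            )
        return ((params["N0"], 0), (params["N1"], params["Ta"]))


def summary_stats_from_counts(locus_counts, n_haplotypes: int) -> dict:
    """The four per-dataset summaries from per-locus derived-allele counts."""
    n = n_haplotypes
    gds = []
    n_mono = 0
    for counts in locus_counts:
        counts = counts[(counts > 0) & (counts < n)] if len(counts) else counts
        if len(counts) == 0:
            n_mono += 1
            continue
        p = counts / n
        gd_sites = (n / (n - 1.0)) * (1.0 - p**2 - (1 - p) ** 2)
        gds.append(float(gd_sites.max()))
    gds = np.asarray(gds)
    n_loci = len(locus_counts)
    mean_poly = float(gds.mean()) if len(gds) else 0.0
    var_poly = float(gds.var(ddof=1)) if len(gds) > 1 else 0.0
    return {
        "prop_mono": n_mono / n_loci,
        "mean_gd_poly": mean_poly,
        "var_gd_poly": var_poly,
        "mean_gd_all": float(gds.sum() / n_loci),
    }


def observed_stats_from_genotypes(gm, n_loci: int = 1000, seed: int = 0) -> dict:
    """Summary statistics of a real dataset on a random subset of loci.

    Gene diversity per locus uses the locus's most variable SNP with
    sample allele frequencies from called genotypes; loci are chromosome
    labels.  Note monomorphic loci can only be counted if invariant loci
    are present in the matrix (after SNP calling they usually are not),
    so ``prop_mono`` reflects the matrix as given.
    """
    rng = np.random.default_rng(seed)
    loci = pd.factorize(gm.site_meta["chrom"])[0]
    unique = np.unique(loci)
    if n_loci < len(unique):
        unique = rng.permutation(unique)[:n_loci]
    counts_per_locus = []
    n = 2 * gm.n_individuals
    for locus in unique:
        sites = np.flatnonzero(loci == locus)
        k = gm.alt_counts()[sites]
        an = gm.allele_numbers()[sites]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, k / an, 0.0)
        counts_per_locus.append(np.round(p * n).astype(int))
    return summary_stats_from_counts(counts_per_locus, n)


def simulate_scenario(
    sc: ABCScenario,
    n_loci: int = 1000,
    n_diploids: int = 153,
    n_sims: int = 100_000,
    seed: int = 0,
    mu: float = 4.6e-9,
    locus_length: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw parameters from the priors and simulate summary statistics."""
    rng = np.random.default_rng(seed)
    n = 2 * n_diploids
    params_rows, stats_rows = [], []
    for _ in range(n_sims):
        params = sc.draw(rng)
        counts = simulate_locus_allele_counts(
            n, sc.epochs(params), mu, locus_length, n_loci, rng
        )
        params_rows.append(params)
        stats_rows.append(summary_stats_from_counts(counts, n))
    return pd.DataFrame(params_rows), pd.DataFrame(stats_rows)[STAT_NAMES]


@dataclass
class ABCResult:
    direct: dict
    logistic: dict
    retained_index: pd.DataFrame  # scenario, row
    pca_coords: pd.DataFrame  # scenario + PC1/PC2 per simulation
    observed_pc: np.ndarray
    observed_in_hull: bool = True


def abc_posterior(
    tables: dict,
    observed: dict,
    tolerance: float = 0.01,
    seed: int = 0,
) -> ABCResult:
    """Rejection and logistic-regression scenario posteriors.

    ``tables`` maps scenario id -> DataFrame of summary statistics;
    ``observed`` is a dict of the four statistics.  Statistics are
    standardized by their pooled SD before Euclidean distances.
    """
    if len(tables) < 2:
        raise ValueError("need at least two scenarios")
    labels = np.concatenate(
        [np.repeat(sid, len(df)) for sid, df in tables.items()]
    )
    X = np.vstack([df[STAT_NAMES].to_numpy(float) for df in tables.values()])
    obs = np.array([observed[k] for k in STAT_NAMES], float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    z_obs = (obs - mu) / sd

    dist = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(Z))), len(tables))
    order = np.argsort(dist, kind="stable")
    kept = order[:n_keep]
    kept_labels = labels[kept]
    ids = list(tables.keys())
    direct = {sid: float(np.mean(kept_labels == sid)) for sid in ids}

    if len(np.unique(kept_labels)) > 1:
        lr = LogisticRegression(max_iter=2000, C=1.0)
        lr.fit(Z[kept], kept_labels)
        prob = lr.predict_proba(z_obs[None, :])[0]
        logistic = {sid: 0.0 for sid in ids}
        for sid, pr in zip(lr.classes_, prob):
            logistic[sid] = float(pr)
    else:
        logistic = dict(direct)

    pca = PCA(n_components=2).fit(Z)
    coords = pca.transform(Z)
    obs_pc = pca.transform(z_obs[None, :])[0]
    in_hull = True
    try:
        tri = Delaunay(coords)
        in_hull = bool(tri.find_simplex(obs_pc) >= 0)
    except QhullError:  # degenerate cloud
        in_hull = False
    if not in_hull:
        warnings.warn("observed statistics not captured by the scenarios (PC1-2)")
    pca_df = pd.DataFrame({"scenario": labels, "PC1": coords[:, 0], "PC2": coords[:, 1]})
    retained = pd.DataFrame({"scenario": kept_labels, "row": kept})
    return ABCResult(direct, logistic, retained, pca_df, obs_pc, in_hull)


@dataclass
class LadderRound:
    name: str
    scenarios: list
    result: ABCResult
    winner: str


def scenario_ladder(
    observed: dict,
    seed: int = 0,
    n_sims: int = 100_000,
    n_loci: int = 1000,
    n_diploids: int = 153,
    tolerance: float = 0.01,
    mu: float = 4.6e-9,
    locus_length: int = 100,
) -> list[LadderRound]:
    """Sequential scenario comparison.

    Round 1: contraction vs expansion; round 2: single vs double
    contraction; round 3: single contraction in four time windows.  The
    ladder follows the winner: if expansion or a double contraction wins
    a round, it stops there and reports.
    """
    rng = np.random.default_rng(seed)
    sim_kwargs = dict(
        n_loci=n_loci, n_diploids=n_diploids, n_sims=n_sims,
        mu=mu, locus_length=locus_length,
    )

    def run_round(name, scenarios):
        tables = {
            sc.id: simulate_scenario(sc, seed=int(rng.integers(2**31 - 1)),
                                     **sim_kwargs)[1]
            for sc in scenarios
        }
        res = abc_posterior(tables, observed, tolerance=tolerance,
                            seed=int(rng.integers(2**31 - 1)))
        winner = max(res.direct, key=res.direct.get)
        return LadderRound(name, scenarios, res, winner)

    rounds = [
        run_round(
            "contraction_vs_expansion",
            [
                ABCScenario("contraction", "single_contraction"),
                ABCScenario("expansion", "expansion"),
            ],
        )
    ]
    if rounds[-1].winner != "contraction":
        return rounds
    rounds.append(
        run_round(
            "single_vs_double",
            [
                ABCScenario("single", "single_contraction"),
                ABCScenario("double", "double_contraction"),
            ],
        )
    )
    if rounds[-1].winner != "single":
        return rounds
    rounds.append(
        run_round(
            "contraction_timing",
            [
                ABCScenario(name, "single_contraction", t_window=window)
                for name, window in TIME_WINDOWS.items()
            ],
        )
    )
    return rounds
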
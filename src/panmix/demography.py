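"""Single-population demographic inference from the folded SFS.

Models are nested piecewise-constant (epoch) histories of one population:

* ``one_epoch`` — constant size, no parameters;
* ``two_epoch`` — an instantaneous change to ``nu`` (size relative to the
  ancestral size) ``T`` coalescent time units ago (1 unit = 2*Ne_anc
  generations);
* ``three_epoch`` — two changes: ancestral -> ``nu1`` for ``T1``, then
  ``nu2`` for ``T2`` up to the present.

The expected folded SFS is computed two ways, and the two backends serve
as mutual cross-checks:

* **analytic** — exact coalescent expectations.  Under any demography the
  expected number of sites at unfolded frequency ``j`` of ``m`` is
  ``(theta/2) * sum_k k E[T_k] P(j | k, m)`` with
  ``P(j|k,m) = C(m-j-1, k-2) / C(m-1, k-1)`` and ``E[T_k]`` the expected
  time during which ``k`` ancestral lineages exist.  ``E[T_k]`` is
  obtained by integrating the lineage-count (pure-death) process across
  epochs with a matrix-exponential occupancy computation, which is
  numerically robust where the classical spectral (Tavare) formula is not.
  At ``theta = 1`` the constant-size model gives the textbook ``1/j`` law.
* **mc** — Monte-Carlo over simulated genealogies (interval times by
  time-rescaled exponentials, topologies by random Kingman merges) with
  branch-length-weighted mutation placement.  A fixed seed reuses the same
  genealogies across parameter evaluations (common random numbers), so the
  likelihood surface seen by the optimizer is smooth.

Fitting maximizes the multinomial log-likelihood of the observed folded
spectrum (masked bins excluded; the additive ``log S! / prod x_j!`` term
is omitted) with a derivative-free simplex on log10 parameters from many
random starts.  theta enters only through the analytically-profiled
``theta_hat = sum(x) / sum(M)``.  Because SNPs on a RAD locus are linked,
this is a composite likelihood: point estimates are consistent but the
chi-square LRT is anti-conservative in principle; it is retained as the
field-standard procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

from .sfs import FoldedSFS, fold

DEFAULT_MU = 4.6e-9  # per-site per-generation, songbird pedigree estimate
DEFAULT_G = 2.0  # generation time, years
DEFAULT_L = 60_429_389  # callable sequence length, bp

MODEL_NPARAMS = {"one_epoch": 0, "two_epoch": 2, "three_epoch": 4}

# optimizer search box (log-uniform starts; hard bounds slightly wider)
NU_START_BOUNDS = (1e-3, 1e2)
T_START_BOUNDS = (1e-4, 5.0)
NU_HARD_BOUNDS = (1e-4, 1e3)
T_HARD_BOUNDS = (1e-5, 10.0)


@dataclass
class EpochModel:
    """A nested epoch history; ``params`` in coalescent units."""

    kind: str
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in MODEL_NPARAMS:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        self.params = tuple(float(p) for p in self.params)
        if len(self.params) != MODEL_NPARAMS[self.kind]:
            raise ValueError(
                f"{self.kind} takes {MODEL_NPARAMS[self.kind]} parameters"
            )
        if any(p <= 0 for p in self.params):
            raise ValueError("epoch parameters must be positive")

    def epochs_backward(self) -> list[tuple[float, float]]:
        """Epochs as (relative size, duration) from the present backwards;
        the terminal ancestral epoch has size 1 and infinite duration."""
        if self.kind == "one_epoch":
            return [(1.0, np.inf)]
        if self.kind == "two_epoch":
            nu, T = self.params
            return [(nu, T), (1.0, np.inf)]
        nu1, T1, nu2, T2 = self.params
        return [(nu2, T2), (nu1, T1), (1.0, np.inf)]


# ---------------------------------------------------------------------------
# analytic backend
# ---------------------------------------------------------------------------


def _death_generator(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Generator of the standard-rate lineage-count chain on states 1..m."""
    lam = np.array([k * (k - 1) / 2.0 for k in range(1, m + 1)])
    Q = np.diag(-lam)
    for k in range(2, m + 1):
        Q[k - 2, k - 1] = lam[k - 1]
    return Q, lam


def expected_interval_times(epochs: list[tuple[float, float]], m: int) -> np.ndarray:
    """``E[T_k]`` (index ``k-1``) in coalescent units for ``m`` lineages
    under a piecewise-constant history given backwards in time."""
    Q, lam = _death_generator(m)
    # block matrix exponential gives both e^{Qs} and its time integral
    B = np.zeros((2 * m, 2 * m))
    B[:m, :m] = Q
    B[:m, m:] = np.eye(m)
    p = np.zeros(m)
    p[m - 1] = 1.0
    ET = np.zeros(m)
    for nu, dur in epochs[:-1]:
        s = dur / nu  # epoch duration in rescaled (standard) time
        E = expm(B * s)
        ET += nu * (E[:m, m:] @ p)
        p = E[:m, :m] @ p
    nu_last = epochs[-1][0]
    # death chain visits every state below its entry point exactly once
    surv = np.cumsum(p[::-1])[::-1]  # P(lineage count >= k) at entry
    ET[1:] += nu_last * surv[1:] / lam[1:]
    return ET


def _branch_subtend_probs(m: int) -> np.ndarray:
    """``P[j-1, k-2] = P(branch subtends j of m tips | k lineages)``."""
    j = np.arange(1, m)[:, None]
    k = np.arange(2, m + 1)[None, :]
    logp = (
        gammaln(m - j)
        - gammaln(k - 1)
        - gammaln(m - j - k + 2)
        - (gammaln(m) - gammaln(k) - gammaln(m - k + 1))
    )
    with np.errstate(invalid="ignore"):
        p = np.where(m - j - k + 2 > 0, np.exp(logp), 0.0)
    return p


def expected_sfs_analytic(model: EpochModel, m: int) -> FoldedSFS:
    """Expected folded SFS at ``theta = 1`` (so one_epoch gives 1/j
    unfolded); bin 0 is zero and masked."""
    if m < 4 or m % 2:
        raise ValueError("m must be even and >= 4")
    ET = expected_interval_times(model.epochs_backward(), m)
    P = _branch_subtend_probs(m)
    k = np.arange(2, m + 1)
    unfolded = 0.5 * (P * (k * ET[1:])[None, :]).sum(axis=1)  # j = 1..m-1
    full = np.concatenate([[0.0], unfolded, [0.0]])
    return FoldedSFS(fold(full), m=m)


# ---------------------------------------------------------------------------
# Monte-Carlo backend (common random numbers)
# ---------------------------------------------------------------------------


class MonteCarloSFS:
    """Genealogy-simulation estimator of the expected folded SFS.

    Simulates ``n_sims`` Kingman genealogies for ``m`` tips once (standard
    exponential interval variates plus random-merge topologies) and reuses
    them for every parameter evaluation: a piecewise-constant history only
    rescales the interval times, and mutations are placed in proportion to
    branch length, so the expected spectrum is
    ``mean_sims 0.5 * sum_k T_k(params) * (#branches subtending j)``.
    """

    def __init__(self, m: int, n_sims: int = 100_000, seed: int = 0):
        if n_sims < 1000:
            raise ValueError("n_sims must be >= 1000")
        if m < 4 or m % 2:
            raise ValueError("m must be even and >= 4")
        self.m = m
        self.n_sims = n_sims
        self.seed = seed
        rng = np.random.default_rng(seed)
        lam = np.array([k * (k - 1) / 2.0 for k in range(m, 1, -1)])
        # standard-time interval waits, state order k = m, m-1, ..., 2
        self._std_cum = np.cumsum(
            rng.exponential(1.0 / lam, size=(n_sims, m - 1)), axis=1
        )
        # topology: count of branches subtending j tips during interval i
        A = np.zeros((n_sims, m - 1, m - 1), dtype=np.uint8)
        u1 = rng.random((n_sims, m - 1))
        u2 = rng.random((n_sims, m - 1))
        for s in range(n_sims):
            sizes = [1] * m
            for i in range(m - 1):
                k = m - i
                A[s, i, :] = np.bincount(sizes, minlength=m)[1:m]
                a = int(u1[s, i] * k)
                b = int(u2[s, i] * (k - 1))
                if b >= a:
                    b += 1
                sizes[a] += sizes[b]
                del sizes[b]
        self._A = A.astype(np.float32)

    def _interval_times(self, model: EpochModel) -> np.ndarray:
        """Map the fixed standard-time variates through the inverse
        time-rescaling of ``model`` -> actual interval lengths."""
        epochs = model.epochs_backward()
        if len(epochs) == 1:
            return np.diff(self._std_cum, axis=1, prepend=0.0)
        nus = np.array([nu for nu, _ in epochs])
        durs = np.array([d for _, d in epochs[:-1]])
        tau_b = np.concatenate([[0.0], np.cumsum(durs)])
        s_b = np.concatenate([[0.0], np.cumsum(durs / nus[:-1])])
        s = self._std_cum
        tau = np.interp(s, s_b, tau_b)
        tail = s > s_b[-1]
        if np.any(tail):
            tau = np.where(tail, tau_b[-1] + (s - s_b[-1]) * nus[-1], tau)
        return np.diff(tau, axis=1, prepend=0.0)

    def expected_sfs(self, model: EpochModel, with_se: bool = False):
        T = self._interval_times(model).astype(np.float32)
        per_sim = 0.5 * np.einsum("si,sij->sj", T, self._A)  # unfolded j=1..m-1
        mean = per_sim.mean(axis=0, dtype=np.float64)
        full = np.concatenate([[0.0], mean, [0.0]])
        out = FoldedSFS(fold(full), m=self.m)
        if not with_se:
            return out
        m = self.m
        folded_sims = np.concatenate(
            [
                np.zeros((self.n_sims, 1), dtype=np.float32),
                per_sim[:, : m // 2 - 1] + per_sim[:, : m // 2 - 1 : -1],
                per_sim[:, m // 2 - 1 : m // 2],
            ],
            axis=1,
        )
        se = folded_sims.std(axis=0, dtype=np.float64) / np.sqrt(self.n_sims)
        return out, se


def expected_sfs_mc(
    model: EpochModel, m: int, n_sims: int = 100_000, seed: int = 0
) -> FoldedSFS:
    """One-shot Monte-Carlo expected folded SFS (theta = 1)."""
    return MonteCarloSFS(m, n_sims=n_sims, seed=seed).expected_sfs(model)


# ---------------------------------------------------------------------------
# likelihood, fitting, model comparison
# ---------------------------------------------------------------------------


def multinomial_ll(data: FoldedSFS, model_sfs: FoldedSFS) -> tuple[float, float]:
    """Multinomial log-likelihood (constant omitted) and profiled theta.

    ``p_j = M_j / sum M`` over unmasked bins; ``LL = sum x_j log p_j``;
    ``theta_hat = sum x_j / sum M_j`` with the model spectrum at theta=1.
    """
    if data.m != model_sfs.m or not np.array_equal(data.mask, model_sfs.mask):
        raise ValueError("data and model spectra must share m and mask")
    x = data.counts[~data.mask]
    M = model_sfs.counts[~model_sfs.mask]
    total = M.sum()
    if total <= 0:
        raise ValueError("model spectrum has no unmasked mass")
    theta_hat = float(x.sum() / total)
    bad = (M <= 0) & (x > 0)
    if bad.any():
        warnings.warn("model assigns zero mass to an occupied bin; LL = -inf")
        return -np.inf, theta_hat
    p = M / total
    with np.errstate(divide="ignore"):
        terms = np.where(x > 0, x * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum()), theta_hat


@dataclass
class FitResult:
    model: EpochModel
    ll: float
    theta_hat: float
    replicates: list = field(default_factory=list)  # (params, LL) per start
    converged: bool = True
    backend: str = "analytic"


def _make_backend(backend, m: int, mc_sims: int, seed: int):
    if callable(backend):
        return backend, "custom"
    if backend == "analytic":
        return (lambda model: expected_sfs_analytic(model, m)), "analytic"
    if backend == "mc":
        mc = MonteCarloSFS(m, n_sims=mc_sims, seed=seed)
        return mc.expected_sfs, "mc"
    raise ValueError(f"unknown backend {backend!r}")


def fit_model(
    data: FoldedSFS,
    kind: str,
    backend: str = "analytic",
    n_starts: int = 50,
    seed: int = 0,
    mc_sims: int = 100_000,
    extra_starts: list | None = None,
    maxiter: int = 400,
) -> FitResult:
    """Maximum-likelihood fit of an epoch model to a folded spectrum.

    ``n_starts`` Nelder-Mead runs on log10 parameters from log-uniform
    random starts (``nu`` in [1e-3, 1e2], ``T`` in [1e-4, 5]); the best
    replicate is the MLE and every replicate is retained.  ``extra_starts``
    prepends deterministic starting points (e.g. a simpler model's MLE) to
    the random ones.
    """
    npar = MODEL_NPARAMS[kind]
    expected, backend_name = _make_backend(backend, data.m, mc_sims, seed)

    if npar == 0:
        ll, theta = multinomial_ll(data, expected(EpochModel("one_epoch")))
        return FitResult(
            EpochModel("one_epoch"), ll, theta, [((), ll)], True, backend_name
        )

    lo = np.log10([NU_START_BOUNDS[0], T_START_BOUNDS[0]] * (npar // 2))
    hi = np.log10([NU_START_BOUNDS[1], T_START_BOUNDS[1]] * (npar // 2))
    hard_lo = np.log10([NU_HARD_BOUNDS[0], T_HARD_BOUNDS[0]] * (npar // 2))
    hard_hi = np.log10([NU_HARD_BOUNDS[1], T_HARD_BOUNDS[1]] * (npar // 2))

    def neg_ll(logp: np.ndarray) -> float:
        if np.any(logp < hard_lo) or np.any(logp > hard_hi):
            return 1e12
        ll, _ = multinomial_ll(data, expected(EpochModel(kind, 10.0 ** logp)))
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    starts = [np.log10(np.asarray(p, float)) for p in (extra_starts or [])]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - len(starts))]

    replicates = []
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        params = tuple(10.0 ** res.x)
        ll = -res.fun
        replicates.append((params, ll))
        if ll > -1e11:
            any_ok = True
        if best is None or ll > best[1]:
            best = (params, ll, bool(res.success))
    if not any_ok:
        raise RuntimeError(
            f"all {len(starts)} optimization starts failed for {kind}"
        )
    params, ll, ok = best
    model = EpochModel(kind, params)
    _, theta = multinomial_ll(data, expected(model))
    return FitResult(model, ll, theta, replicates, ok, backend_name)


def lrt(simple: FitResult, complex: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested epoch models.

    Returns ``(Lambda, df, p)`` with ``Lambda = 2 (LL_c - LL_s)`` and the
    chi-square survival p-value (for df=2, ``p = exp(-Lambda/2)``).
    """
    order = ["one_epoch", "two_epoch", "three_epoch"]
    df = MODEL_NPARAMS[complex.model.kind] - MODEL_NPARAMS[simple.model.kind]
    if (
        order.index(complex.model.kind) <= order.index(simple.model.kind)
        or df <= 0
    ):
        raise ValueError("models are not a nested simple/complex pair")
    stat = 2.0 * (complex.ll - simple.ll)
    if stat < 0:
        warnings.warn(
            "complex model fits worse than simple one; re-optimization advised"
        )
        stat = 0.0
    return stat, df, float(chi2.sf(stat, df))


@dataclass
class ScaledEstimates:
    """Epoch parameters converted to diploids, generations and years."""

    mu: float
    g: float
    L: float
    theta_hat: float
    ne_anc: float
    epoch_sizes: dict
    times_generations: dict
    times_years: dict

    @property
    def ne_lt(self) -> float:
        """Most recent (long-term / post-change) epoch size in diploids."""
        for key in ("nu2", "nu"):
            if key in self.epoch_sizes:
                return self.epoch_sizes[key]
        return self.ne_anc


def scale_estimates(
    fit: FitResult,
    mu: float = DEFAULT_MU,
    g: float = DEFAULT_G,
    L: float = DEFAULT_L,
) -> ScaledEstimates:
    """Physical-unit conversion: ``Ne_anc = theta / (4 mu L)``, sizes
    ``nu * Ne_anc``, times ``2 Ne_anc * T`` generations (``* g`` years)."""
    if mu <= 0 or g <= 0 or L <= 0:
        raise ValueError("mu, g and L must be positive")
    ne_anc = fit.theta_hat / (4.0 * mu * L)
    names = {
        "one_epoch": (),
        "two_epoch": ("nu", "T"),
        "three_epoch": ("nu1", "T1", "nu2", "T2"),
    }[fit.model.kind]
    sizes, tg, ty = {}, {}, {}
    for name, value in zip(names, fit.model.params):
        if name.startswith("nu"):
            sizes[name] = value * ne_anc
        else:
            tg[name] = 2.0 * ne_anc * value
            ty[name] = 2.0 * ne_anc * value * g
    return ScaledEstimates(mu, g, L, fit.theta_hat, ne_anc, sizes, tg, ty)


@dataclass
class GridSurface:
    nu_grid: np.ndarray
    T_grid: np.ndarray
    delta_ll: np.ndarray  # (len(nu_grid), len(T_grid)), LL(MLE) - LL(point)
    mle: tuple  # (nu, T, LL)
    five_unit_ranges: dict  # {"nu": (lo, hi), "T": (lo, hi)}
    open_ranges: bool = False


def grid_search(
    data: FoldedSFS,
    backend: str = "analytic",
    nu_bounds: tuple = (1e-2, 10.0),
    T_bounds: tuple = (1e-3, 1.0),
    n: int = 100,
    fit: FitResult | None = None,
    seed: int = 0,
    mc_sims: int = 100_000,
) -> GridSurface:
    """Log10-even ``n x n`` likelihood surface for the two-epoch model,
    with parameter intervals within 5 log-likelihood units of the MLE."""
    expected, _ = _make_backend(backend, data.m, mc_sims, seed)
    if fit is None:
        fit = fit_model(data, "two_epoch", backend=backend, seed=seed, mc_sims=mc_sims)
    if fit.model.kind != "two_epoch":
        raise ValueError("grid_search applies to the two_epoch model only")
    nu_grid = np.logspace(np.log10(nu_bounds[0]), np.log10(nu_bounds[1]), n)
    T_grid = np.logspace(np.log10(T_bounds[0]), np.log10(T_bounds[1]), n)
    ll = np.empty((n, n))
    for i, nu in enumerate(nu_grid):
        for j, T in enumerate(T_grid):
            ll[i, j], _ = multinomial_ll(
                data, expected(EpochModel("two_epoch", (nu, T)))
            )
    delta = fit.ll - ll
    delta = np.maximum(delta, 0.0)
    inside = delta <= 5.0
    open_ranges = False
    nu_mle, T_mle = fit.model.params
    if not (nu_bounds[0] <= nu_mle <= nu_bounds[1]) or not (
        T_bounds[0] <= T_mle <= T_bounds[1]
    ):
        warnings.warn("MLE lies outside the grid bounds; ranges are open")
        open_ranges = True
    if inside.any():
        nus = nu_grid[inside.any(axis=1)]
        Ts = T_grid[inside.any(axis=0)]
        ranges = {
            "nu": (float(nus.min()), float(nus.max())),
            "T": (float(Ts.min()), float(Ts.max())),
        }
        if (
            nus.min() == nu_grid[0]
            or nus.max() == nu_grid[-1]
            or Ts.min() == T_grid[0]
            or Ts.max() == T_grid[-1]
        ):
            open_ranges = True
    else:
        ranges = {"nu": (np.nan, np.nan), "T": (np.nan, np.nan)}
        open_ranges = True
    return GridSurface(nu_grid, T_grid, delta, (nu_mle, T_mle, fit.ll), ranges, open_ranges)
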
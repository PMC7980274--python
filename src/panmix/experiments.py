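"""Parameter-recovery experiments at desk scale.

The empirical estimates this package is organized around — a ~50%
contraction of a large songbird population ~21,000 generations ago
(Ne_anc ~174,000 -> Ne_lt ~91,000) and a contemporary LD-based Ne of
~3,100 — cannot be recomputed without the original RAD-Seq data.  What
can be verified is the machinery: simulate data under exactly those
published point estimates, run the inference, and check the truth is
recovered.  These experiments are shared by the test suite, the
acceptance script, and the analysis drivers.

Scales are deliberately desk-sized: the SFS experiments use a 10 Mb
callable length instead of the study's 60.4 Mb (about 120k SNPs instead
of 700k), and the Wright-Fisher experiment uses ~1,500 unlinked SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import (
    DEFAULT_MU,
    EpochModel,
    FitResult,
    expected_sfs_analytic,
    fit_model,
    lrt,
    scale_estimates,
)
from .ld_ne import ld_ne
from .sfs import FoldedSFS
from .synthetic_data import WFConfig, simulate_wright_fisher

# published two-epoch point estimates (diffusion fit / coalescent fit)
STUDY_NE_ANC = 174_455
STUDY_NE_LT = 91_315
STUDY_T_GEN = 21_317
STUDY_NE_ANC_COAL = 174_617
STUDY_NE_LT_COAL = 90_941
STUDY_T_GEN_COAL = 20_144
STUDY_CURRENT_NE = 3_100

TRUE_NU = STUDY_NE_LT / STUDY_NE_ANC  # ~0.523
TRUE_T = STUDY_T_GEN / (2 * STUDY_NE_ANC)  # ~0.0611


def study_truth_model() -> EpochModel:
    return EpochModel("two_epoch", (TRUE_NU, TRUE_T))


def simulate_study_sfs(
    seed: int,
    m: int = 38,
    L: float = 1e7,
    mu: float = DEFAULT_MU,
    ne_anc: float = STUDY_NE_ANC,
    model: EpochModel | None = None,
) -> FoldedSFS:
    """Simulate a folded SFS of unlinked sites under the study history.

    The expected spectrum at ``theta = 4 Ne_anc mu L`` is Poisson-sampled
    bin by bin — the sampling distribution of an SFS of independent
    sites (a parametric bootstrap of the fitted history).
    """
    model = model or study_truth_model()
    rng = np.random.default_rng(seed)
    theta = 4.0 * ne_anc * mu * L
    expected = expected_sfs_analytic(model, m)
    counts = expected.counts * theta
    counts[~expected.mask] = rng.poisson(counts[~expected.mask])
    counts[expected.mask] = 0.0
    return FoldedSFS(counts, m=m, mask=expected.mask)


@dataclass
class RecoveryRun:
    fit_one: FitResult
    fit_two: FitResult
    fit_three: FitResult | None
    ne_anc_hat: float
    ne_lt_hat: float
    t_gen_hat: float
    nu_hat: float
    p_one_vs_two: float
    p_two_vs_three: float | None


def two_epoch_recovery(
    n_reps: int = 10,
    seed: int = 1,
    m: int = 38,
    L: float = 1e7,
    mu: float = DEFAULT_MU,
    n_starts: int = 50,
    fit_three_epoch: bool = True,
    n_starts_three: int = 15,
    backend: str = "analytic",
    mc_sims: int = 10_000,
) -> pd.DataFrame:
    """Simulate-and-refit replicates of the published two-epoch history.

    Per replicate: draw an SFS under the truth, fit the one- and
    two-epoch models (and optionally the three-epoch model, seeded with
    the two-epoch MLE so the nesting inequality holds), and scale the
    MLE to diploids and generations.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep_seed in ss.spawn(n_reps):
        data_seed, fit_seed = rep_seed.generate_state(2) >> 1  # keep < 2^31
        data = simulate_study_sfs(int(data_seed), m=m, L=L, mu=mu)
        fit1 = fit_model(data, "one_epoch", backend=backend, mc_sims=mc_sims,
                         seed=int(fit_seed))
        fit2 = fit_model(
            data, "two_epoch", backend=backend, n_starts=n_starts,
            seed=int(fit_seed), mc_sims=mc_sims,
        )
        _, _, p12 = lrt(fit1, fit2)
        p23 = None
        fit3 = None
        if fit_three_epoch:
            nu, T = fit2.model.params
            fit3 = fit_model(
                data,
                "three_epoch",
                backend=backend,
                n_starts=n_starts_three,
                seed=int(fit_seed) + 1,
                mc_sims=mc_sims,
                extra_starts=[(nu, T / 2, nu, T / 2)],
            )
            _, _, p23 = lrt(fit2, fit3)
        scaled = scale_estimates(fit2, mu=mu, L=L)
        rows.append(
            {
                "ne_anc_hat": scaled.ne_anc,
                "ne_lt_hat": scaled.ne_lt,
                "t_gen_hat": scaled.times_generations["T"],
                "nu_hat": fit2.model.params[0],
                "T_hat": fit2.model.params[1],
                "theta_hat": fit2.theta_hat,
                "ll_one": fit1.ll,
                "ll_two": fit2.ll,
                "ll_three": fit3.ll if fit3 else np.nan,
                "p_one_vs_two": p12,
                "p_two_vs_three": p23 if p23 is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def wf_ldne_recovery(
    n_reps: int = 10,
    seed: int = 1,
    ne: int = STUDY_CURRENT_NE,
    n_loci: int = 2500,
    generations: int = 60,
    n_sampled: int = 132,
    maf: float = 0.01,
) -> pd.DataFrame:
    """Forward Wright-Fisher populations at the published contemporary
    Ne, sampled like the adult cohort, estimated with the LD method."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep_seed in ss.spawn(n_reps):
        s1, s2 = rep_seed.generate_state(2) >> 1
        gm = simulate_wright_fisher(
            WFConfig(ne=ne, n_loci=n_loci, generations=generations,
                     n_sampled=n_sampled, seed=int(s1))
        )
        res = ld_ne(gm, maf=maf, seed=int(s2))
        rows.append(
            {
                "ne_hat": res.ne_hat,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "mean_r2": res.mean_r2,
                "r2_drift": res.r2_drift,
                "n_snps": res.n_snps,
            }
        )
    return pd.DataFrame(rows)


def mu_rescaling_factor(mu_ref: float = DEFAULT_MU, mu_alt: float = 4.598e-10):
    """Scale factor on Ne and time-in-generations when re-scaling the
    same fit with a different mutation rate (Ne ~ 1/mu exactly)."""
    fit = FitResult(study_truth_model(), ll=0.0, theta_hat=1.0)
    a = scale_estimates(fit, mu=mu_ref, L=1e7)
    b = scale_estimates(fit, mu=mu_alt, L=1e7)
    return (
        b.ne_lt / a.ne_lt,
        b.times_generations["T"] / a.times_generations["T"],
    )
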
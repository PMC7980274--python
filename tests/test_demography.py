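"""Expected-SFS backends, multinomial likelihood, fitting, LRT, scaling."""

import numpy as np
import pytest

from panmix.demography import (
    EpochModel,
    MonteCarloSFS,
    expected_interval_times,
    expected_sfs_analytic,
    fit_model,
    grid_search,
    lrt,
    multinomial_ll,
    scale_estimates,
)
from panmix.experiments import simulate_study_sfs
from panmix.sfs import FoldedSFS, fold


def folded_one_over_j(m):
    unf = np.concatenate([[0.0], 1.0 / np.arange(1, m), [0.0]])
    return fold(unf)


def test_one_epoch_is_one_over_j_law():
    sfs = expected_sfs_analytic(EpochModel("one_epoch"), 4)
    assert np.allclose(sfs.counts, [0.0, 4 / 3, 1 / 2])
    big = expected_sfs_analytic(EpochModel("one_epoch"), 38)
    assert np.max(np.abs(big.counts - folded_one_over_j(38))) < 1e-8


@pytest.mark.parametrize("T", [0.01, 0.3, 2.0])
def test_two_epoch_nesting_limit_at_nu_one(T):
    one = expected_sfs_analytic(EpochModel("one_epoch"), 20)
    two = expected_sfs_analytic(EpochModel("two_epoch", (1.0, T)), 20)
    assert np.max(np.abs(one.counts - two.counts)) < 1e-8


def test_interval_times_constant_size():
    """E[T_k] = 2/(k(k-1)) coalescent units for a constant population."""
    ET = expected_interval_times([(1.0, np.inf)], 10)
    k = np.arange(2, 11)
    assert np.allclose(ET[1:], 2.0 / (k * (k - 1)))


def test_mc_backend_agrees_with_analytic():
    model = EpochModel("two_epoch", (0.5, 0.25))
    mc = MonteCarloSFS(8, n_sims=20_000, seed=1)
    est, se = mc.expected_sfs(model, with_se=True)
    ana = expected_sfs_analytic(model, 8)
    z = (est.counts[1:] - ana.counts[1:]) / se[1:]
    assert np.all(np.abs(z) < 3)


def test_mc_one_epoch_small_m():
    est, se = MonteCarloSFS(4, n_sims=20_000, seed=2).expected_sfs(
        EpochModel("one_epoch"), with_se=True
    )
    assert np.all(np.abs(est.counts[1:] - [4 / 3, 0.5]) < 3 * se[1:])


def test_mc_error_scaling_with_n_sims():
    """Quadrupling the simulation count halves the standard error."""
    model = EpochModel("two_epoch", (0.5, 0.25))
    _, se1 = MonteCarloSFS(8, n_sims=5_000, seed=3).expected_sfs(model, with_se=True)
    _, se2 = MonteCarloSFS(8, n_sims=20_000, seed=4).expected_sfs(model, with_se=True)
    ratio = se2[1:].mean() / se1[1:].mean()
    assert 0.35 < ratio < 0.65


def test_multinomial_ll_best_fit_is_proportional_data():
    model = expected_sfs_analytic(EpochModel("one_epoch"), 12)
    data = FoldedSFS(model.counts * 1000.0, m=12)
    ll_true, theta = multinomial_ll(data, model)
    assert theta == pytest.approx(1000.0)
    worse = expected_sfs_analytic(EpochModel("two_epoch", (0.2, 0.1)), 12)
    ll_worse, _ = multinomial_ll(data, worse)
    assert ll_true > ll_worse


def test_multinomial_ll_zero_mass_bin():
    model = expected_sfs_analytic(EpochModel("one_epoch"), 6)
    zeroed = FoldedSFS(
        np.where(np.arange(4) == 3, 0.0, model.counts), m=6, mask=model.mask
    )
    data = FoldedSFS(np.array([0.0, 10, 5, 2]), m=6)
    with pytest.warns(UserWarning, match="zero mass"):
        ll, _ = multinomial_ll(data, zeroed)
    assert ll == -np.inf


def test_theta_hat_recovers_simulation_truth():
    theta_true = 4 * 174_455 * 4.6e-9 * 1e7
    data = simulate_study_sfs(5)
    from panmix.experiments import study_truth_model

    _, theta = multinomial_ll(data, expected_sfs_analytic(study_truth_model(), 38))
    se = np.sqrt(theta_true / expected_sfs_analytic(study_truth_model(), 38).counts.sum())
    assert abs(theta - theta_true) < 3 * se


def test_fit_one_epoch_no_optimization():
    data = FoldedSFS(folded_one_over_j(10) * 500, m=10)
    fit = fit_model(data, "one_epoch")
    ll, _ = multinomial_ll(data, expected_sfs_analytic(EpochModel("one_epoch"), 10))
    assert fit.ll == ll
    assert fit.model.params == ()


def test_fit_two_epoch_recovers_truth():
    data = simulate_study_sfs(17)
    fit = fit_model(data, "two_epoch", n_starts=15, seed=3)
    nu, T = fit.model.params
    assert nu == pytest.approx(91_315 / 174_455, rel=0.10)
    assert T == pytest.approx(21_317 / (2 * 174_455), rel=0.10)
    best_ll = max(ll for _, ll in fit.replicates)
    assert fit.ll >= best_ll - 1e-9


def test_nesting_inequality_of_maximized_lls():
    data = simulate_study_sfs(23)
    fit1 = fit_model(data, "one_epoch")
    fit2 = fit_model(data, "two_epoch", n_starts=10, seed=1)
    nu, T = fit2.model.params
    fit3 = fit_model(data, "three_epoch", n_starts=5, seed=2,
                     extra_starts=[(nu, T / 2, nu, T / 2)])
    assert fit2.ll >= fit1.ll - 1e-4
    assert fit3.ll >= fit2.ll - 1e-4


def test_model_consistency_under_simulation():
    """Data simulated from the contraction history prefers it over the
    constant-size model."""
    wins = 0
    for seed in range(5):
        data = simulate_study_sfs(100 + seed, L=1e6)
        ll1 = fit_model(data, "one_epoch").ll
        ll2 = fit_model(data, "two_epoch", n_starts=8, seed=seed).ll
        wins += ll2 > ll1
    assert wins == 5


def test_lrt_closed_form():
    from panmix.demography import FitResult

    f1 = FitResult(EpochModel("one_epoch"), -100.0, 1.0)
    f2 = FitResult(EpochModel("two_epoch", (0.5, 0.1)), -100.0, 1.0)
    stat, df, p = lrt(f1, f2)
    assert (stat, df, p) == (0.0, 2, 1.0)
    f3 = FitResult(EpochModel("two_epoch", (0.5, 0.1)), -95.0, 1.0)
    stat, df, p = lrt(f1, f3)
    assert stat == pytest.approx(10.0)
    assert p == pytest.approx(np.exp(-5.0))
    with pytest.raises(ValueError, match="nested"):
        lrt(f3, f1)


def test_scale_estimates_identities():
    from panmix.demography import FitResult

    fit = FitResult(EpochModel("two_epoch", (0.5, 0.1)), -1.0, 4.0)
    unit = scale_estimates(fit, mu=1.0, g=1.0, L=1.0)
    assert unit.ne_anc == pytest.approx(1.0)
    scaled = scale_estimates(fit, mu=4.6e-9, g=2.0, L=60_429_389)
    # exact scaling identities
    assert scaled.ne_anc * 4 * 4.6e-9 * 60_429_389 == pytest.approx(4.0)
    assert scaled.times_years["T"] == pytest.approx(
        2 * scaled.ne_anc * 0.1 * 2.0
    )
    assert scaled.ne_lt == pytest.approx(0.5 * scaled.ne_anc)


def test_mu_rescaling_is_inverse_proportional():
    from panmix.demography import FitResult

    fit = FitResult(EpochModel("two_epoch", (0.5, 0.1)), -1.0, 4.0)
    a = scale_estimates(fit, mu=4.6e-9)
    b = scale_estimates(fit, mu=4.6e-9 / 10.004)
    for x, y in [
        (b.ne_anc, a.ne_anc),
        (b.ne_lt, a.ne_lt),
        (b.times_generations["T"], a.times_generations["T"]),
    ]:
        assert x / y == pytest.approx(10.004)


def test_grid_search_surface():
    data = simulate_study_sfs(31)
    fit = fit_model(data, "two_epoch", n_starts=10, seed=7)
    surface = grid_search(
        data, nu_bounds=(0.4, 0.7), T_bounds=(0.04, 0.09), n=50, fit=fit
    )
    assert surface.delta_ll.shape == (50, 50)
    assert surface.delta_ll.min() >= 0
    # minimum sits at (or adjacent to) the grid point nearest the MLE
    i, j = np.unravel_index(surface.delta_ll.argmin(), (50, 50))
    nu_mle, T_mle, _ = surface.mle
    assert abs(np.log10(surface.nu_grid[i] / nu_mle)) < 2 * np.diff(
        np.log10(surface.nu_grid)
    )[0]
    assert abs(np.log10(surface.T_grid[j] / T_mle)) < 2 * np.diff(
        np.log10(surface.T_grid)
    )[0]
    # 5-LL-unit ranges contain the simulation truth
    assert surface.five_unit_ranges["nu"][0] < 91_315 / 174_455 < surface.five_unit_ranges["nu"][1]
    assert surface.five_unit_ranges["T"][0] < 0.0611 < surface.five_unit_ranges["T"][1]


def test_invalid_model_parameters():
    with pytest.raises(ValueError):
        EpochModel("two_epoch", (0.5,))
    with pytest.raises(ValueError):
        EpochModel("two_epoch", (-1.0, 0.1))
    with pytest.raises(ValueError):
        EpochModel("four_epoch", ())
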
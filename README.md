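# panmix

Single-population conservation-genomics analyses for range-wide SNP
datasets: is a declining species still one randomly mating population,
and what do its genomes say about the history and present size of that
population?

The package reimplements, as a tested pipeline over synthetic data, the
analysis battery used for RAD-Seq studies of threatened birds such as
the tricolored-blackbird system it is modeled on:

* **Panmixia battery** — KING-robust kinship with first-order-relative
  pruning (phi > 0.177), genotype PCA with automated outlier removal,
  per-colony H_O / H_E / F_IS, pairwise Weir–Cockerham F_ST (groups with
  N >= 3), missing-data-corrected Tajima's D with simulation-based
  significance, and a Mantel test of isolation by distance.
* **Folded-SFS demographic inference** — hypergeometric projection of a
  genotype matrix with missing data onto a common haploid size m
  (after a >75%-heterozygosity paralog filter), then maximum-likelihood
  fits of nested one/two/three-epoch histories under a multinomial
  likelihood, with two interchangeable expected-SFS backends: exact
  coalescent expectations, and Monte-Carlo genealogy simulation with
  common random numbers. Model choice by likelihood-ratio test; a
  100x100 log10 grid maps the likelihood surface and the parameter
  ranges within 5 LL units of the MLE.
* **ABC scenario ladder** — DIY-ABC-style sequential scenario choice
  (contraction vs expansion, single vs double contraction, four time
  windows) from four summary statistics of RAD loci, with rejection and
  logistic-regression posteriors.
* **LD-based contemporary Ne** — Burrows composite disequilibrium among
  unlinked SNP pairs, the 1/S + 3.19/S^2 sampling correction and the
  bias-corrected estimator Ne = (1/3 + sqrt(1/9 − 2.76 r²'))/(2 r²').
* **Synthetic data** — a piecewise-constant-Ne coalescent generator for
  RAD-like diploid datasets (unlinked short loci, missingness, planted
  relatives, colony sheets) and a forward Wright–Fisher simulator whose
  drift LD exercises the Ne estimator. Every generator is seeded and
  deterministic, so each stage is verifiable by parameter recovery.

The core scaling identities are the standard coalescent ones: with a
projected folded spectrum x_j and model spectrum M_j(nu, T) at theta=1,
theta_hat = sum x / sum M, Ne_anc = theta_hat / (4 mu L), epoch sizes
are nu * Ne_anc, and times are 2 * Ne_anc * T generations (times g
years). Defaults: mu = 4.6e-9 per site per generation, g = 2 years,
L = 60,429,389 bp.

## Worked example

Simulate a folded SFS under a two-epoch history with a ~50% contraction
(Ne 174,455 -> 91,315 diploids) 21,317 generations ago over a 10 Mb
callable length, then refit it:

```python
from panmix.demography import fit_model, lrt, scale_estimates
from panmix.experiments import simulate_study_sfs

data = simulate_study_sfs(seed=101)           # ~117k unlinked SNPs at m=38
fit1 = fit_model(data, "one_epoch")
fit2 = fit_model(data, "two_epoch", n_starts=50, seed=5)
print(lrt(fit1, fit2))
scaled = scale_estimates(fit2, mu=4.6e-9, g=2.0, L=1e7)
print(round(scaled.ne_anc), round(scaled.ne_lt),
      round(scaled.times_generations["T"]))
```

```
(np.float64(2509.4730028177146), 2, 0.0)
174528 93165 21448
```

The constant-size model is rejected overwhelmingly (Lambda ~ 2509 on
2 df, p below floating-point resolution), and the recovered ancestral
size (174,528), post-contraction size (93,165) and contraction time
(21,448 generations) land within ~2% of the simulation truth.

The same workflow is available from the shell
(`panmix filter | stats | sfs | fit | grid | abc | ldne | simulate | run`),
and the `analysis/` directory holds numbered driver scripts that run the
full study workflow on synthetic data and write tables under `results/`:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_panmixia_battery.py
python analysis/03_sfs_demography.py
python analysis/04_abc_ladder.py
python analysis/05_ldne.py
```

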
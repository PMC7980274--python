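"""Filter the synthetic dataset and run the panmixia battery.

Expected outcomes (panmixia and planted relatives are ground truth):
the three planted parent-offspring pairs are flagged and pruned, PCA
shows no clustering with small leading eigenvalues, colony diversity is
homogeneous with F_IS near zero, pairwise F_ST is small and patternless,
and the Mantel test finds no isolation by distance.  Tajima's D is
positive, the signature of the simulated ancient contraction.

Writes results/stats/: filter report, kinship pairs, PCA scores,
diversity, F_ST matrix, and a summary JSON.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from panmix import popgen_stats as ps
from panmix.vcf_io import FilterConfig, apply_filters, read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stats"
OUT.mkdir(parents=True, exist_ok=True)

gm = read_vcf(ROOT / "data" / "dataset.vcf", ROOT / "data" / "samples.csv")
gm, report = apply_filters(gm, FilterConfig(min_gq=0, min_dp=0))
print(f"filtered to {gm.n_individuals} x {gm.n_sites}; "
      f"removals: {report.as_dict()}")

km = ps.king_kinship(gm)
pairs = km.flagged_pairs()
print(f"first-order pairs (kinship > 0.177): {len(pairs)}")
gm = ps.prune_relatives(km, gm)
print(f"after pruning relatives: {gm.n_individuals} individuals")

pca = ps.pca_with_outlier_removal(gm)
print(f"PCA: PC1 {pca.explained_var[0]:.2%}, PC2 {pca.explained_var[1]:.2%} "
      f"explained variance; outliers removed: {pca.removed_ids}")
pca.scores.to_csv(OUT / "pca_scores.csv", index=False)
gm = gm.take_individuals(
    np.flatnonzero(~gm.sample_meta["id"].isin(pca.removed_ids))
)

div = ps.diversity(gm)
div.to_csv(OUT / "diversity.csv", index=False)
print("diversity per colony:")
print(div.to_string(index=False))

fst = ps.pairwise_fst(gm, min_n=3)
fst.as_frame().to_csv(OUT / "fst.csv")
r, p = ps.mantel_ibd(fst, seed=1)
taj = ps.tajimas_d(gm, n_sims=1000, seed=1)
print(f"mean pairwise F_ST: {fst.mean_offdiag():.4f}")
print(f"Mantel IBD: r = {r:.3f}, p = {p:.3f}")
print(f"Tajima's D: {taj.d:.3f} (CI {taj.ci_low:.3f}-{taj.ci_high:.3f}), "
      f"p = {taj.p:.4f}")

summary = {
    "n_first_order_pairs": len(pairs),
    "pca_pc1_pc2": [float(v) for v in pca.explained_var[:2]],
    "pca_removed": pca.removed_ids,
    "mean_pairwise_fst": fst.mean_offdiag(),
    "mantel_r": r,
    "mantel_p": p,
    "tajimas_d": taj.d,
    "tajimas_d_ci": [taj.ci_low, taj.ci_high],
    "tajimas_d_p": taj.p,
}
with open(OUT / "summary.json", "w") as fh:
    json.dump(summary, fh, indent=1)
print(f"wrote {OUT}")
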
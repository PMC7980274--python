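"""Folded site-frequency spectrum with hypergeometric projection.

Missing genotypes make the per-site sample size uneven, so the SFS is
built by projecting every site down to a common haploid size ``m``:
a site with ``n`` called alleles of which ``k`` are ALT contributes
hypergeometric weight ``C(k,j) C(n-k, m-j) / C(n,m)`` to unfolded bin
``j`` (the expected composition of a random draw of ``m`` alleles).
Sites with fewer than ``m`` called alleles are dropped.  The spectrum is
then folded onto minor-allele counts ``j = 0..m/2``; bin 0 carries the
(projected-)monomorphic mass and is masked by default, following the
usual convention for multinomial SFS likelihoods.

Counts stay fractional: the projection produces expected counts, and the
multinomial likelihood downstream accepts fractional data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .vcf_io import GenotypeMatrix


@dataclass
class FoldedSFS:
    """Folded spectrum indexed by minor-allele count ``j = 0..m/2``.

    ``counts`` may be fractional (expected counts after projection);
    ``mask`` marks entries excluded from likelihoods (bin 0 by default).
    """

    counts: np.ndarray
    m: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.m < 2 or self.m % 2:
            raise ValueError("projected haploid size m must be even and >= 2")
        if self.counts.shape != (self.m // 2 + 1,):
            raise ValueError(
                f"folded spectrum for m={self.m} needs {self.m // 2 + 1} entries"
            )
        if np.any(self.counts < -1e-9):
            raise ValueError("spectrum counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.m // 2 + 1, dtype=bool)
            self.mask[0] = True
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def S(self) -> float:
        """Total (unmasked) segregating-site mass."""
        return float(self.counts[~self.mask].sum())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, FoldedSFS)
            and self.m == other.m
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.counts, other.counts)
        )


def het_filter(gm: GenotypeMatrix, max_het: float = 0.75) -> GenotypeMatrix:
    """Drop sites whose heterozygote fraction among called genotypes
    exceeds ``max_het`` — the standard excess-heterozygosity screen for
    collapsed paralogs in RAD data."""
    called = gm.called
    n_called = called.sum(axis=0)
    n_het = (gm.genotypes == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / n_called, 0.0)
    return gm.take_sites(np.flatnonzero(frac <= max_het))


def fold(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum over ``j = 0..m`` onto ``j = 0..m/2``."""
    m = len(unfolded) - 1
    if m % 2:
        raise ValueError("unfolded spectrum length must be odd (even m)")
    half = m // 2
    folded = np.array(
        [unfolded[j] + unfolded[m - j] for j in range(half)] + [unfolded[half]]
    )
    return folded


def project_sfs(gm: GenotypeMatrix, m: int) -> FoldedSFS:
    """Build the folded SFS by hypergeometric projection to ``m`` alleles."""
    if m % 2 or not (2 <= m <= 2 * gm.n_individuals):
        raise ValueError(
            f"projection size m={m} must be even and within [2, {2 * gm.n_individuals}]"
        )
    n = gm.allele_numbers()
    k = gm.alt_counts()
    ok = n >= m
    unfolded = np.zeros(m + 1)
    j = np.arange(m + 1)
    # group identical (n, k) pairs; RAD data has few distinct combinations
    pairs, counts = np.unique(
        np.stack([n[ok], k[ok]], axis=1), axis=0, return_counts=True
    )
    for (n_i, k_i), c in zip(pairs, counts):
        unfolded += c * hypergeom.pmf(j, n_i, k_i, m)
    return FoldedSFS(fold(unfolded), m=m)


def sfs_from_counts(alt_counts: np.ndarray, m: int) -> FoldedSFS:
    """Directly counted folded SFS for complete data at fixed size ``m``."""
    alt_counts = np.asarray(alt_counts, dtype=int)
    unfolded = np.bincount(alt_counts, minlength=m + 1).astype(float)
    return FoldedSFS(fold(unfolded), m=m)


def write_sfs(sfs: FoldedSFS, path) -> None:
    """Plain-text SFS: line 1 ``m mask_style``, line 2 counts, line 3 mask."""
    with open(path, "w") as fh:
        fh.write(f"{sfs.m} folded\n")
        fh.write(" ".join(repr(float(c)) for c in sfs.counts) + "\n")
        fh.write(" ".join("1" if b else "0" for b in sfs.mask) + "\n")


def read_sfs(path) -> FoldedSFS:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        m = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed header at line 1") from exc
    try:
        counts = np.array([float(x) for x in lines[1].split()])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed counts at line 2") from exc
    mask = None
    if len(lines) > 2 and lines[2].strip():
        try:
            mask = np.array([bool(int(x)) for x in lines[2].split()])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed mask at line 3") from exc
    return FoldedSFS(counts, m=m, mask=mask)
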
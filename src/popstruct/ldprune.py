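"""Windowed pairwise-r² linkage-disequilibrium pruning.

A window of ``window_snps`` markers slides along each chromosome in steps of
``step_snps``; within each window any surviving pair with genotype-dosage
r² above ``r2_max`` is resolved by removing one member, and the whole scan
is repeated for ``passes`` passes over the surviving set. The removal rule
(higher missingness, then lower MAF, then larger position) is fixed so runs
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from popstruct.genio import MISSING, GenotypeMatrix


@dataclass
class PruneConfig:
    window_snps: int = 200
    step_snps: int = 25
    r2_max: float = 0.2
    passes: int = 2

    def __post_init__(self) -> None:
        if not (self.window_snps > self.step_snps >= 1):
            raise ValueError("require window_snps > step_snps >= 1")
        if not (0 < self.r2_max < 1):
            raise ValueError("r2_max outside (0, 1)")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def pairwise_r2(gA: np.ndarray, gB: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; zero-variance input gives 0.
    """
    gA = np.asarray(gA, dtype=float)
    gB = np.asarray(gB, dtype=float)
    both = (gA != MISSING) & (gB != MISSING)
    if both.sum() < 2:
        raise ValueError("need at least two samples with both genotypes observed")
    a, b = gA[both], gB[both]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _window_r2_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs r² for the SNP columns of one window, missing-aware."""
    obs = values != MISSING
    g = np.where(obs, values, 0).astype(float)
    o = obs.astype(float)
    n = o.T @ o  # pairwise-complete counts
    s1 = g.T @ o  # sum of a over complete pairs (a indexed by row of result)
    s2 = o.T @ g
    s11 = (g * g).T @ o
    s22 = o.T @ (g * g)
    s12 = g.T @ g
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = s12 / n - (s1 / n) * (s2 / n)
        va = s11 / n - (s1 / n) ** 2
        vb = s22 / n - (s2 / n) ** 2
        r2 = cov**2 / (va * vb)
    r2 = np.where((va <= 0) | (vb <= 0) | (n < 2), 0.0, r2)
    return r2


def _prune_window(
    r2: np.ndarray,
    missingness: np.ndarray,
    maf: np.ndarray,
    position: np.ndarray,
    r2_max: float,
) -> np.ndarray:
    """Return local indices removed from one window under the fixed rule."""
    alive = np.ones(r2.shape[0], dtype=bool)
    r2 = r2.copy()
    np.fill_diagonal(r2, 0.0)
    while True:
        masked = np.where(np.outer(alive, alive), r2, 0.0)
        if masked.max() <= r2_max:
            break
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        drop = _choose_removal(i, j, missingness, maf, position)
        alive[drop] = False
    return np.flatnonzero(~alive)


def _choose_removal(i, j, missingness, maf, position) -> int:
    if missingness[i] != missingness[j]:
        return i if missingness[i] > missingness[j] else j
    if maf[i] != maf[j]:
        return i if maf[i] < maf[j] else j
    return i if position[i] > position[j] else j


def prune_windowed(
    geno: GenotypeMatrix, snps: pd.DataFrame, config: PruneConfig | None = None
) -> list[str]:
    """LD-prune the SNP set; returns the kept SNP ids in input order.

    Windows never span chromosomes; the full windowed scan is repeated
    ``config.passes`` times on the surviving set.
    """
    config = config or PruneConfig()
    snps = snps.set_index("snp_id").loc[geno.snp_ids].reset_index()
    for _, chrom_tab in snps.groupby("chrom", sort=False):
        if not chrom_tab["pos"].is_monotonic_increasing:
            raise ValueError("SNPs must be sorted by position within chromosome")

    obs = geno.values != MISSING
    missingness = 1.0 - obs.mean(axis=0)
    freq = geno.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    position = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()

    alive = np.ones(geno.n_snps, dtype=bool)
    for _ in range(config.passes):
        for c in pd.unique(chrom):
            on_chrom = np.flatnonzero((chrom == c) & alive)
            start = 0
            while start < len(on_chrom):
                # surviving SNPs re-indexed each step so windows track removals
                on_chrom = np.flatnonzero((chrom == c) & alive)
                if start >= len(on_chrom):
                    break
                win = on_chrom[start : start + config.window_snps]
                if len(win) >= 2:
                    r2 = _window_r2_matrix(geno.values[:, win])
                    removed_local = _prune_window(
                        r2, missingness[win], maf[win], position[win], config.r2_max
                    )
                    alive[win[removed_local]] = False
                if start + config.window_snps >= len(on_chrom):
                    break
                start += config.step_snps
    return [geno.snp_ids[j] for j in np.flatnonzero(alive)]


def prune_bruteforce(
    geno: GenotypeMatrix, snps: pd.DataFrame, config: PruneConfig | None = None
) -> list[str]:
    """Reference pruner for small instances: one window per chromosome,
    pair-at-a-time scan with :func:`pairwise_r2`. Oracle for tests; O(m²·n)."""
    config = config or PruneConfig()
    snps = snps.set_index("snp_id").loc[geno.snp_ids].reset_index()
    obs = geno.values != MISSING
    missingness = 1.0 - obs.mean(axis=0)
    freq = geno.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    position = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    alive = np.ones(geno.n_snps, dtype=bool)
    for c in pd.unique(chrom):
        while True:
            idx = np.flatnonzero((chrom == c) & alive)
            best, best_pair = 0.0, None
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    r2 = pairwise_r2(geno.values[:, idx[a]], geno.values[:, idx[b]])
                    if r2 > best:
                        best, best_pair = r2, (idx[a], idx[b])
            if best <= config.r2_max or best_pair is None:
                break
            i, j = best_pair
            alive[_choose_removal(i, j, missingness, maf, position)] = False
    return [geno.snp_ids[j] for j in np.flatnonzero(alive)]
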
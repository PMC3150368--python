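"""Pairwise F_st between groups, genomic-inflation translation, summaries.

F_st uses the Hudson estimator combined across SNPs as a ratio of averages:
per SNP j the numerator is (p̂1-p̂2)² - p̂1(1-p̂1)/(n1-1) - p̂2(1-p̂2)/(n2-1)
with n the sampled allele (haploid) count per group, and the denominator is
p̂1(1-p̂2) + p̂2(1-p̂1); the estimate is ΣN_j / ΣD_j.
The expected genomic-control inflation of a fully stratified case-control
study of n_total samples is λ = 1 + n_total·F_st. Hierarchical clustering
(complete linkage) and classical MDS summarize the F_st matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from popstruct.genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FstMatrix:
    group_labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.group_labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("F_st matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("F_st diagonal must be 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.group_labels, columns=self.group_labels
        )


def _group_freq_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP allele-1 frequency and diploid sample count over observed calls."""
    obs = values != MISSING
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(obs, values, 0).sum(axis=0) / (2.0 * n)
    return p, n


def hudson_fst_pair(
    gA: np.ndarray, gB: np.ndarray, return_se: bool = False, n_blocks: int = 20
):
    """Hudson ratio-of-averages F_st between two groups of dosage rows.

    SNPs with fewer than two genotyped samples in either group, or
    monomorphic in the pooled pair, are excluded. With ``return_se`` a
    block-jackknife standard error over SNP blocks is attached.
    """
    gA = np.atleast_2d(np.asarray(gA))
    gB = np.atleast_2d(np.asarray(gB))
    if gA.shape[0] < 2 or gB.shape[0] < 2:
        raise ValueError("both groups need at least two samples")
    p1, n1 = _group_freq_counts(gA)
    p2, n2 = _group_freq_counts(gB)
    pooled_obs = np.where(gA != MISSING, gA, 0).sum(axis=0) + np.where(
        gB != MISSING, gB, 0
    ).sum(axis=0)
    pooled_n = 2 * ((gA != MISSING).sum(axis=0) + (gB != MISSING).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_p = pooled_obs / pooled_n
    usable = (n1 >= 2) & (n2 >= 2) & (pooled_p > 0) & (pooled_p < 1)
    if not usable.any():
        raise ValueError("no usable SNPs for F_st")
    p1, n1, p2, n2 = p1[usable], n1[usable], p2[usable], n2[usable]
    # n in the finite-sample correction is the allele (haploid) count
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (2 * n1 - 1)
        - p2 * (1 - p2) / (2 * n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = float(num.sum() / den.sum())
    if not return_se:
        return fst
    m = len(num)
    blocks = np.array_split(np.arange(m), min(n_blocks, m))
    loo = []
    for block in blocks:
        mask = np.ones(m, dtype=bool)
        mask[block] = False
        loo.append(num[mask].sum() / den[mask].sum())
    loo = np.asarray(loo)
    b = len(blocks)
    se = float(np.sqrt((b - 1) / b * ((loo - loo.mean()) ** 2).sum()))
    return fst, se


def pairwise_fst(
    geno: GenotypeMatrix,
    groups: np.ndarray,
    min_group_size: int = 2,
) -> FstMatrix:
    """Hudson F_st over all unordered pairs of groups.

    Groups below ``min_group_size`` samples are excluded with a warning.
    """
    groups = np.asarray(groups)
    labels, sizes = [], {}
    for lab in pd.unique(groups):
        if pd.isna(lab):
            continue
        size = int((groups == lab).sum())
        if size < min_group_size:
            logger.warning(
                "group %s excluded: only %d samples (< %d)", lab, size, min_group_size
            )
            continue
        labels.append(str(lab))
        sizes[str(lab)] = size
    k = len(labels)
    if k < 2:
        logger.warning("fewer than two usable groups; empty F_st matrix")
        return FstMatrix(labels, np.zeros((k, k)), sizes)
    mat = np.zeros((k, k))
    rows = {lab: np.flatnonzero(groups == lab) for lab in labels}
    for a in range(k):
        for b in range(a + 1, k):
            fst = hudson_fst_pair(
                geno.values[rows[labels[a]]], geno.values[rows[labels[b]]]
            )
            mat[a, b] = mat[b, a] = fst
    return FstMatrix(labels, mat, sizes)


def lambda_from_fst(fst: float, n_total: int = 1000) -> float:
    """Expected genomic-control λ of a fully stratified study of n_total
    samples: λ = 1 + n_total · F_st (negative estimates floored at 0)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 1.0 + n_total * max(float(fst), 0.0)


def fst_lambda_table(fst: FstMatrix, n_total: int = 1000) -> pd.DataFrame:
    """Square table with F_st above the diagonal and λ below it."""
    k = len(fst.group_labels)
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if a < b:
                out[a, b] = fst.values[a, b]
            elif a > b:
                out[a, b] = lambda_from_fst(fst.values[a, b], n_total)
    return pd.DataFrame(out, index=fst.group_labels, columns=fst.group_labels)


def cluster_groups(
    fst: FstMatrix, n_clusters: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Complete-linkage agglomerative clustering of the F_st matrix.

    Negative distances are floored at 0. Returns (scipy linkage matrix,
    flat cluster labels if ``n_clusters`` given). Label order breaks ties
    deterministically (scipy's canonical ordering of the condensed matrix).
    """
    k = len(fst.group_labels)
    if k < 2:
        return np.empty((0, 4)), (np.array([1] * k) if n_clusters else None)
    dist = np.maximum(fst.values, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    flat = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, flat


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node):
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"


def classical_mds(fst: FstMatrix, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of the F_st matrix as distances.

    Double-centers -D²/2, eigendecomposes, returns the top-``dims``
    coordinates; negative eigenvalues are truncated to zero.
    """
    d = np.maximum(np.asarray(fst.values, dtype=float), 0.0)
    k = d.shape[0]
    if k == 0:
        return np.zeros((0, dims))
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:dims]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    return coords


def mds_stress(fst: FstMatrix, coords: np.ndarray) -> float:
    """Kruskal raw stress between input distances and embedded distances."""
    d = np.maximum(fst.values, 0.0)
    k = d.shape[0]
    emb = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    )
    iu = np.triu_indices(k, 1)
    denom = (d[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d[iu] - emb[iu]) ** 2).sum() / denom))
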
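"""PCA of pruned genotypes, ancestry exclusion, projection, geography models.

Genotypes are Patterson-normalized (centered by the column mean, scaled by
sqrt(p(1-p)) with p estimated with a +1/+2 pseudo-count), the sample
covariance is eigendecomposed, and the stored per-SNP weights and
normalization constants let held-out samples be projected onto the same
axes. Ancestry exclusion is a configurable half-plane cutoff in the
(PC1, PC2) plane plus a k-th-nearest-neighbor outlier sweep (k = 1..5,
z > 4). Geography models quantify how much of a component latitude and
longitude explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from popstruct.genio import MISSING, GenotypeMatrix


@dataclass
class PCAModel:
    """Eigenvalues, per-sample scores, per-SNP weights and the normalization
    constants (μ_j, s_j) needed to project new samples."""

    eigenvalues: np.ndarray  # descending, length K
    sample_scores: np.ndarray  # samples x K
    snp_weights: np.ndarray  # SNPs x K
    mu: np.ndarray  # per-SNP centering constant
    scale: np.ndarray  # per-SNP scaling constant
    snp_ids: list[str]
    sample_ids: list[str]


@dataclass
class AncestryCutoff:
    """Half-plane boundary in the (PC1, PC2) plane.

    A sample with normal·(pc1, pc2) + offset strictly > 0 lies on the
    exclusion side. The normal is stored unit length.
    """

    normal: tuple[float, float]
    offset: float

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.normal))
        if norm == 0:
            raise ValueError("cutoff normal must be nonzero")
        self.normal = (self.normal[0] / norm, self.normal[1] / norm)
        self.offset = float(self.offset) / norm


def patterson_normalize(
    geno: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each SNP column and scale by its binomial standard deviation.

    μ_j is the mean dosage over non-missing entries; s_j = sqrt(p̂(1-p̂))
    with p̂ = (1 + Σg)/(2 + 2n) over non-missing entries. Missing entries
    are set to 0 after centering. Returns (normalized matrix, μ, s).
    """
    obs = geno.values != MISSING
    if not obs.any(axis=0).all():
        raise ValueError("column with all entries missing")
    g = np.where(obs, geno.values, 0).astype(float)
    n_obs = obs.sum(axis=0)
    total = g.sum(axis=0)
    mu = total / n_obs
    p_hat = (1.0 + total) / (2.0 + 2.0 * n_obs)
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    normalized = np.where(obs, (g - mu) / scale, 0.0)
    return normalized, mu, scale


def compute_pca(
    geno: GenotypeMatrix, k: int = 10
) -> PCAModel:
    """Top-K PCA of the Patterson-normalized genotype matrix.

    Eigenvalues are singular values squared over (n-1); each component's
    SNP-weight vector is oriented so its largest-magnitude loading is
    positive, making signs reproducible.
    """
    normalized, mu, scale = patterson_normalize(geno)
    n = normalized.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for K={k}")
    u, s, vt = np.linalg.svd(normalized, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"K={k} exceeds matrix rank {rank}")
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| SNP weight positive
    for comp in range(k):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    return PCAModel(
        eigenvalues=eigenvalues,
        sample_scores=scores,
        snp_weights=vt.T,
        mu=mu,
        scale=scale,
        snp_ids=list(geno.snp_ids),
        sample_ids=list(geno.sample_ids),
    )


def project_samples(model: PCAModel, geno_new: GenotypeMatrix) -> np.ndarray:
    """Project new samples onto the model's axes via the stored SNP weights.

    SNP sets must be id-aligned; new genotypes are normalized with the
    model's μ and s (missing set to 0 after centering), then multiplied by
    the weight matrix. A fully missing sample lands at the origin.
    """
    if geno_new.snp_ids != model.snp_ids:
        raise ValueError("SNP sets not aligned between model and new samples")
    obs = geno_new.values != MISSING
    g = np.where(obs, geno_new.values, 0).astype(float)
    normalized = np.where(obs, (g - model.mu) / model.scale, 0.0)
    return normalized @ model.snp_weights


def mean_nonzero_test(scores: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t test of mean 0; returns (t, p).

    Degenerate inputs: n = 1 raises; zero variance with nonzero mean reports
    p at the floating-point underflow floor.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    if scores.std(ddof=1) == 0:
        if scores.mean() == 0:
            return 0.0, 1.0
        return float(np.inf), float(np.finfo(float).tiny)
    t, p = stats.ttest_1samp(scores, 0.0)
    return float(t), float(p)


def ancestry_cutoff_filter(
    model: PCAModel, cutoff: AncestryCutoff
) -> list[str]:
    """Sample ids strictly on the exclusion side of the (PC1, PC2) cutoff."""
    pc12 = model.sample_scores[:, :2]
    side = pc12 @ np.asarray(cutoff.normal) + cutoff.offset
    return [model.sample_ids[i] for i in np.flatnonzero(side > 0)]


def nearest_neighbor_outliers(
    coords: np.ndarray,
    sample_ids: list[str],
    k_max: int = 5,
    z_max: float = 4.0,
) -> list[str]:
    """Outlier removal by the k-th-nearest-neighbor distance criterion.

    For each k = 1..k_max, each sample's distance to its k-th nearest
    neighbor is z-scored across samples and samples with z > z_max are
    removed; removals accumulate over k. ``coords`` may be the normalized
    genotype matrix or PC scores.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k_max + 1:
        raise ValueError(f"need more than {k_max + 1} samples")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(coords)
    dists, _ = nn.kneighbors(coords)  # column 0 is self (distance 0)
    removed: set[str] = set()
    for k in range(1, k_max + 1):
        dk = dists[:, k]
        sd = dk.std(ddof=1)
        if sd == 0:
            continue
        z = (dk - dk.mean()) / sd
        removed |= {sample_ids[i] for i in np.flatnonzero(z > z_max)}
    return sorted(removed)


def pc_geography_regression(
    scores: np.ndarray, samples: pd.DataFrame
) -> dict[str, float]:
    """OLS of one PC on latitude, on longitude, and the longitude increment.

    Returns R² for the latitude-only and longitude-only models and the ΔR²
    from adding longitude to the latitude model. Samples lacking coordinates
    are dropped.
    """
    tab = pd.DataFrame(
        {
            "pc": np.asarray(scores, dtype=float),
            "lat": samples["latitude"].to_numpy(dtype=float),
            "lon": samples["longitude"].to_numpy(dtype=float),
        }
    ).dropna()
    lat_model = sm.OLS(tab["pc"], sm.add_constant(tab["lat"])).fit()
    lon_model = sm.OLS(tab["pc"], sm.add_constant(tab["lon"])).fit()
    both_model = sm.OLS(tab["pc"], sm.add_constant(tab[["lat", "lon"]])).fit()
    return {
        "r2_latitude": float(lat_model.rsquared),
        "r2_longitude": float(lon_model.rsquared),
        "delta_r2_longitude_given_latitude": float(
            both_model.rsquared - lat_model.rsquared
        ),
        "p_latitude": float(lat_model.pvalues["lat"]),
        "p_longitude": float(lon_model.pvalues["lon"]),
        "n": int(len(tab)),
    }


def nagelkerke_r2(binary_outcome: np.ndarray, predictors: np.ndarray) -> float:
    """Nagelkerke pseudo-R² of a logistic model against the intercept-only fit.

    R²_N = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)). Perfect separation raises
    (the likelihood is unbounded; no finite fit exists to report).
    """
    y = np.asarray(binary_outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if X.size == 0 or X.shape[1] == 0:
        return 0.0
    null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not full.mle_retvals.get("converged", True) or np.any(
        ~np.isfinite(full.bse)
    ):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    ll0, ll1 = null.llf, full.llf
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    return float(cox_snell / max_cs)


def variance_share(scores: np.ndarray, group_mask: np.ndarray) -> float:
    """Share of a component's total sum of squares (about the overall mean)
    contributed by the masked samples."""
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    dev = (scores - scores.mean()) ** 2
    total = dev.sum()
    if total == 0:
        return 0.0
    return float(dev[mask].sum() / total)


def jitter_coordinates(
    samples: pd.DataFrame, radius: float, seed: int
) -> pd.DataFrame:
    """Add uniform jitter within ``radius`` degrees to each coordinate,
    deterministically under ``seed`` (for plotting de-identification)."""
    rng = np.random.default_rng(seed)
    out = samples.copy()
    n = len(out)
    out["latitude"] = out["latitude"] + rng.uniform(-radius, radius, n)
    out["longitude"] = out["longitude"] + rng.uniform(-radius, radius, n)
    return out
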
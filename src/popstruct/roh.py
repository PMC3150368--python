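"""Runs of homozygosity: sliding-window detection, inbreeding, count models.

A 20-SNP window slides one SNP at a time along each chromosome; a window is
called homozygous if it contains at most one heterozygous call (missing
calls count as neither het nor hom). A SNP is an ROH candidate when at
least 10% of the windows covering it were called homozygous; maximal
candidate runs become segments, which must then be at least 1 Mb long, span
at least 50 SNPs, and contain at most 5% heterozygous calls. Per-sample
segment counts are modeled with a log-link Poisson regression adjusted for
source study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from popstruct.genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RohConfig:
    window_snps: int = 20
    window_max_het: int = 1
    overlap_frac_min: float = 0.10  # "at least 10%": >= comparison
    seg_min_bp: int = 1_000_000
    seg_min_snps: int = 50
    seg_max_het_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.seg_min_bp < 1 or self.seg_min_snps < 1:
            raise ValueError("window/segment minima must be positive")
        if not (0 < self.overlap_frac_min <= 1):
            raise ValueError("overlap_frac_min outside (0, 1]")
        if not (0 < self.seg_max_het_frac <= 1):
            raise ValueError("seg_max_het_frac outside (0, 1]")


@dataclass
class RohSegment:
    """One called homozygous run (1-based inclusive bp coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int


def _candidate_mask(genotypes: np.ndarray, config: RohConfig) -> np.ndarray:
    """Per-SNP ROH-candidate flags for one chromosome's dosage vector."""
    m = len(genotypes)
    w = config.window_snps
    if m < w:
        return np.zeros(m, dtype=bool)
    het = (genotypes == 1).astype(int)
    # het count of each window starting at i, i = 0..m-w
    csum = np.concatenate([[0], np.cumsum(het)])
    win_het = csum[w:] - csum[:-w]
    win_hom = win_het <= config.window_max_het
    # SNP j is covered by windows starting in [max(0, j-w+1), min(j, m-w)]
    hom_csum = np.concatenate([[0], np.cumsum(win_hom.astype(int))])
    starts = np.maximum(np.arange(m) - w + 1, 0)
    ends = np.minimum(np.arange(m), m - w)  # inclusive window-start index
    covering = ends - starts + 1
    hom_covering = hom_csum[ends + 1] - hom_csum[starts]
    frac = hom_covering / covering
    return frac >= config.overlap_frac_min


def scan_roh_sample(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    sample_id: str,
    config: RohConfig | None = None,
) -> list[RohSegment]:
    """Call ROH segments for one sample across all chromosomes.

    Segment boundaries are the first and last candidate SNP positions.
    Chromosomes shorter than one window yield no calls (with a warning).
    """
    config = config or RohConfig()
    genotypes = np.asarray(genotypes)
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    segments: list[RohSegment] = []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        if np.any(np.diff(pos_arr[idx]) <= 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
        g = genotypes[idx]
        if len(idx) < config.window_snps:
            logger.warning(
                "chromosome %s has %d SNPs (< window %d); skipped",
                chrom, len(idx), config.window_snps,
            )
            continue
        cand = _candidate_mask(g, config)
        # maximal candidate runs
        padded = np.concatenate([[False], cand, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        for s, e in zip(starts, ends):
            run = idx[s : e + 1]
            n_snps = len(run)
            n_het = int((genotypes[run] == 1).sum())
            length = int(pos_arr[run[-1]] - pos_arr[run[0]] + 1)
            if length < config.seg_min_bp:
                continue
            if n_snps < config.seg_min_snps:
                continue
            if n_het / n_snps > config.seg_max_het_frac:
                continue
            segments.append(
                RohSegment(
                    sample_id=sample_id,
                    chrom=str(chrom),
                    start_bp=int(pos_arr[run[0]]),
                    end_bp=int(pos_arr[run[-1]]),
                    n_snps=n_snps,
                    n_het=n_het,
                )
            )
    return segments


def scan_roh(
    geno: GenotypeMatrix, snps: pd.DataFrame, config: RohConfig | None = None
) -> list[RohSegment]:
    """Call ROH segments for every sample."""
    config = config or RohConfig()
    segments: list[RohSegment] = []
    for i, sample_id in enumerate(geno.sample_ids):
        segments.extend(
            scan_roh_sample(geno.values[i], snps, sample_id, config)
        )
    return segments


def scan_roh_bruteforce(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    sample_id: str,
    config: RohConfig | None = None,
) -> list[RohSegment]:
    """Reference scanner: explicit enumeration of every window and every
    SNP's overlap fraction. Oracle for tests on small fixtures."""
    config = config or RohConfig()
    genotypes = np.asarray(genotypes)
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    segments: list[RohSegment] = []
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        g = genotypes[idx]
        m = len(idx)
        w = config.window_snps
        if m < w:
            continue
        window_hom = []
        for start in range(m - w + 1):
            het = int((g[start : start + w] == 1).sum())
            window_hom.append(het <= config.window_max_het)
        cand = np.zeros(m, dtype=bool)
        for j in range(m):
            covering = [s for s in range(m - w + 1) if s <= j <= s + w - 1]
            hom = sum(window_hom[s] for s in covering)
            cand[j] = (hom / len(covering)) >= config.overlap_frac_min
        j = 0
        while j < m:
            if not cand[j]:
                j += 1
                continue
            e = j
            while e + 1 < m and cand[e + 1]:
                e += 1
            run = idx[j : e + 1]
            n_snps = len(run)
            n_het = int((genotypes[run] == 1).sum())
            length = int(pos_arr[run[-1]] - pos_arr[run[0]] + 1)
            if (
                length >= config.seg_min_bp
                and n_snps >= config.seg_min_snps
                and n_het / n_snps <= config.seg_max_het_frac
            ):
                segments.append(
                    RohSegment(sample_id, str(chrom), int(pos_arr[run[0]]),
                               int(pos_arr[run[-1]]), n_snps, n_het)
                )
            j = e + 1
    return segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "n_het"],
    )


def segments_to_bed(segments: list[RohSegment]) -> pd.DataFrame:
    """BED-style frame: 0-based half-open coordinates (start-1, end)."""
    tab = segments_to_frame(segments)
    return pd.DataFrame(
        {
            "chrom": tab["chrom"],
            "start": tab["start_bp"] - 1,
            "end": tab["end_bp"],
            "sample_id": tab["sample_id"],
            "n_snps": tab["n_snps"],
            "n_het": tab["n_het"],
        }
    )


def segment_counts(segments: list[RohSegment], sample_ids: list[str]) -> pd.Series:
    tab = segments_to_frame(segments)
    counts = tab.groupby("sample_id").size()
    return counts.reindex(sample_ids, fill_value=0)


def inbreeding_coefficient(
    genotypes: np.ndarray, freqs: np.ndarray
) -> float:
    """Method-of-moments inbreeding coefficient from excess homozygosity.

    F = (O_hom - E_hom) / (N - E_hom), with the expected homozygous count
    E_hom = Σ_j [1 - 2 p_j (1-p_j) · 2n_j/(2n_j - 1)] over the sample's
    non-missing SNPs; n_j is the diploid count behind the frequency
    estimate (the small-sample correction of the expected heterozygosity).
    """
    genotypes = np.asarray(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    obs = (genotypes != MISSING) & ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    g = genotypes[obs]
    p = freqs[obs]
    n_obs = len(g)
    if n_obs == 0:
        raise ValueError("no usable SNPs")
    o_hom = float((g != 1).sum())
    n_chrom = 2.0 * n_obs
    e_hom = float((1.0 - 2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1.0)).sum())
    denom = n_obs - e_hom
    if denom == 0:
        raise ValueError("degenerate: N equals expected homozygous count")
    return (o_hom - e_hom) / denom


def inbreeding_coefficients(geno: GenotypeMatrix) -> pd.Series:
    """Per-sample F using combined-sample allele frequencies."""
    freqs = geno.allele_frequency()
    vals = [
        inbreeding_coefficient(geno.values[i], freqs) for i in range(geno.n_samples)
    ]
    return pd.Series(vals, index=geno.sample_ids, name="F")


def segment_count_model(
    counts: pd.Series,
    samples: pd.DataFrame,
    covariate: str = "latitude",
    baseline_group: str | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Poisson regression of per-sample segment counts on geography.

    ``covariate`` is either a numeric column (e.g. latitude) or ``group``
    for a categorical county model against ``baseline_group``; source study
    is always included as a categorical adjustment. Group-coefficient
    p-values are Bonferroni-adjusted across groups.
    """
    tab = samples.set_index("sample_id").loc[counts.index].reset_index()
    tab["count"] = counts.to_numpy()
    tab = tab.dropna(subset=[covariate if covariate != "group" else "group", "study"])
    y = tab["count"].to_numpy(dtype=float)
    study_dummies = pd.get_dummies(tab["study"], prefix="study", drop_first=True)
    if covariate == "group":
        cats = sorted(tab["group"].unique())
        baseline = baseline_group or cats[0]
        if baseline not in cats:
            raise ValueError(f"baseline group {baseline!r} not present")
        order = [baseline] + [c for c in cats if c != baseline]
        group_dummies = pd.get_dummies(
            pd.Categorical(tab["group"], categories=order), prefix="group",
            drop_first=True,
        )
        X = pd.concat([group_dummies, study_dummies], axis=1)
        adjust_names = list(group_dummies.columns)
    else:
        X = pd.concat(
            [tab[[covariate]].astype(float), study_dummies], axis=1
        )
        adjust_names = [covariate]
    X = sm.add_constant(X.astype(float))
    model = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    out = pd.DataFrame(
        {
            "coef": model.params,
            "se": model.bse,
            "p": model.pvalues,
        }
    )
    out["p_adjusted"] = out["p"]
    if adjust == "bonferroni":
        k = len(adjust_names)
        out.loc[adjust_names, "p_adjusted"] = np.minimum(
            out.loc[adjust_names, "p"] * k, 1.0
        )
    return out
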
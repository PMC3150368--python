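"""Cross-study merging and SNP/sample quality control.

The filter battery mirrors standard multi-study GWAS practice: per-study
call rate, combined-sample MAF and Hardy-Weinberg exact test, and a
1-vs-rest allelic chi-square that catches undetected strand flips and other
between-study artifacts. Sample-level QC removes close relatives
(method-of-moments IBD, π̂ > threshold) and high-missingness samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from popstruct.genio import MISSING, GenotypeMatrix, validate_snp_table

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QcConfig:
    snp_call_rate_min: float = 0.95  # per study
    maf_min: float = 0.01  # all studies combined
    hwe_p_min: float = 1e-6  # all studies combined
    one_vs_rest_p_min: float = 1e-6
    pihat_max: float = 0.20
    sample_missing_max: float = 0.02

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclass
class QcReport:
    """Per-filter accounting of removed SNPs and samples.

    ``snp_removed[f]`` is every SNP failing filter ``f`` (evaluated on the
    merged pre-QC set); ``snp_removed_solely[f]`` those failing only ``f`` —
    the two columns of a standard SNP-QC summary table.
    """

    n_snps_start: int = 0
    allele_mismatch_removed: list[str] = field(default_factory=list)
    snp_removed: dict[str, set] = field(default_factory=dict)
    snp_removed_solely: dict[str, set] = field(default_factory=dict)
    samples_removed: dict[str, list] = field(default_factory=dict)
    n_snps_final: int = 0
    steps: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.steps.append(msg)
        logger.info(msg)

    def finalize_solely(self) -> None:
        for name, removed in self.snp_removed.items():
            others: set = set()
            for other_name, other in self.snp_removed.items():
                if other_name != name:
                    others |= other
            self.snp_removed_solely[name] = removed - others

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "filter": name,
                "removed": len(removed),
                "removed_solely": len(self.snp_removed_solely.get(name, set())),
            }
            for name, removed in self.snp_removed.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_snps_start": self.n_snps_start,
            "allele_mismatch_removed": sorted(self.allele_mismatch_removed),
            "snp_removed": {k: sorted(v) for k, v in self.snp_removed.items()},
            "snp_removed_solely": {
                k: sorted(v) for k, v in self.snp_removed_solely.items()
            },
            "samples_removed": self.samples_removed,
            "n_snps_final": self.n_snps_final,
            "steps": self.steps,
        }


# ---------------------------------------------------------------------------
# Merging


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _alleles_match(a1: str, a2: str, b1: str, b2: str) -> str | None:
    """Return 'same', 'swapped', 'flip', 'flip_swapped' or None (mismatch)."""
    if (a1, a2) == (b1, b2):
        return "same"
    if (a1, a2) == (b2, b1):
        return "swapped"
    fb1, fb2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if (a1, a2) == (fb1, fb2):
        return "flip"
    if (a1, a2) == (fb2, fb1):
        return "flip_swapped"
    return None


def intersect_and_merge(
    datasets: list[tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]],
    reference_index: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, QcReport]:
    """Merge studies on the SNP intersection, restricted to the reference set.

    The reference dataset defaults to the one with the largest sample count
    (the convention of anchoring the merge on the largest study). SNPs whose
    allele pairs cannot be reconciled — after allowing allele swaps and
    strand complements, except for strand-ambiguous A/T and C/G SNPs which
    cannot be complement-normalized and are compared as-is — are dropped and
    counted. Genotypes of swapped-orientation SNPs are recoded 2-g so the
    merged matrix counts a single consistent allele.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to merge")
    report = QcReport()
    if reference_index is None:
        reference_index = int(np.argmax([g.n_samples for g, _, _ in datasets]))
    ref_geno, ref_snps, _ = datasets[reference_index]
    report.n_snps_start = ref_geno.n_snps

    all_sample_ids = [s for g, _, _ in datasets for s in g.sample_ids]
    if len(set(all_sample_ids)) != len(all_sample_ids):
        raise ValueError("duplicate sample ids across studies")

    common = set(ref_snps["snp_id"])
    for geno, snps, _ in datasets:
        common &= set(snps["snp_id"])
    if not common:
        raise ValueError("zero SNP overlap between datasets")
    keep_ids = [s for s in ref_snps["snp_id"] if s in common]

    ref_alleles = ref_snps.set_index("snp_id")[["allele1", "allele2"]]
    mismatched: set[str] = set()
    # per dataset: snp_id -> recode action
    actions: list[dict[str, str]] = []
    for d, (geno, snps, _) in enumerate(datasets):
        alleles = snps.set_index("snp_id")[["allele1", "allele2"]]
        act: dict[str, str] = {}
        for sid in keep_ids:
            a1, a2 = ref_alleles.loc[sid]
            b1, b2 = alleles.loc[sid]
            if _is_ambiguous(a1, a2) or _is_ambiguous(b1, b2):
                rel = "same" if (a1, a2) == (b1, b2) else (
                    "swapped" if (a1, a2) == (b2, b1) else None
                )
            else:
                rel = _alleles_match(a1, a2, b1, b2)
            if rel is None:
                mismatched.add(sid)
            else:
                act[sid] = rel
        actions.append(act)
    keep_ids = [s for s in keep_ids if s not in mismatched]
    report.allele_mismatch_removed = sorted(mismatched)
    report.log(
        f"merge: {len(keep_ids)} SNPs in common with matching alleles; "
        f"{len(mismatched)} dropped for allele mismatch"
    )

    blocks, sample_frames = [], []
    for (geno, snps, samples), act in zip(datasets, actions):
        col = {s: j for j, s in enumerate(geno.snp_ids)}
        sub = geno.values[:, [col[s] for s in keep_ids]].copy()
        swap_cols = [
            j for j, sid in enumerate(keep_ids)
            if act[sid] in ("swapped", "flip_swapped")
        ]
        if swap_cols:
            view = sub[:, swap_cols]
            obs = view != MISSING
            view[obs] = 2 - view[obs]
            sub[:, swap_cols] = view
        blocks.append(sub)
        sample_frames.append(samples)
    merged_values = np.vstack(blocks)
    merged_samples = pd.concat(sample_frames, ignore_index=True)
    merged_snps = ref_snps[ref_snps["snp_id"].isin(keep_ids)].reset_index(drop=True)
    validate_snp_table(merged_snps)
    merged = GenotypeMatrix(merged_values, all_sample_ids, keep_ids)
    return merged, merged_snps, merged_samples, report


# ---------------------------------------------------------------------------
# SNP filters


def snp_call_rate_filter(
    geno: GenotypeMatrix, study_labels: np.ndarray, threshold: float = 0.95
) -> tuple[list[str], dict[str, set]]:
    """SNPs removed iff call rate < threshold in ANY study.

    Returns (kept snp ids, per-study removal sets).
    """
    study_labels = np.asarray(study_labels)
    removed_by_study: dict[str, set] = {}
    removed_any = np.zeros(geno.n_snps, dtype=bool)
    for study in sorted(pd.unique(study_labels)):
        rows = np.flatnonzero(study_labels == study)
        if len(rows) == 0:
            raise ValueError(f"study {study} has zero samples")
        call_rate = 1.0 - (geno.values[rows] == MISSING).mean(axis=0)
        fail = call_rate < threshold
        removed_by_study[study] = {geno.snp_ids[j] for j in np.flatnonzero(fail)}
        removed_any |= fail
    kept = [geno.snp_ids[j] for j in np.flatnonzero(~removed_any)]
    return kept, removed_by_study


def genotype_counts(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP (n_hom_a1, n_het, n_hom_a2) counts over non-missing calls."""
    counts = np.empty((geno.n_snps, 3), dtype=np.int64)
    counts[:, 0] = (geno.values == 2).sum(axis=0)
    counts[:, 1] = (geno.values == 1).sum(axis=0)
    counts[:, 2] = (geno.values == 0).sum(axis=0)
    return counts


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.01) -> list[str]:
    """SNPs with combined-sample minor allele frequency < threshold removed."""
    freq = geno.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    fail = np.isnan(maf) | (maf < threshold)
    return [geno.snp_ids[j] for j in np.flatnonzero(fail)]


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts (same parity), the conditional probabilities that do not exceed
    the observed configuration's probability. Monomorphic SNPs return 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_hom1 + n_het  # rarer-or-not allele count; symmetry makes order moot
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    n_minor = min(n_a, n_b)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(n_het = h | allele counts) up to a shared constant
    homs1 = (n_minor - hets) // 2
    homs2 = n - hets - homs1
    logp = (
        hets * np.log(2.0)
        - gammaln(homs1 + 1)
        - gammaln(hets + 1)
        - gammaln(homs2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    # tolerance guards against ties lost to floating-point rounding
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_filter(geno: GenotypeMatrix, threshold: float = 1e-6) -> list[str]:
    counts = genotype_counts(geno)
    removed = []
    for j in range(geno.n_snps):
        if counts[j].sum() == 0:
            continue
        if hwe_exact_test(*counts[j]) < threshold:
            removed.append(geno.snp_ids[j])
    return removed


def one_vs_rest_frequency_test(
    geno: GenotypeMatrix, study_labels: np.ndarray
) -> np.ndarray:
    """Per-SNP minimum p over 1-vs-rest allelic chi-square comparisons.

    For each study, allele counts in that study are compared against all
    other studies pooled with a 1-df chi-square on the 2x2 allele table.
    Zero-variance tables give p = 1; a single study yields all-1 p-values.
    """
    study_labels = np.asarray(study_labels)
    studies = sorted(pd.unique(study_labels))
    min_p = np.ones(geno.n_snps)
    if len(studies) < 2:
        return min_p
    obs = geno.values != MISSING
    dosage = np.where(obs, geno.values, 0)
    for study in studies:
        in_study = study_labels == study
        a1_in = dosage[in_study].sum(axis=0).astype(float)
        tot_in = 2.0 * obs[in_study].sum(axis=0)
        a1_out = dosage[~in_study].sum(axis=0).astype(float)
        tot_out = 2.0 * obs[~in_study].sum(axis=0)
        p = _allelic_chi2_p(a1_in, tot_in, a1_out, tot_out)
        min_p = np.minimum(min_p, p)
    return min_p


def _allelic_chi2_p(
    a1_in: np.ndarray, tot_in: np.ndarray, a1_out: np.ndarray, tot_out: np.ndarray
) -> np.ndarray:
    """Vectorized 1-df chi-square on 2x2 allele-count tables."""
    a2_in = tot_in - a1_in
    a2_out = tot_out - a1_out
    n = tot_in + tot_out
    row1 = a1_in + a1_out
    row2 = a2_in + a2_out
    with np.errstate(divide="ignore", invalid="ignore"):
        e11 = row1 * tot_in / n
        e12 = row1 * tot_out / n
        e21 = row2 * tot_in / n
        e22 = row2 * tot_out / n
        chi2 = (
            np.where(e11 > 0, (a1_in - e11) ** 2 / e11, 0.0)
            + np.where(e12 > 0, (a1_out - e12) ** 2 / e12, 0.0)
            + np.where(e21 > 0, (a2_in - e21) ** 2 / e21, 0.0)
            + np.where(e22 > 0, (a2_out - e22) ** 2 / e22, 0.0)
        )
    chi2 = np.where((row1 == 0) | (row2 == 0) | (tot_in == 0) | (tot_out == 0), 0.0, chi2)
    return stats.chi2.sf(chi2, df=1)


# ---------------------------------------------------------------------------
# Relatedness


def estimate_pihat(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None, min_informative: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise π̂ = P(IBD=2) + P(IBD=1)/2 by the method of moments.

    IBS0/IBS1/IBS2 sharing counts over pairwise-complete SNPs are converted
    to IBD-state probabilities using the expected IBS distribution given the
    sample allele frequencies, with probabilities truncated into [0,1] and
    renormalized. Returns (π̂ matrix with NaN diagonal, boolean matrix
    flagging pairs with fewer than ``min_informative`` shared SNPs).
    """
    n = geno.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    p = geno.allele_frequency() if freqs is None else np.asarray(freqs, dtype=float)
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    g = geno.values[:, usable]
    p = p[usable]
    q = 1 - p

    # per-SNP P(IBS=s | IBD=k) under the allele frequencies
    e00 = 2 * p**2 * q**2                 # P(IBS0 | IBD0)
    e10 = 4 * p**3 * q + 4 * p * q**3     # P(IBS1 | IBD0)
    e11 = 2 * p**2 * q + 2 * p * q**2     # P(IBS1 | IBD1)

    obs = (g != MISSING).astype(float)
    hom0 = ((g == 0)).astype(float)
    het = ((g == 1)).astype(float)
    hom2 = ((g == 2)).astype(float)

    ibs0 = hom0 @ hom2.T + hom2 @ hom0.T
    ibs1 = het @ (hom0 + hom2).T + (hom0 + hom2) @ het.T
    E00 = (obs * e00) @ obs.T
    E10 = (obs * e10) @ obs.T
    E11 = (obs * e11) @ obs.T
    m_shared = obs @ obs.T

    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(E00 > 0, ibs0 / E00, 0.0)
        P0 = np.clip(P0, 0.0, 1.0)
        P1 = np.where(E11 > 0, (ibs1 - P0 * E10) / E11, 0.0)
    P1 = np.clip(P1, 0.0, 1.0 - P0)
    P2 = 1.0 - P0 - P1
    pihat = P2 + P1 / 2.0
    pihat[m_shared == 0] = np.nan
    np.fill_diagonal(pihat, np.nan)
    unreliable = m_shared < min_informative
    np.fill_diagonal(unreliable, False)
    return pihat, unreliable


def remove_related(
    pihat: np.ndarray,
    sample_ids: list[str],
    missingness: np.ndarray,
    threshold: float = 0.20,
) -> list[str]:
    """Greedy removal until no pair exceeds the π̂ threshold.

    At each step the remaining pair with the highest π̂ is resolved by
    dropping the member with higher genotype missingness (tie: the higher
    sample index).
    """
    pihat = np.array(pihat, dtype=float)
    np.fill_diagonal(pihat, np.nan)
    active = np.ones(len(sample_ids), dtype=bool)
    removed: list[str] = []
    while True:
        masked = np.where(np.outer(active, active), pihat, np.nan)
        if np.all(np.isnan(masked)) or np.nanmax(masked) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(masked), masked.shape)
        if missingness[i] > missingness[j]:
            drop = i
        elif missingness[j] > missingness[i]:
            drop = j
        else:
            drop = max(i, j)
        active[drop] = False
        removed.append(sample_ids[drop])
    return removed


def sample_missingness_filter(
    geno: GenotypeMatrix, threshold: float = 0.02
) -> list[str]:
    """Samples with missingness strictly above threshold, on the current SNP set."""
    miss = geno.sample_missingness()
    return [geno.sample_ids[i] for i in np.flatnonzero(miss > threshold)]


# ---------------------------------------------------------------------------
# Orchestration


def run_snp_qc(
    geno: GenotypeMatrix,
    snps: pd.DataFrame,
    samples: pd.DataFrame,
    config: QcConfig | None = None,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Apply the four SNP filters; returns the filtered set and accounting.

    Each filter is evaluated on the full merged pre-QC matrix (so the
    "solely for that reason" accounting is well defined); the removal set
    is their union.
    """
    config = config or QcConfig()
    report = report or QcReport()
    if report.n_snps_start == 0:
        report.n_snps_start = geno.n_snps
    study = samples.set_index("sample_id")["study"]
    study_labels = np.asarray([study[s] for s in geno.sample_ids])

    _, by_study = snp_call_rate_filter(geno, study_labels, config.snp_call_rate_min)
    call_rate_removed: set = set().union(*by_study.values()) if by_study else set()
    report.snp_removed["call_rate"] = call_rate_removed
    for st, ids in by_study.items():
        report.log(f"call rate < {config.snp_call_rate_min} in {st}: {len(ids)} SNPs")

    report.snp_removed["hwe"] = set(hwe_filter(geno, config.hwe_p_min))
    report.log(f"HWE p < {config.hwe_p_min}: {len(report.snp_removed['hwe'])} SNPs")

    report.snp_removed["maf"] = set(maf_filter(geno, config.maf_min))
    report.log(f"MAF < {config.maf_min}: {len(report.snp_removed['maf'])} SNPs")

    min_p = one_vs_rest_frequency_test(geno, study_labels)
    ovr = {geno.snp_ids[j] for j in np.flatnonzero(min_p < config.one_vs_rest_p_min)}
    report.snp_removed["one_vs_rest"] = ovr
    report.log(f"1-vs-rest p < {config.one_vs_rest_p_min}: {len(ovr)} SNPs")

    report.finalize_solely()
    removed_all = set().union(*report.snp_removed.values())
    keep_idx = [j for j, s in enumerate(geno.snp_ids) if s not in removed_all]
    filtered = geno.subset(snp_idx=keep_idx)
    filtered_snps = snps[snps["snp_id"].isin(filtered.snp_ids)].reset_index(drop=True)
    report.n_snps_final = filtered.n_snps
    report.log(f"SNP QC: {geno.n_snps} -> {filtered.n_snps} SNPs")
    return filtered, filtered_snps, report


def run_sample_qc(
    geno: GenotypeMatrix,
    config: QcConfig | None = None,
    report: QcReport | None = None,
    pihat_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Relatedness removal then sample-missingness filter, in that order."""
    config = config or QcConfig()
    report = report or QcReport()
    pihat, _ = estimate_pihat(geno, freqs=pihat_freqs)
    related = remove_related(
        pihat, geno.sample_ids, geno.sample_missingness(), config.pihat_max
    )
    report.samples_removed["relatedness"] = related
    report.log(f"relatedness π̂ > {config.pihat_max}: removed {len(related)} samples")
    keep = [i for i, s in enumerate(geno.sample_ids) if s not in set(related)]
    geno = geno.subset(sample_idx=keep)

    high_miss = sample_missingness_filter(geno, config.sample_missing_max)
    report.samples_removed["missingness"] = high_miss
    report.log(
        f"sample missingness > {config.sample_missing_max}: removed {len(high_miss)}"
    )
    keep = [i for i, s in enumerate(geno.sample_ids) if s not in set(high_miss)]
    return geno.subset(sample_idx=keep), report
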
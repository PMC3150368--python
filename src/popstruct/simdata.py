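"""Synthetic multi-study, spatially structured genotype datasets.

Subpopulation allele frequencies follow the Balding–Nichols model: each SNP
has an ancestral frequency p drawn uniformly from a MAF range, and
subpopulation k draws its frequency from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k),
so E[p_k] = p and Var[p_k] = F_k p(1-p). Genotypes are Binomial(2, p_k).
Divergence F_k is configured to increase with latitude, emulating a
north-south gradient; a divergent "admixture source" population can
contribute ancestry to a subset of samples. Study labels are assigned
round-robin within subpopulation so geography and study are not confounded
(a flag requests confounding instead). Per-study batch artifacts
(differential missingness, strand flips on A/T- and C/G-ambiguous-free SNPs),
close-relative pairs, and autozygous runs can be planted; everything planted
is recorded in :class:`SimTruth` so downstream stages can be tested against
known ground truth.

Randomness comes from a single seed; each generation stage uses an
independent child stream (fixed spawn keys), so injections are
order-independent and a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from popstruct.genio import (
    MISSING,
    GenotypeMatrix,
    make_snp_table,
    write_plink_binary,
    write_sample_metadata,
)

# fixed spawn keys: one independent stream per generation stage
_STREAM_FREQS = 0
_STREAM_GENOTYPES = 1
_STREAM_RELATIVES = 2
_STREAM_ADMIX = 3
_STREAM_BATCH = 4
_STREAM_ROH = 5

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe six county-like subpopulations sampled along a
    south-to-north transect (divergence growing with latitude to about
    F = 0.002, the magnitude seen between well-separated regions of a
    single European country), genotyped in three studies.
    """

    n_subpops: int = 6
    samples_per_subpop: int = 50
    n_snps: int = 2000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    subpop_F: list[float] | None = None
    subpop_latitude: list[float] | None = None
    subpop_longitude: list[float] | None = None
    admix_fraction: float = 0.0
    admix_source_F: float = 0.02
    admix_alpha: float = 1.0
    n_studies: int = 3
    study_missingness: list[float] | None = None
    flip_snps: int = 0
    relative_pairs: int = 0
    roh_segments: list[tuple[int, float, int]] = field(default_factory=list)
    snp_spacing_bp: int = 50_000
    n_chromosomes: int = 2
    confound_study_with_subpop: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subpop_F is None:
            # divergence increases linearly with latitude rank
            self.subpop_F = [0.0005 + 0.0015 * k / max(self.n_subpops - 1, 1)
                             for k in range(self.n_subpops)]
        if self.subpop_latitude is None:
            self.subpop_latitude = [55.0 + 10.0 * k / max(self.n_subpops - 1, 1)
                                    for k in range(self.n_subpops)]
        if self.subpop_longitude is None:
            self.subpop_longitude = [13.0 + 6.0 * k / max(self.n_subpops - 1, 1)
                                     for k in range(self.n_subpops)]
        if self.study_missingness is None:
            self.study_missingness = [0.0] * self.n_studies
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for F in list(self.subpop_F) + [self.admix_source_F]:
            if not (0 <= F < 1):
                raise ValueError(f"divergence F={F} outside [0, 1)")
        if len(self.subpop_F) != self.n_subpops:
            raise ValueError("subpop_F length != n_subpops")
        if len(self.subpop_latitude) != self.n_subpops:
            raise ValueError("subpop_latitude length != n_subpops")
        if len(self.subpop_longitude) != self.n_subpops:
            raise ValueError("subpop_longitude length != n_subpops")
        if len(self.study_missingness) != self.n_studies:
            raise ValueError("study_missingness length != n_studies")
        if not (0 <= self.admix_fraction <= 1):
            raise ValueError("admix_fraction outside [0, 1]")
        if not (0 <= self.admix_alpha <= 1):
            raise ValueError("admix_alpha outside [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of everything the generator planted."""

    ancestral_freqs: np.ndarray | None = None
    subpop_freqs: np.ndarray | None = None  # subpops x SNPs
    admix_source_freqs: np.ndarray | None = None
    subpop_of_sample: list[str] = field(default_factory=list)
    relatives: list[dict] = field(default_factory=list)  # {id1, id2, kind}
    admixed_sample_ids: list[str] = field(default_factory=list)
    flipped_snp_ids: list[dict] = field(default_factory=list)  # {snp_id, study}
    roh_intervals: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = asdict(self)
        for key in ("ancestral_freqs", "subpop_freqs", "admix_source_freqs"):
            arr = payload[key]
            payload[key] = None if arr is None else np.asarray(arr).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _balding_nichols_freqs(p_anc: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    if F == 0:
        return p_anc.copy()
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def simulate_structured_genotypes(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate the base cohort: genotypes, sample metadata, SNP table, truth.

    Planted artifacts (relatives, admixture, batch effects, ROH) are applied
    by the ``inject_*`` functions; this function draws only the clean
    structured genotypes.
    """
    freq_rng = _rng(config.seed, _STREAM_FREQS)
    geno_rng = _rng(config.seed, _STREAM_GENOTYPES)

    lo, hi = config.ancestral_maf_range
    p_anc = freq_rng.uniform(lo, hi, size=config.n_snps)
    subpop_freqs = np.vstack(
        [_balding_nichols_freqs(p_anc, F, freq_rng) for F in config.subpop_F]
    )
    source_freqs = _balding_nichols_freqs(p_anc, config.admix_source_F, freq_rng)

    n_total = config.n_subpops * config.samples_per_subpop
    values = np.empty((n_total, config.n_snps), dtype=np.int8)
    sample_ids, groups, studies, lats, lons = [], [], [], [], []
    row = 0
    for k in range(config.n_subpops):
        pk = subpop_freqs[k]
        for i in range(config.samples_per_subpop):
            values[row] = geno_rng.binomial(2, pk).astype(np.int8)
            sample_ids.append(f"S{k}_{i:04d}")
            groups.append(f"subpop{k}")
            if config.confound_study_with_subpop:
                studies.append(f"study{k % config.n_studies}")
            else:
                studies.append(f"study{i % config.n_studies}")
            lats.append(config.subpop_latitude[k])
            lons.append(config.subpop_longitude[k])
            row += 1

    snp_ids = [f"snp{j:06d}" for j in range(config.n_snps)]
    per_chrom = int(np.ceil(config.n_snps / config.n_chromosomes))
    chroms = [str(1 + j // per_chrom) for j in range(config.n_snps)]
    pos = [(j % per_chrom + 1) * config.snp_spacing_bp for j in range(config.n_snps)]
    # alleles drawn from non-complementary pairs so strand flips are plantable
    allele_pairs = np.array([["A", "C"], ["A", "G"], ["T", "C"], ["T", "G"]])
    pair_idx = freq_rng.integers(0, 4, size=config.n_snps)
    snps = make_snp_table(
        snp_ids, chroms, pos, allele_pairs[pair_idx, 0], allele_pairs[pair_idx, 1]
    )

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study": studies,
            "group": groups,
            "latitude": lats,
            "longitude": lons,
            "ancestry": "main",
        }
    )
    geno = GenotypeMatrix(values, sample_ids, snp_ids)
    truth = SimTruth(
        ancestral_freqs=p_anc,
        subpop_freqs=subpop_freqs,
        admix_source_freqs=source_freqs,
        subpop_of_sample=groups,
    )
    return geno, samples, snps, truth


def inject_relatives(
    geno: GenotypeMatrix,
    truth: SimTruth,
    pairs: list[tuple[str, str, str]],
    subpop_freqs_of_target: np.ndarray | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Overwrite the second sample of each pair with a relative of the first.

    ``pairs`` holds (template_id, target_id, kind) with kind one of
    ``duplicate``, ``parent_offspring``, ``full_sib``. Transmission follows
    Mendelian segregation given the template's genotype and the target
    subpopulation's allele frequencies (for the untransmitted allele).
    """
    rng = _rng(seed, _STREAM_RELATIVES)
    values = geno.values.copy()
    used: set[str] = set()
    idx = {s: i for i, s in enumerate(geno.sample_ids)}
    for id1, id2, kind in pairs:
        if id1 in used or id2 in used:
            raise ValueError(f"sample in more than one relative pair: {id1}/{id2}")
        used.update((id1, id2))
        i1, i2 = idx[id1], idx[id2]
        g1 = values[i1]
        if subpop_freqs_of_target is not None:
            freqs = np.asarray(subpop_freqs_of_target, dtype=float)
        elif truth.subpop_freqs is not None:
            k = int(truth.subpop_of_sample[i2].removeprefix("subpop"))
            freqs = truth.subpop_freqs[k]
        else:
            raise ValueError("no allele frequencies available for relative simulation")
        if kind == "duplicate":
            values[i2] = g1
        elif kind == "parent_offspring":
            # one allele transmitted from the parent genotype, one from the population
            transmitted = np.where(
                g1 == 1, rng.integers(0, 2, size=len(g1)), (g1 == 2).astype(np.int8)
            )
            values[i2] = (transmitted + rng.binomial(1, freqs)).astype(np.int8)
        elif kind == "full_sib":
            # both sibs from the same two random parents; sib1 = g1 kept as drawn
            # approximate: redraw target sharing 0/1/2 parental alleles w.p. 1/4,1/2,1/4
            n_shared = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=len(g1))
            hap1 = np.where(g1 == 1, rng.integers(0, 2, size=len(g1)), g1 // 2)
            hap2 = g1 - hap1
            new1 = np.where(n_shared >= 1, hap1, rng.binomial(1, freqs))
            new2 = np.where(n_shared == 2, hap2, rng.binomial(1, freqs))
            values[i2] = (new1 + new2).astype(np.int8)
        else:
            raise ValueError(f"unknown relative kind: {kind}")
        truth.relatives.append({"id1": id1, "id2": id2, "kind": kind})
    return GenotypeMatrix(values, geno.sample_ids, geno.snp_ids)


def inject_admixed_samples(
    geno: GenotypeMatrix,
    truth: SimTruth,
    fraction: float,
    alpha: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Give a fraction of each subpopulation's samples outside ancestry.

    Each allele of a selected sample is redrawn from the admixture-source
    frequency with probability ``alpha`` (allele-level mixture), so alpha=1
    replaces the genotype entirely and alpha=0 leaves it unchanged.
    """
    if fraction == 0 or alpha == 0:
        return geno
    if truth.admix_source_freqs is None or truth.subpop_freqs is None:
        raise ValueError("truth lacks frequency draws needed for admixture")
    rng = _rng(seed, _STREAM_ADMIX)
    values = geno.values.copy()
    source = truth.admix_source_freqs
    subpops = np.asarray(truth.subpop_of_sample)
    for k_label in dict.fromkeys(truth.subpop_of_sample):
        rows = np.flatnonzero(subpops == k_label)
        n_sel = int(round(fraction * len(rows)))
        sel = rng.choice(rows, size=n_sel, replace=False)
        k = int(k_label.removeprefix("subpop"))
        pk = truth.subpop_freqs[k]
        mix = (1 - alpha) * pk + alpha * source
        for i in sel:
            miss = values[i] == MISSING
            values[i] = rng.binomial(2, mix).astype(np.int8)
            values[i, miss] = MISSING
            truth.admixed_sample_ids.append(geno.sample_ids[i])
    return GenotypeMatrix(values, geno.sample_ids, geno.snp_ids)


def inject_batch_effects(
    geno: GenotypeMatrix,
    truth: SimTruth,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
    study_missingness: list[float],
    flip_snps: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply per-study missingness and plant strand flips in the first study.

    A flipped SNP has one study's genotypes recoded 2-g and its alleles
    relabeled to the complementary bases, emulating an undetected strand
    flip at merge time. Returns the modified genotypes and SNP table.
    """
    rng = _rng(seed, _STREAM_BATCH)
    values = geno.values.copy()
    snps = snps.copy()
    study_of = samples.set_index("sample_id")["study"]
    studies = sorted(study_of.unique())
    if len(study_missingness) != len(studies):
        raise ValueError("study_missingness length != number of studies")
    for study, rate in zip(studies, study_missingness):
        if rate == 0:
            continue
        rows = [i for i, s in enumerate(geno.sample_ids) if study_of[s] == study]
        mask = rng.random((len(rows), geno.n_snps)) < rate
        sub = values[rows]
        sub[mask] = MISSING
        values[rows] = sub
    if flip_snps > 0:
        flip_idx = rng.choice(geno.n_snps, size=flip_snps, replace=False)
        flip_study = studies[0]
        rows = [i for i, s in enumerate(geno.sample_ids) if study_of[s] == flip_study]
        for j in flip_idx:
            obs = values[np.ix_(rows, [j])]
            obs[obs != MISSING] = 2 - obs[obs != MISSING]
            values[np.ix_(rows, [j])] = obs
            snps.loc[snps.index[j], "allele1"] = _COMPLEMENT[snps.iloc[j]["allele1"]]
            snps.loc[snps.index[j], "allele2"] = _COMPLEMENT[snps.iloc[j]["allele2"]]
            truth.flipped_snp_ids.append(
                {"snp_id": geno.snp_ids[j], "study": flip_study}
            )
    return GenotypeMatrix(values, geno.sample_ids, geno.snp_ids), snps


def inject_roh(
    geno: GenotypeMatrix,
    truth: SimTruth,
    snps: pd.DataFrame,
    roh_spec: list[tuple[str, str, int, int]],
    seed: int = 0,
) -> GenotypeMatrix:
    """Plant autozygous runs: (sample_id, chrom, start_snp_index, n_snps).

    Within the interval the genotype is set homozygous for a single haplotype
    drawn from the sample's subpopulation frequencies (dosage 0 or 2 at every
    SNP), as if both chromosomes descended from one recent ancestor.
    """
    if not roh_spec:
        return geno
    rng = _rng(seed, _STREAM_ROH)
    values = geno.values.copy()
    idx = {s: i for i, s in enumerate(geno.sample_ids)}
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    for sample_id, chrom, start, n in roh_spec:
        i = idx[sample_id]
        on_chrom = np.flatnonzero(chrom_arr == str(chrom))
        span = on_chrom[start : start + n]
        if truth.subpop_freqs is not None:
            k = int(truth.subpop_of_sample[i].removeprefix("subpop"))
            freqs = truth.subpop_freqs[k][span]
        else:
            freqs = np.full(len(span), 0.5)
        hap = rng.binomial(1, freqs)
        values[i, span] = (2 * hap).astype(np.int8)
        truth.roh_intervals.append(
            {
                "sample_id": sample_id,
                "chrom": str(chrom),
                "start_bp": int(pos_arr[span[0]]),
                "end_bp": int(pos_arr[span[-1]]),
                "n_snps": int(len(span)),
            }
        )
    return GenotypeMatrix(values, geno.sample_ids, geno.snp_ids)


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Full generator: base cohort plus every artifact the config requests."""
    geno, samples, snps, truth = simulate_structured_genotypes(config)
    if config.relative_pairs > 0:
        rng = _rng(config.seed, _STREAM_RELATIVES + 100)
        kinds = ["duplicate", "parent_offspring", "full_sib"]
        pairs = []
        free = list(geno.sample_ids)
        for p in range(config.relative_pairs):
            id1 = free.pop(int(rng.integers(len(free))))
            id2 = free.pop(int(rng.integers(len(free))))
            pairs.append((id1, id2, kinds[p % 3]))
        geno = inject_relatives(geno, truth, pairs, seed=config.seed)
    if config.admix_fraction > 0 and config.admix_alpha > 0:
        geno = inject_admixed_samples(
            geno, truth, config.admix_fraction, config.admix_alpha, seed=config.seed
        )
        admixed = set(truth.admixed_sample_ids)
        samples = samples.assign(
            ancestry=[
                "admixed" if s in admixed else a
                for s, a in zip(samples["sample_id"], samples["ancestry"])
            ]
        )
    if config.roh_segments:
        spec = []
        for subpop, _length_bp, n in config.roh_segments:
            sample_id = f"S{subpop}_{0:04d}"
            spec.append((sample_id, "1", 0, int(n)))
        geno = inject_roh(geno, truth, snps, spec, seed=config.seed)
    if any(m > 0 for m in config.study_missingness) or config.flip_snps > 0:
        geno, snps = inject_batch_effects(
            geno, truth, samples, snps,
            config.study_missingness, config.flip_snps, seed=config.seed,
        )
    return geno, samples, snps, truth


def write_dataset(
    geno: GenotypeMatrix,
    samples: pd.DataFrame,
    snps: pd.DataFrame,
    truth: SimTruth,
    prefix: str,
) -> None:
    """Emit PLINK binary + TSV metadata + JSON truth under a path prefix."""
    write_plink_binary(geno, snps, samples, prefix)
    write_sample_metadata(samples, f"{prefix}.meta.tsv")
    truth.to_json(f"{prefix}.truth.json")
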
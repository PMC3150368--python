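"""Genotype and metadata I/O: PLINK 1 binary (.bed/.bim/.fam) and TSV metadata.

Genotypes are held as minor-allele dosages in {0, 1, 2} with ``-1`` marking a
missing call. The .bed payload is the standard SNP-major 2-bit encoding:
magic bytes ``0x6C 0x1B``, a mode byte (``0x01`` = SNP-major), then one row of
``ceil(n_samples / 4)`` bytes per SNP, samples packed low-bits-first with
codes 00 = homozygous allele1 (dosage 2), 01 = missing, 10 = heterozygous,
11 = homozygous allele2 (dosage 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01
# 2-bit code -> dosage of allele1, per packed code value 0..3
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]
SAMPLE_COLUMNS = ["sample_id", "study", "group", "latitude", "longitude", "ancestry"]


class PlinkFormatError(ValueError):
    """Raised when a .bed file violates the PLINK 1 binary format."""


@dataclass
class GenotypeMatrix:
    """samples x SNPs dosage matrix with aligned identifier lists.

    ``values[i, j]`` is the minor-allele dosage of sample ``i`` at SNP ``j``,
    an integer in {0, 1, 2}, or -1 for a missing call.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} snp ids for {m} columns")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def sample_missingness(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - self.missing_mask().mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele1 among observed alleles (NaN if none)."""
        vals = np.ma.masked_equal(self.values, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq = vals.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(freq, dtype=float)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.values[np.ix_(sample_idx, snp_idx)],
            [self.sample_ids[i] for i in sample_idx],
            [self.snp_ids[j] for j in snp_idx],
        )


def make_snp_table(snp_id, chrom, pos, allele1, allele2) -> pd.DataFrame:
    tab = pd.DataFrame(
        {"snp_id": snp_id, "chrom": chrom, "pos": pos, "allele1": allele1, "allele2": allele2}
    )
    validate_snp_table(tab)
    return tab


def validate_snp_table(snps: pd.DataFrame) -> None:
    missing_cols = set(SNP_COLUMNS) - set(snps.columns)
    if missing_cols:
        raise ValueError(f"SNP table missing columns: {sorted(missing_cols)}")
    if snps["snp_id"].duplicated().any():
        dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id: {dup}")


def validate_sample_table(samples: pd.DataFrame) -> None:
    missing_cols = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    lat = samples["latitude"].dropna()
    lon = samples["longitude"].dropna()
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude outside [-180, 180]")


# ---------------------------------------------------------------------------
# PLINK 1 binary


def _unpack_bed_row(row_bytes: np.ndarray, n_samples: int) -> np.ndarray:
    codes = np.empty(len(row_bytes) * 4, dtype=np.uint8)
    for k in range(4):
        codes[k::4] = (row_bytes >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:n_samples]]


def _pack_bed_row(dosages: np.ndarray) -> np.ndarray:
    n = len(dosages)
    n_bytes = (n + 3) // 4
    codes = np.full(n_bytes * 4, 0b01, dtype=np.uint8)  # pad bits: missing
    lut = np.zeros(4, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        lut[dose % 4] = code  # MISSING=-1 maps to index 3; dosage 0/1/2 to 0/1/2
    codes[:n] = lut[dosages.astype(np.int64) % 4]
    out = np.zeros(n_bytes, dtype=np.uint8)
    for k in range(4):
        out |= codes[k::4] << (2 * k)
    return out


def read_plink_binary(prefix: str) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK 1 fileset; returns (genotypes, SNP table, sample stub).

    The sample stub carries only the .fam identifiers; study/geography come
    from :func:`read_sample_metadata`.
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n_samples, n_snps = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if len(header) < 3 or header[:2] != _MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {header[:2]!r}")
    if header[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: individual-major mode (0x{header[2]:02x}) unsupported"
        )
    bytes_per_snp = (n_samples + 3) // 4
    expected = bytes_per_snp * n_snps
    if len(payload) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: payload is {len(payload)} bytes, expected {expected}"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_snps, bytes_per_snp)
    values = np.empty((n_samples, n_snps), dtype=np.int8)
    for j in range(n_snps):
        values[:, j] = _unpack_bed_row(raw[j], n_samples)
    geno = GenotypeMatrix(values, list(fam["iid"]), list(bim["snp_id"]))
    snps = bim[["snp_id", "chrom", "pos", "allele1", "allele2"]].copy()
    validate_snp_table(snps)
    stub = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "study": pd.NA,
            "group": pd.NA,
            "latitude": np.nan,
            "longitude": np.nan,
            "ancestry": pd.NA,
        }
    )
    return geno, snps, stub


def write_plink_binary(
    geno: GenotypeMatrix, snps: pd.DataFrame, samples: pd.DataFrame, prefix: str
) -> None:
    """Write a PLINK 1 fileset that round-trips with :func:`read_plink_binary`."""
    validate_snp_table(snps)
    if list(snps["snp_id"]) != geno.snp_ids:
        raise ValueError("SNP table ids do not match genotype matrix")
    if list(samples["sample_id"]) != geno.sample_ids:
        raise ValueError("sample table ids do not match genotype matrix")
    bim = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "snp_id": snps["snp_id"],
            "cm": 0,
            "pos": snps["pos"],
            "allele1": snps["allele1"],
            "allele2": snps["allele2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        for j in range(geno.n_snps):
            fh.write(_pack_bed_row(geno.values[:, j]).tobytes())


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Read the tab-separated per-sample metadata table.

    Columns: sample_id, study, group, latitude, longitude, ancestry.
    Missing coordinates are permitted (NaN) and logged; duplicate sample ids
    or unparseable coordinates raise.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("latitude", "longitude"):
        if col in table.columns:
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unparseable {col} values in {path}: {exc}")
    validate_sample_table(table)
    n_missing = int(table[["latitude", "longitude"]].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d samples in %s lack coordinates", n_missing, path)
    return table


def write_sample_metadata(samples: pd.DataFrame, path: str) -> None:
    validate_sample_table(samples)
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def align_metadata(stub: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join .fam-order sample stubs with a metadata table.

    Samples absent from the metadata are retained with null group/coordinates
    (and are thereby excluded from group-wise analyses); a warning is logged.
    """
    validate_sample_table(metadata)
    merged = stub[["sample_id"]].merge(metadata, on="sample_id", how="left")
    n_unmatched = int(merged["group"].isna().sum())
    if n_unmatched:
        logger.warning("%d genotyped samples missing from metadata", n_unmatched)
    return merged
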
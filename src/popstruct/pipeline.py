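"""End-to-end orchestration: merge -> QC -> prune -> PCA -> F_st -> ROH -> power.

Stages run in the canonical order for this kind of analysis; each stage's
outputs are written under a single directory and a manifest records the
seed, configuration, and a content hash per emitted file, so a rerun with
the same inputs and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from popstruct import genio, qc, ldprune, structure, diffstats, roh, stratsim

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bed_prefixes: list[str]
    metadata_path: str | None
    out_dir: str
    seed: int = 0
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    prune: ldprune.PruneConfig = field(default_factory=ldprune.PruneConfig)
    roh: roh.RohConfig = field(default_factory=roh.RohConfig)
    pca_k: int = 10
    cutoff_normal: tuple[float, float] | None = None
    cutoff_offset: float = 0.0
    skip_ancestry_exclusion: bool = False
    nn_k_max: int = 5
    nn_z_max: float = 4.0
    min_group_size: int = 20
    lambda_n_total: int = 1000
    power_maf: list[float] = field(default_factory=lambda: [0.1, 0.16])
    power_or: list[float] = field(default_factory=lambda: [1.5, 2.0])
    power_lambda: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.0, 3.0])
    power_replicates: int = 10_000

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub_cls in (("qc", qc.QcConfig), ("prune", ldprune.PruneConfig),
                             ("roh", roh.RohConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(**raw[key])
        if "cutoff_normal" in raw and raw["cutoff_normal"] is not None:
            raw["cutoff_normal"] = tuple(raw["cutoff_normal"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    t_all = time.time()

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["files"][name] = _hash_file(path)

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time() - t_all}
        return name

    # --- merge ------------------------------------------------------------
    name = stage("merge")
    try:
        datasets = []
        for prefix in config.bed_prefixes:
            geno, snps, stub = genio.read_plink_binary(prefix)
            if config.metadata_path:
                meta = genio.read_sample_metadata(config.metadata_path)
                samples = genio.align_metadata(stub, meta)
            else:
                samples = stub
            datasets.append((geno, snps, samples))
        if len(datasets) > 1:
            geno, snps, samples, report = qc.intersect_and_merge(datasets)
        else:
            geno, snps, samples = datasets[0]
            report = qc.QcReport(n_snps_start=geno.n_snps)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- SNP and sample QC -------------------------------------------------
    name = stage("qc")
    try:
        if samples["study"].isna().all():
            samples = samples.assign(study="study0")
        geno, snps, report = qc.run_snp_qc(geno, snps, samples, config.qc, report)
        geno, report = qc.run_sample_qc(geno, config.qc, report)
        samples = samples[samples["sample_id"].isin(geno.sample_ids)].reset_index(
            drop=True
        )
        with open(out / "qc_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        manifest["files"]["qc_report.json"] = _hash_file(out / "qc_report.json")
        emit("qc_summary.tsv", report.summary_table())
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- LD pruning ---------------------------------------------------------
    name = stage("prune")
    try:
        kept = ldprune.prune_windowed(geno, snps, config.prune)
        kept_set = set(kept)
        (out / "pruned_kept.txt").write_text("\n".join(kept) + "\n")
        removed = [s for s in geno.snp_ids if s not in kept_set]
        (out / "pruned_removed.txt").write_text("\n".join(removed) + "\n")
        manifest["files"]["pruned_kept.txt"] = _hash_file(out / "pruned_kept.txt")
        keep_idx = [j for j, s in enumerate(geno.snp_ids) if s in kept_set]
        pruned = geno.subset(snp_idx=keep_idx)
        pruned_snps = snps[snps["snp_id"].isin(kept_set)].reset_index(drop=True)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- PCA + exclusions ---------------------------------------------------
    name = stage("pca")
    try:
        k = min(config.pca_k, pruned.n_samples - 1, pruned.n_snps - 1)
        model = structure.compute_pca(pruned, k=k)
        removed_ids: list[str] = []
        if not config.skip_ancestry_exclusion and config.cutoff_normal is not None:
            cutoff = structure.AncestryCutoff(config.cutoff_normal, config.cutoff_offset)
            removed_ids += structure.ancestry_cutoff_filter(model, cutoff)
        survivors = [s for s in model.sample_ids if s not in set(removed_ids)]
        if len(survivors) > config.nn_k_max + 1:
            keep_rows = [i for i, s in enumerate(pruned.sample_ids) if s in set(survivors)]
            sub = pruned.subset(sample_idx=keep_rows)
            normalized, _, _ = structure.patterson_normalize(sub)
            removed_ids += structure.nearest_neighbor_outliers(
                normalized, sub.sample_ids, config.nn_k_max, config.nn_z_max
            )
        (out / "excluded_samples.txt").write_text("\n".join(sorted(removed_ids)) + "\n")
        manifest["files"]["excluded_samples.txt"] = _hash_file(
            out / "excluded_samples.txt"
        )
        keep_rows = [
            i for i, s in enumerate(pruned.sample_ids) if s not in set(removed_ids)
        ]
        pruned = pruned.subset(sample_idx=keep_rows)
        geno = geno.subset(
            sample_idx=[
                i for i, s in enumerate(geno.sample_ids) if s not in set(removed_ids)
            ]
        )
        samples = samples[samples["sample_id"].isin(pruned.sample_ids)].reset_index(
            drop=True
        )
        k = min(config.pca_k, pruned.n_samples - 1, pruned.n_snps - 1)
        model = structure.compute_pca(pruned, k=k)
        scores = pd.DataFrame(
            model.sample_scores,
            columns=[f"PC{i+1}" for i in range(model.sample_scores.shape[1])],
        )
        scores.insert(0, "sample_id", model.sample_ids)
        emit("pca_scores.tsv", scores)
        weights = pd.DataFrame(
            model.snp_weights,
            columns=[f"PC{i+1}" for i in range(model.snp_weights.shape[1])],
        )
        weights.insert(0, "snp_id", model.snp_ids)
        emit("pca_weights.tsv", weights)
        emit(
            "pca_scree.tsv",
            pd.DataFrame(
                {"component": np.arange(1, len(model.eigenvalues) + 1),
                 "eigenvalue": model.eigenvalues}
            ),
        )
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- geography regression + map table ------------------------------------
    have_geo = (
        config.metadata_path is not None
        and samples["latitude"].notna().any()
    )
    if have_geo:
        name = stage("geography")
        try:
            ordered = samples.set_index("sample_id").loc[model.sample_ids].reset_index()
            geo = structure.pc_geography_regression(
                model.sample_scores[:, 0], ordered
            )
            with open(out / "pc1_geography.json", "w") as fh:
                json.dump(geo, fh, indent=1)
            manifest["files"]["pc1_geography.json"] = _hash_file(
                out / "pc1_geography.json"
            )
            jittered = structure.jitter_coordinates(ordered, 0.05, config.seed)
            emit(
                "map_plot.tsv",
                pd.DataFrame(
                    {
                        "sample_id": jittered["sample_id"],
                        "latitude": jittered["latitude"],
                        "longitude": jittered["longitude"],
                        "pc1": model.sample_scores[:, 0],
                        "pc2": model.sample_scores[:, 1]
                        if model.sample_scores.shape[1] > 1
                        else np.nan,
                    }
                ),
            )
        except Exception as exc:
            raise StageError(name, exc) from exc
    else:
        logger.warning("no metadata/coordinates: geography stage skipped")
        manifest["stages"]["geography"] = {"skipped": True}

    # --- F_st / lambda -------------------------------------------------------
    if have_geo and samples["group"].notna().any():
        name = stage("fst")
        try:
            ordered = samples.set_index("sample_id").loc[pruned.sample_ids]
            fst = diffstats.pairwise_fst(
                pruned, ordered["group"].to_numpy(), config.min_group_size
            )
            table = diffstats.fst_lambda_table(fst, config.lambda_n_total)
            table.to_csv(out / "fst_lambda_table.tsv", sep="\t")
            manifest["files"]["fst_lambda_table.tsv"] = _hash_file(
                out / "fst_lambda_table.tsv"
            )
            long = fst.to_frame().stack().rename("fst").reset_index()
            long.columns = ["group1", "group2", "fst"]
            emit("fst_long.tsv", long)
            if len(fst.group_labels) >= 2:
                linkage, _ = diffstats.cluster_groups(fst)
                (out / "fst_dendrogram.newick").write_text(
                    diffstats.linkage_to_newick(linkage, fst.group_labels) + "\n"
                )
                manifest["files"]["fst_dendrogram.newick"] = _hash_file(
                    out / "fst_dendrogram.newick"
                )
                coords = diffstats.classical_mds(fst)
                emit(
                    "fst_mds.tsv",
                    pd.DataFrame(
                        {"group": fst.group_labels,
                         "dim1": coords[:, 0],
                         "dim2": coords[:, 1] if coords.shape[1] > 1 else 0.0}
                    ),
                )
        except Exception as exc:
            raise StageError(name, exc) from exc
    else:
        logger.warning("no group labels: F_st stage skipped")
        manifest["stages"]["fst"] = {"skipped": True}

    # --- ROH -----------------------------------------------------------------
    name = stage("roh")
    try:
        segments = roh.scan_roh(pruned, pruned_snps, config.roh)
        emit("roh_segments.tsv", roh.segments_to_bed(segments))
        counts = roh.segment_counts(segments, pruned.sample_ids)
        emit(
            "roh_counts.tsv",
            counts.rename("n_segments").rename_axis("sample_id").reset_index(),
        )
        emit(
            "inbreeding.tsv",
            roh.inbreeding_coefficients(pruned).rename_axis("sample_id").reset_index(),
        )
        if have_geo and samples["study"].notna().any() and counts.sum() > 0:
            coef = roh.segment_count_model(counts, samples, covariate="latitude")
            emit("roh_latitude_model.tsv", coef.reset_index(names="term"))
        elif counts.sum() == 0:
            logger.warning("no ROH segments called: count model skipped")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- power ---------------------------------------------------------------
    name = stage("power")
    try:
        base = stratsim.PowerScenario(
            n_replicates=config.power_replicates, seed=config.seed
        )
        grid = stratsim.power_grid(
            config.power_maf, config.power_or, config.power_lambda, base
        )
        emit("power_grid.tsv", grid)
    except Exception as exc:
        raise StageError(name, exc) from exc

    manifest["runtime_s"] = round(time.time() - t_all, 3)
    manifest["config"] = json.loads(json.dumps(asdict(config), default=str))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
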
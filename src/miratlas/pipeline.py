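"""Config-driven orchestration of the full synthetic-atlas pipeline.

A declarative YAML config drives: simulate (or load) -> merge technical
replicates -> outlier flagging -> feature filtering -> normalization
benchmark -> characterization -> deconvolution.  One global seed fans out to
per-stage child seeds derived by stable hashing of stage names, so toggling a
stage never reshuffles another stage's randomness.  Identical config + seed
produce a byte-identical bundle of output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .atlas_io import (
    AtlasValidationError,
    NormalizedMatrix,
    compute_rpm,
    filter_features,
    merge_technical_replicates,
    summarize_by_cell_type,
    write_annotation,
    write_counts,
    write_matrix,
    write_metadata,
)
from .benchmark import METHODS, compare_normalizations
from .characterization import (
    CharacterizationThresholds,
    call_strand_dominance,
    categorize_specificity,
    class_enrichment,
    compare_mirna_ages,
    tissue_cell_ratios,
)
from .deconvolution import build_signature, deconvolve_cohort
from .normalization import (
    add_pseudocount,
    size_factors_median_of_ratios,
    vst_normalize,
)
from .simulate import AtlasSimConfig, simulate_atlas, simulate_mixture

__all__ = ["PipelineConfig", "flag_outliers", "run_pipeline", "child_seed"]

logger = logging.getLogger("miratlas")


def child_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed from the master seed and the stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _from_mapping(cls, data: Mapping[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise AtlasValidationError(
            f"unknown config key(s) {sorted(unknown)} in section {where!r}"
        )
    return cls(**data)


@dataclass
class PipelineConfig:
    """Declarative parameters for one pipeline run; unknown keys rejected."""

    seed: int = 0
    simulate: AtlasSimConfig = field(default_factory=AtlasSimConfig)
    # stage toggles
    run_benchmark: bool = True
    run_characterize: bool = True
    run_deconvolve: bool = True
    # feature filter
    mirgenedb_only: bool = True
    min_max_rpm: float | None = 100.0
    min_total_count: int | None = None
    # benchmark
    methods: tuple[str, ...] = tuple(METHODS)
    ruv_k: int = 1
    ruvr_design: str = "batch"
    # characterization; defaults scaled down to the synthetic atlas size
    thresholds: CharacterizationThresholds = field(
        default_factory=lambda: CharacterizationThresholds(
            strand_min_reads=100, strand_min_cells=3
        )
    )
    # deconvolution
    n_mixtures: int = 10
    mixture_noise_log_sd: float = 0.05
    q_threshold: float = 0.5
    g_min: int = 5
    g_max: int = 50
    deconv_solver: str = "nu_svr"
    # outlier flagging
    outlier_z: float = 4.0

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sub: dict[str, Any] = {}
        if "simulate" in data:
            sub["simulate"] = _from_mapping(
                AtlasSimConfig, data.pop("simulate"), "simulate"
            )
        if "thresholds" in data:
            sub["thresholds"] = _from_mapping(
                CharacterizationThresholds, data.pop("thresholds"), "thresholds"
            )
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        cfg = _from_mapping(cls, {**data, **sub}, "pipeline")
        unknown = [m for m in cfg.methods if m not in METHODS]
        if unknown:
            raise AtlasValidationError(f"unknown normalization method(s) {unknown}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def flag_outliers(
    matrix: NormalizedMatrix,
    labels: Mapping[str, str],
    z_threshold: float = 4.0,
) -> pd.DataFrame:
    """Flag samples far from their own-label centroid.

    For every label group with >= 3 samples, each sample's Euclidean distance
    to the centroid of the *other* group members is computed; the sample is
    flagged when that distance exceeds mean + z_threshold * sd of the other
    members' leave-self-out distances.  Groups of < 3 samples are skipped
    (``skipped`` column True).
    """
    cols = list(matrix.values.columns)
    missing = [c for c in cols if c not in labels]
    if missing:
        raise AtlasValidationError(f"samples without labels: {missing[:5]}")
    X = matrix.values.to_numpy(float).T
    rows = []
    by_label: dict[str, list[int]] = {}
    for i, c in enumerate(cols):
        by_label.setdefault(labels[c], []).append(i)
    for label, idx in sorted(by_label.items()):
        if len(idx) < 3:
            logger.warning("outlier flagging: group %r has < 3 samples; skipped",
                           label)
            for i in idx:
                rows.append((cols[i], label, np.nan, False, True))
            continue
        sub = X[idx]
        total = sub.sum(axis=0)
        n = len(idx)
        dists = np.array(
            [
                float(np.linalg.norm(sub[j] - (total - sub[j]) / (n - 1)))
                for j in range(n)
            ]
        )
        for j, i in enumerate(idx):
            others = np.delete(dists, j)
            mu, sd = others.mean(), others.std(ddof=1)
            flagged = bool(dists[j] > mu + z_threshold * sd) if sd > 0 else False
            rows.append((cols[i], label, dists[j], flagged, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "label", "distance", "flagged", "skipped"]
    ).set_index("sample_id")


def _mixture_truth_frame(truths: list[dict[str, float]], ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(truths, index=ids)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns the manifest dict.  The bundle contains the simulated atlas
    tables, the benchmark (Table-2-style) accuracy CSV, strand/tier/
    enrichment/age CSVs, deconvolution proportion CSVs, a JSON manifest and a
    log file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    manifest: dict[str, Any] = {
        "package": "miratlas",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        # ---- simulate ----------------------------------------------------
        sim_cfg = dataclasses.replace(
            config.simulate, seed=child_seed(config.seed, "simulate")
        )
        counts, meta, annotation, truth = simulate_atlas(sim_cfg)
        logger.info("simulate: %d miRNAs x %d runs", *counts.shape)
        write_counts(counts, out / "counts.csv")
        write_metadata(meta, out / "metadata.csv")
        write_annotation(annotation, out / "annotation.csv")
        truth.to_json(out / "ground_truth.json")
        manifest["stages"]["simulate"] = {
            "n_mirnas": counts.shape[0],
            "n_runs": counts.shape[1],
            "seed": sim_cfg.seed,
        }

        # ---- merge -------------------------------------------------------
        counts, meta = merge_technical_replicates(counts, meta)
        logger.info("merge: %d samples", counts.shape[1])

        # ---- outlier flagging -------------------------------------------
        rpm = compute_rpm(counts)
        log_rpm = NormalizedMatrix(
            np.log2(rpm.values + 1.0), "adjusted", rpm.provenance + ["log2p"]
        )
        flags = flag_outliers(
            log_rpm, {m.run_id: m.cell_type for m in meta}, config.outlier_z
        )
        flags.to_csv(out / "outlier_flags.csv")
        n_flagged = int(flags["flagged"].sum())
        logger.info("outliers: %d of %d samples flagged", n_flagged, len(flags))
        manifest["stages"]["outliers"] = {"flagged": n_flagged}

        # ---- feature filter ---------------------------------------------
        cell_mean_rpm = summarize_by_cell_type(rpm, meta, "mean")
        filtered = filter_features(
            counts,
            annotation,
            mirgenedb_only=config.mirgenedb_only,
            min_max_rpm=config.min_max_rpm,
            min_total_count=config.min_total_count,
            rpm=cell_mean_rpm,
        )
        logger.info(
            "filter: %d -> %d features", counts.shape[0], filtered.shape[0]
        )
        manifest["stages"]["filter"] = {
            "features_in": counts.shape[0],
            "features_out": filtered.shape[0],
        }

        # ---- benchmark ---------------------------------------------------
        if config.run_benchmark:
            table = compare_normalizations(
                filtered,
                meta,
                list(config.methods),
                ruv_k=config.ruv_k,
                ruvr_design=config.ruvr_design,  # type: ignore[arg-type]
            )
            table.to_csv(out / "benchmark_accuracy.csv")
            logger.info("benchmark: best method %s", table["accuracy"].idxmax())
            manifest["stages"]["benchmark"] = {
                "methods": list(config.methods),
                "best": str(table["accuracy"].idxmax()),
                "best_accuracy": float(table["accuracy"].max()),
            }

        # ---- characterization -------------------------------------------
        th = config.thresholds
        if config.run_characterize:
            cell_counts = summarize_by_cell_type(
                NormalizedMatrix(counts.values.astype(float), "raw", []),
                meta,
                "mean",
            )
            strand = call_strand_dominance(cell_counts, annotation, th)
            pd.DataFrame([vars(s) for s in strand]).to_csv(
                out / "strand_calls.csv", index=False
            )
            guide_rpm = filter_features(
                cell_mean_rpm, annotation, mirgenedb_only=True, guide_only=True
            )
            tiers = categorize_specificity(guide_rpm, annotation, th)
            pd.DataFrame([vars(t) for t in tiers]).to_csv(
                out / "specificity_tiers.csv", index=False
            )
            class_of = {}
            for m in meta:
                class_of[m.cell_type] = m.cell_class
            enrich = class_enrichment(cell_mean_rpm, class_of)
            enrich.to_csv(out / "class_enrichment.csv")

            c1 = add_pseudocount(filtered)
            vst_m, _ = vst_normalize(c1, size_factors_median_of_ratios(c1))
            write_matrix(vst_m.values, out / "vst.csv", vst_m.provenance)
            try:
                old_mean, young_mean, statistic, p, picked = compare_mirna_ages(
                    vst_m, annotation, meta, th, exclude_classes=()
                )
                age = {
                    "old_mean": old_mean,
                    "young_mean": young_mean,
                    "statistic": statistic,
                    "p_value": p,
                    "n_samples": len(picked),
                }
            except AtlasValidationError as exc:
                age = {"skipped": str(exc)}
            with open(out / "age_contrast.json", "w") as fh:
                json.dump(age, fh, indent=1, sort_keys=True)
            manifest["stages"]["characterize"] = {
                "strand_calls": len(strand),
                "tiers": len(tiers),
                "age": age,
            }

            # tissue-like mixture vs constituent cells
            rng_seed = child_seed(config.seed, "tissue")
            n_ct = cell_mean_rpm.values.shape[1]
            props = np.random.default_rng(rng_seed).dirichlet(np.ones(n_ct))
            tissue, _ = simulate_mixture(
                cell_mean_rpm, props, noise_log_sd=0.0, seed=rng_seed,
                mixture_id="tissue",
            )
            ratios = tissue_cell_ratios(tissue, cell_mean_rpm, th)
            ratios.to_csv(out / "tissue_cell_ratios.csv")

        # ---- deconvolution ----------------------------------------------
        if config.run_deconvolve:
            sig = build_signature(
                rpm,
                config.q_threshold,
                config.g_min,
                config.g_max,
                labels={m.run_id: m.cell_type for m in meta},
            )
            mix_seed = child_seed(config.seed, "mixtures")
            rng = np.random.default_rng(mix_seed)
            cols = {}
            truths = []
            ids = []
            n_ct = cell_mean_rpm.values.shape[1]
            for i in range(config.n_mixtures):
                props = rng.dirichlet(np.ones(n_ct))
                mix, t = simulate_mixture(
                    cell_mean_rpm,
                    props,
                    noise_log_sd=config.mixture_noise_log_sd,
                    seed=child_seed(mix_seed, f"mix{i}"),
                    mixture_id=f"mix{i:03d}",
                )
                cols[f"mix{i:03d}"] = mix
                truths.append(t)
                ids.append(f"mix{i:03d}")
            mixtures = NormalizedMatrix(
                pd.DataFrame(cols), "adjusted", ["simulate_mixture"]
            )
            estimates = deconvolve_cohort(
                mixtures, sig, mode="per_sample", solver=config.deconv_solver  # type: ignore[arg-type]
            )
            prop_df = pd.DataFrame(
                {e.mixture_id: e.proportions for e in estimates}
            ).T
            prop_df.to_csv(out / "mixture_proportions.csv")
            _mixture_truth_frame(truths, ids).to_csv(
                out / "mixture_truth.csv"
            )
            mae = float(
                (prop_df - _mixture_truth_frame(truths, ids)).abs().mean().mean()
            )
            logger.info("deconvolve: mean absolute error %.4f", mae)
            manifest["stages"]["deconvolve"] = {
                "n_mixtures": config.n_mixtures,
                "signature_genes": len(sig.selected_genes),
                "condition_number": sig.condition_number,
                "mean_abs_error": mae,
            }

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        return manifest
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
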
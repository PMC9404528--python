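"""Synthetic multi-study miRNA count atlases with known ground truth.

The generator emulates the structure the downstream analyses assume: many
studies sharing cell types, per-(study, miRNA) multiplicative batch effects,
negative-binomial counts, planted cell-type-specific / ubiquitous miRNAs,
paired 5p/3p hairpin arms with a planted dominant arm, and mixture samples
(plasma- or tissue-like) composed from cell-type profiles.

Counts for run j, miRNA g are drawn NB with

    mean = library_size_j * profile[g, cell_type(j)] / 1e6 * batch[study(j), g]

where each cell type's profile column is scaled to sum to 1e6, so ``profile``
is also the expected RPM of the run (up to batch wobble).  Variance is
mu + alpha * mu**2 with a single global dispersion alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import (
    CELL_CLASSES,
    NODES,
    CountMatrix,
    MiRNAAnnotation,
    NormalizedMatrix,
    RunMetadata,
)

__all__ = [
    "SPECIFICITY_TIERS",
    "AtlasSimConfig",
    "GroundTruth",
    "simulate_atlas",
    "simulate_mixture",
]

#: Five planted cell-specificity tiers, sparsest first.
SPECIFICITY_TIERS = (
    "cell_specific",
    "infrequent",
    "frequent",
    "near_ubiquitous",
    "ubiquitous",
)

# classes available for cell types; "plasma" is reserved for mixture samples
_CLASS_POOL = tuple(c for c in CELL_CLASSES if c != "plasma")


@dataclass
class AtlasSimConfig:
    """Parameters of one synthetic atlas draw."""

    n_mirnas: int = 300
    n_cell_types: int = 8
    n_classes: int = 4
    n_studies: int = 6
    samples_per_study: int = 6
    library_size_log_mean: float = float(np.log(5e5))
    library_size_log_sd: float = 0.25
    nb_dispersion: float = 0.2
    batch_log_sd: float = 0.5
    planted_category_counts: Mapping[str, int] = field(
        default_factory=lambda: {"cell_specific": 20, "ubiquitous": 10}
    )
    specific_high_rpm: float = 5000.0
    background_rpm: float = 5.0
    arm_pair_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.batch_log_sd < 0:
            raise ValueError("batch_log_sd must be >= 0")
        if not 0 <= self.arm_pair_fraction <= 1:
            raise ValueError("arm_pair_fraction must be in [0, 1]")
        if self.specific_high_rpm <= 0 or self.background_rpm <= 0:
            raise ValueError("expression rates must be positive")
        bad = set(self.planted_category_counts) - set(SPECIFICITY_TIERS)
        if bad:
            raise ValueError(f"unknown specificity tiers {sorted(bad)}")
        if sum(self.planted_category_counts.values()) > self.n_mirnas:
            raise ValueError("planted_category_counts sums to more than n_mirnas")
        if not 1 <= self.n_classes <= len(_CLASS_POOL):
            raise ValueError(f"n_classes must be in [1, {len(_CLASS_POOL)}]")


@dataclass
class GroundTruth:
    """Planted structure emitted by the simulator; the recovery surface."""

    specificity_label: dict[str, str]
    home_cells: dict[str, list[str]]
    dominant_arm: dict[str, str]
    batch_factors: pd.DataFrame  # study x miRNA
    mixture_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_rpm: pd.DataFrame | None = None  # miRNA x cell type

    def to_json(self, path) -> None:
        payload = {
            "specificity_label": self.specificity_label,
            "home_cells": self.home_cells,
            "dominant_arm": self.dominant_arm,
            "batch_factors": self.batch_factors.to_dict(),
            "mixture_proportions": self.mixture_proportions,
            "expected_rpm": None
            if self.expected_rpm is None
            else self.expected_rpm.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _n_home_cells(tier: str, n_ct: int, rng: np.random.Generator) -> int:
    """Home-cell count for a planted tier, matching the default tier cutoffs
    (<5 / [5,10) / [10,30) / >=30 / >90% of cells) where n_ct allows."""
    if tier == "cell_specific":
        return int(rng.integers(1, min(4, n_ct) + 1))
    if tier == "infrequent":
        lo, hi = 5, min(9, n_ct)
    elif tier == "frequent":
        lo, hi = 10, min(29, n_ct)
    elif tier == "near_ubiquitous":
        lo, hi = 30, int(np.floor(0.9 * n_ct))
    else:  # ubiquitous
        return n_ct
    if hi < lo:
        raise ValueError(
            f"tier {tier!r} not plantable with n_cell_types={n_ct}; increase it"
        )
    return int(rng.integers(lo, hi + 1))


def simulate_atlas(
    config: AtlasSimConfig,
) -> tuple[CountMatrix, list[RunMetadata], list[MiRNAAnnotation], GroundTruth]:
    """Draw one seeded synthetic atlas.

    Studies are assigned cell types round-robin so that every cell type
    appears in at least two studies (error otherwise).  Identical config and
    seed give bitwise-identical output.
    """
    cfg = config
    if min(cfg.n_studies, cfg.samples_per_study) < 2:
        raise ValueError(
            "every cell type must be coverable by >=2 studies; "
            "increase n_studies and samples_per_study to >=2"
        )
    rng = np.random.default_rng(cfg.seed)
    n_ct = cfg.n_cell_types
    cell_types = [f"ct{t:02d}" for t in range(n_ct)]
    class_names = list(_CLASS_POOL[: cfg.n_classes])
    class_of = {ct: class_names[t % cfg.n_classes] for t, ct in enumerate(cell_types)}

    # --- hairpins and arms -------------------------------------------------
    n_hairpins = max(1, round(cfg.n_mirnas / (1.0 + cfg.arm_pair_fraction)))
    n_paired = min(max(cfg.n_mirnas - n_hairpins, 0), n_hairpins)
    # rows: paired hairpins contribute 2 mature miRNAs, the rest 1
    n_hairpins = cfg.n_mirnas - n_paired

    hairpins = [f"mir-{h:04d}" for h in range(n_hairpins)]
    paired = set(hairpins[:n_paired])
    arm_ratio_choices = {"5p": 4.0, "3p": 0.25, "codominant": 1.0}

    mirna_ids: list[str] = []
    guide_ids: list[str] = []
    annotation: list[MiRNAAnnotation] = []
    dominant_arm: dict[str, str] = {}
    star_of: dict[str, str] = {}  # guide id -> star id (paired hairpins)
    star_ratio: dict[str, float] = {}  # guide id -> star/guide expression ratio

    node_probs = np.array([0.15, 0.25, 0.2, 0.2, 0.2])
    for h in hairpins:
        node = str(rng.choice(NODES, p=node_probs))
        in_gdb = bool(rng.random() < 0.9)
        gdb = (None, f"Mir-{h.split('-')[1]}")[in_gdb]
        if h in paired:
            call = str(rng.choice(["5p", "3p", "codominant"], p=[0.4, 0.4, 0.2]))
            dominant_arm[h] = call
            if call == "codominant":
                guide_arm = str(rng.choice(["5p", "3p"]))
                ratio = 1.0
            else:
                guide_arm = call
                ratio = 0.25  # star expressed at 1/4 of guide
            star_arm = "3p" if guide_arm == "5p" else "5p"
            gid, sid = f"{h}-{guide_arm}", f"{h}-{star_arm}"
            annotation.append(
                MiRNAAnnotation(gid, gdb and f"{gdb}_{guide_arm}", guide_arm,
                                "guide" if in_gdb else None, node, h)
            )
            annotation.append(
                MiRNAAnnotation(sid, gdb and f"{gdb}_{star_arm}*", star_arm,
                                "star" if in_gdb else None, node, h)
            )
            mirna_ids += [gid, sid]
            guide_ids.append(gid)
            star_of[gid] = sid
            star_ratio[gid] = ratio
        else:
            arm = str(rng.choice(["5p", "3p"]))
            gid = f"{h}-{arm}"
            annotation.append(
                MiRNAAnnotation(gid, gdb and f"{gdb}_{arm}", arm,
                                "guide" if in_gdb else None, node, h)
            )
            mirna_ids.append(gid)
            guide_ids.append(gid)

    # --- planted expression profiles (RPM scale, guide strands) ------------
    profile = np.zeros((len(mirna_ids), n_ct))
    row_of = {g: i for i, g in enumerate(mirna_ids)}
    specificity_label: dict[str, str] = {}
    home_cells: dict[str, list[str]] = {}

    order = rng.permutation(len(guide_ids))
    cursor = 0
    planted: list[tuple[str, str]] = []
    for tier in SPECIFICITY_TIERS:
        for _ in range(cfg.planted_category_counts.get(tier, 0)):
            planted.append((guide_ids[order[cursor]], tier))
            cursor += 1

    for gid, tier in planted:
        n_home = _n_home_cells(tier, n_ct, rng)
        home = rng.choice(n_ct, size=n_home, replace=False)
        row = np.full(n_ct, cfg.background_rpm)
        # mild jitter keeps ubiquitous profiles flat but not degenerate
        row[home] = cfg.specific_high_rpm * np.exp(rng.normal(0.0, 0.1, n_home))
        profile[row_of[gid]] = row
        specificity_label[gid] = tier
        home_cells[gid] = sorted(cell_types[i] for i in home)

    # unplanted guides get lognormal relative weights; they absorb whatever
    # RPM budget the planted rows leave, so planted RPM levels are exact
    unplanted_rows = []
    for i in range(cursor, len(guide_ids)):
        gid = guide_ids[order[i]]
        base = 50.0 * np.exp(rng.normal(0.0, 1.0))
        profile[row_of[gid]] = base * np.exp(rng.normal(0.0, 0.4, n_ct))
        unplanted_rows.append(row_of[gid])

    # star strands follow their guide at the planted ratio
    for gid, sid in star_of.items():
        profile[row_of[sid]] = profile[row_of[gid]] * star_ratio[gid]
        if row_of[gid] in set(unplanted_rows):
            unplanted_rows.append(row_of[sid])

    unplanted_rows = sorted(set(unplanted_rows))
    planted_rows = [i for i in range(len(mirna_ids)) if i not in set(unplanted_rows)]
    planted_sum = profile[planted_rows].sum(axis=0) if planted_rows else 0.0
    if np.any(planted_sum >= 1e6):
        raise ValueError(
            "planted expression exceeds the per-column RPM budget of 1e6; "
            "lower specific_high_rpm or plant fewer miRNAs"
        )
    if unplanted_rows:
        w = profile[unplanted_rows]
        profile[unplanted_rows] = w / w.sum(axis=0, keepdims=True) * (
            1e6 - planted_sum
        )
    else:
        # no free rows: fall back to global rescale
        profile = profile / profile.sum(axis=0, keepdims=True) * 1e6
    expected_rpm = pd.DataFrame(profile, index=mirna_ids, columns=cell_types)

    # --- study design -------------------------------------------------------
    studies = [f"study{s:02d}" for s in range(cfg.n_studies)]
    meta: list[RunMetadata] = []
    ct_index: list[int] = []
    for s in range(cfg.n_studies):
        for j in range(cfg.samples_per_study):
            # global round-robin: every cell type lands in many studies
            t = (s * cfg.samples_per_study + j) % n_ct
            ct = cell_types[t]
            meta.append(
                RunMetadata(
                    run_id=f"{studies[s]}_r{j:02d}",
                    sample_id=f"{studies[s]}_r{j:02d}",
                    study_id=studies[s],
                    cell_type=ct,
                    cell_class=class_of[ct],
                )
            )
            ct_index.append(t)
    coverage = pd.DataFrame({"ct": ct_index, "study": [m.study_id for m in meta]})
    n_studies_per_ct = coverage.groupby("ct")["study"].nunique()
    covered = set(n_studies_per_ct.index)
    if any(t not in covered for t in range(n_ct)) or (n_studies_per_ct < 2).any():
        raise ValueError(
            "some cell type is covered by fewer than two studies; "
            "increase n_studies or samples_per_study"
        )

    # --- counts -------------------------------------------------------------
    batch = np.exp(
        rng.normal(0.0, cfg.batch_log_sd, size=(cfg.n_studies, len(mirna_ids)))
    )
    batch_factors = pd.DataFrame(batch, index=studies, columns=mirna_ids)
    lib = rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd,
                        size=len(meta))
    study_idx = {s: i for i, s in enumerate(studies)}
    alpha = cfg.nb_dispersion
    counts = np.empty((len(mirna_ids), len(meta)), dtype=np.int64)
    for j, m in enumerate(meta):
        mu = lib[j] * profile[:, ct_index[j]] / 1e6 * batch[study_idx[m.study_id]]
        r = 1.0 / alpha
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=mirna_ids, columns=[m.run_id for m in meta]),
        ["simulate_atlas"],
    )
    truth = GroundTruth(
        specificity_label=specificity_label,
        home_cells=home_cells,
        dominant_arm=dominant_arm,
        batch_factors=batch_factors,
        expected_rpm=expected_rpm,
    )
    return cm, meta, annotation, truth


def simulate_mixture(
    profiles: NormalizedMatrix,
    proportions: Sequence[float],
    noise_log_sd: float = 0.0,
    seed: int = 0,
    mixture_id: str = "mixture",
) -> tuple[pd.Series, dict[str, float]]:
    """Compose a mixture sample from cell-type profile columns.

    mixture = profiles . proportions, each entry then multiplied by
    exp(Normal(0, noise_log_sd)).  Proportions must be nonnegative and sum to
    one within 1e-9.  Returns the mixture vector and the ground-truth
    proportion record keyed by cell type.
    """
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 1 or len(props) != profiles.values.shape[1]:
        raise ValueError("proportions length must match number of profile columns")
    if (props < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {props.sum()!r}, not 1")
    rng = np.random.default_rng(seed)
    mix = profiles.values.to_numpy(float) @ props
    if noise_log_sd > 0:
        mix = mix * np.exp(rng.normal(0.0, noise_log_sd, size=mix.shape))
    series = pd.Series(mix, index=profiles.values.index, name=mixture_id)
    truth = dict(zip(profiles.values.columns, props.tolist()))
    return series, truth
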
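"""Atlas characterization: strand dominance, specificity tiers, class
enrichment, evolutionary-age contrast and tissue-vs-cell expression ratios."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import (
    AtlasValidationError,
    CountMatrix,
    MiRNAAnnotation,
    NormalizedMatrix,
    RunMetadata,
    annotation_frame,
)

__all__ = [
    "CharacterizationThresholds",
    "StrandCall",
    "SpecificityCall",
    "call_strand_dominance",
    "categorize_specificity",
    "class_enrichment",
    "rank_sum_test",
    "compare_mirna_ages",
    "tissue_cell_ratios",
    "OLD_NODES",
    "YOUNG_NODES",
]

OLD_NODES = frozenset({"Bilateria", "Vertebrata"})
YOUNG_NODES = frozenset({"Catarrhini", "HomoSapiens"})


@dataclass
class CharacterizationThresholds:
    """Every numeric cutoff used by the characterization stage.

    Defaults mirror the atlas-scale analysis: expression floor 100 RPM,
    strand-call eligibility >=1000 reads in >100 cell types with a 75%
    same-arm fraction, tier boundaries <5 / [5,10) / [10,30) and a >90%
    at-floor fraction for ubiquity, ratio cap 1.25, top-10 tissue miRNAs and
    8 top samples per class for the age contrast.
    """

    rpm_floor: float = 100.0
    strand_min_reads: int = 1000
    strand_min_cells: int = 100
    strand_cell_fraction: float = 0.75
    specific_max: int = 5
    infrequent_max: int = 10
    frequent_max: int = 30
    ubiquitous_fraction: float = 0.90
    dominant_rel_fraction: float = 0.10
    ubiquitous_peak_ceiling: float = 20.0  # max/median ceiling for "no peaks"
    ratio_cap: float = 1.25
    top_k_tissue: int = 10
    age_top_samples: int = 8

    def __post_init__(self) -> None:
        if not self.specific_max < self.infrequent_max < self.frequent_max:
            raise ValueError("tier boundaries must be strictly increasing")
        if not 0 < self.ubiquitous_fraction < 1:
            raise ValueError("ubiquitous_fraction must be in (0, 1)")
        for name in ("rpm_floor", "strand_min_reads", "strand_min_cells",
                     "strand_cell_fraction", "dominant_rel_fraction",
                     "ratio_cap", "top_k_tissue", "age_top_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StrandCall:
    hairpin_family: str
    eligible_cells: int
    fraction_5p: float
    call: Literal["5p", "3p", "codominant"]


@dataclass
class SpecificityCall:
    mirna: str
    n_dominant_cells: int
    n_cells_at_floor: int
    tier: str


def call_strand_dominance(
    counts: CountMatrix | NormalizedMatrix,
    annotation: Sequence[MiRNAAnnotation],
    th: CharacterizationThresholds | None = None,
) -> list[StrandCall]:
    """Call the dominant arm (5p/3p/codominant) of each eligible hairpin.

    ``counts`` is a cell-type-level matrix (columns = cell types).  A cell
    type is eligible for a hairpin when the summed 5p+3p reads reach
    ``strand_min_reads``; the hairpin gets a call when more than
    ``strand_min_cells`` cell types are eligible.  Within an eligible cell
    the arm with the larger value dominates (ties count half to each arm);
    the call requires the same arm in more than ``strand_cell_fraction`` of
    eligible cells, else codominant.  Hairpins with a single annotated arm
    are skipped with a warning.
    """
    th = th or CharacterizationThresholds()
    ann = annotation_frame(annotation)
    vals = counts.values
    calls: list[StrandCall] = []
    skipped: list[str] = []
    for fam, grp in ann.groupby("hairpin_family", sort=True):
        arms = dict(zip(grp["arm"], grp["mirbase_id"]))
        if set(arms) != {"5p", "3p"}:
            skipped.append(str(fam))
            continue
        if arms["5p"] not in vals.index or arms["3p"] not in vals.index:
            skipped.append(str(fam))
            continue
        v5 = vals.loc[arms["5p"]].to_numpy(float)
        v3 = vals.loc[arms["3p"]].to_numpy(float)
        eligible = (v5 + v3) >= th.strand_min_reads
        n_eligible = int(eligible.sum())
        if n_eligible <= th.strand_min_cells:
            continue
        wins5 = (v5[eligible] > v3[eligible]).sum() + 0.5 * (
            v5[eligible] == v3[eligible]
        ).sum()
        frac5 = float(wins5) / n_eligible
        if frac5 > th.strand_cell_fraction:
            call = "5p"
        elif (1.0 - frac5) > th.strand_cell_fraction:
            call = "3p"
        else:
            call = "codominant"
        calls.append(StrandCall(fam, n_eligible, frac5, call))
    if skipped:
        warnings.warn(
            f"{len(skipped)} hairpin(s) lack a paired arm in the matrix and "
            f"were skipped (first: {skipped[0]!r})",
            stacklevel=2,
        )
    return calls


def categorize_specificity(
    cell_rpm: NormalizedMatrix,
    annotation: Sequence[MiRNAAnnotation],
    th: CharacterizationThresholds | None = None,
) -> list[SpecificityCall]:
    """Assign each miRNA a cell-specificity tier from cell-type-level RPM.

    A cell is *dominant* for a miRNA when its RPM is at least ``rpm_floor``
    and at least ``dominant_rel_fraction`` of the miRNA's maximum across
    cells (the formulaic stand-in for "relative RPM peaks").  Tiers by the
    dominant-cell count: <specific_max cell_specific, <infrequent_max
    infrequent, <frequent_max frequent, else near_ubiquitous — promoted to
    ubiquitous when the at-floor cell fraction exceeds
    ``ubiquitous_fraction`` and the profile shows no dominant peak
    (max/median below ``ubiquitous_peak_ceiling``).  miRNAs never reaching
    the floor are unclassified.  Restrict the input to curated guide strands
    first (``filter_features``).
    """
    th = th or CharacterizationThresholds()
    if cell_rpm.values.size == 0:
        raise AtlasValidationError("empty matrix")
    vals = cell_rpm.values.to_numpy(float)
    n_cells = vals.shape[1]
    vmax = vals.max(axis=1)
    at_floor = (vals >= th.rpm_floor).sum(axis=1)
    dominant = (
        (vals >= th.rpm_floor)
        & (vals >= th.dominant_rel_fraction * vmax[:, None])
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        med = np.median(vals, axis=1)
        peak_ratio = np.where(med > 0, vmax / med, np.inf)

    calls = []
    for i, mirna in enumerate(cell_rpm.values.index):
        if vmax[i] < th.rpm_floor:
            tier = "unclassified"
        elif dominant[i] < th.specific_max:
            tier = "cell_specific"
        elif dominant[i] < th.infrequent_max:
            tier = "infrequent"
        elif dominant[i] < th.frequent_max:
            tier = "frequent"
        elif (
            at_floor[i] > th.ubiquitous_fraction * n_cells
            and peak_ratio[i] < th.ubiquitous_peak_ceiling
        ):
            tier = "ubiquitous"
        else:
            tier = "near_ubiquitous"
        calls.append(
            SpecificityCall(str(mirna), int(dominant[i]), int(at_floor[i]), tier)
        )
    return calls


def class_enrichment(
    cell_rpm: NormalizedMatrix,
    class_of: Mapping[str, str],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-miRNA class enrichment: sum RPM within class, rescale to 100.

    ``class_of`` maps every cell-type column to a class (e.g. a 7-way
    grouping where blood = immune + rbc + platelet).  Rows with zero total
    get all-zero output and a False ``expressed`` flag instead of an error.
    """
    missing = [c for c in cell_rpm.values.columns if c not in class_of]
    if missing:
        raise AtlasValidationError(f"cell types without a class: {missing[:5]}")
    groups = pd.Index([class_of[c] for c in cell_rpm.values.columns])
    if classes is None:
        classes = sorted(groups.unique())
    sums = cell_rpm.values.T.groupby(groups).sum().T.reindex(columns=classes,
                                                             fill_value=0.0)
    total = sums.sum(axis=1)
    out = sums.div(total.where(total > 0, 1.0), axis=0) * 100.0
    out[total == 0] = 0.0
    out["expressed"] = total > 0
    return out


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact permutation enumeration (tie-safe) when both groups have <= 10
    observations; otherwise the normal approximation with tie correction and
    continuity correction.  Returns (Mann-Whitney U of ``x``, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n].sum()
    u_obs = w_obs - n * (n + 1) / 2.0
    if n <= 10 and m <= 10:
        mean_w = ranks.sum() * n / (n + m)
        obs_dev = abs(w_obs - mean_w)
        count = 0
        total = 0
        for comb in itertools.combinations(range(n + m), n):
            w = ranks[list(comb)].sum()
            if abs(w - mean_w) >= obs_dev - 1e-12:
                count += 1
            total += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_mirna_ages(
    vst: NormalizedMatrix,
    annotation: Sequence[MiRNAAnnotation],
    meta: Sequence[RunMetadata],
    th: CharacterizationThresholds | None = None,
    exclude_classes: Sequence[str] = ("other",),
) -> tuple[float, float, float, float, list[str]]:
    """Contrast expression of evolutionarily old vs young miRNAs.

    From each cell class, the ``age_top_samples`` samples with the highest
    summed VST are selected; the per-(miRNA, sample) VST values of
    Bilateria/Vertebrata-node miRNAs are compared against
    Catarrhini/HomoSapiens-node miRNAs with a two-sided rank-sum test.
    Returns (old_mean, young_mean, U statistic, p-value, selected samples).
    """
    th = th or CharacterizationThresholds()
    ann = annotation_frame(annotation).reindex(vst.values.index)
    old_ids = ann.index[ann["node_of_origin"].isin(OLD_NODES)]
    young_ids = ann.index[ann["node_of_origin"].isin(YOUNG_NODES)]
    if len(old_ids) == 0 or len(young_ids) == 0:
        raise AtlasValidationError("old or young node group is empty")

    mmap = {m.run_id: m for m in meta}
    cols = [c for c in vst.values.columns if c in mmap]
    by_class: dict[str, list[str]] = {}
    for c in cols:
        cl = mmap[c].cell_class
        if cl in exclude_classes:
            continue
        by_class.setdefault(cl, []).append(c)
    sums = vst.values.sum(axis=0)
    selected: list[str] = []
    for cl, members in sorted(by_class.items()):
        if len(members) < th.age_top_samples:
            continue
        top = sums[members].sort_values(ascending=False).index[: th.age_top_samples]
        selected.extend(top)
    if not selected:
        raise AtlasValidationError(
            f"no class has >= {th.age_top_samples} samples"
        )
    old_vals = vst.values.loc[old_ids, selected].to_numpy(float).ravel()
    young_vals = vst.values.loc[young_ids, selected].to_numpy(float).ravel()
    statistic, p = rank_sum_test(old_vals, young_vals)
    return (
        float(old_vals.mean()),
        float(young_vals.mean()),
        statistic,
        p,
        selected,
    )


def tissue_cell_ratios(
    tissue_rpm: pd.Series,
    cell_rpm: NormalizedMatrix,
    th: CharacterizationThresholds | None = None,
) -> pd.DataFrame:
    """Ratio of tissue RPM to the mean constituent-cell RPM for the tissue's
    top expressed miRNAs.

    Selects the ``top_k_tissue`` miRNAs by tissue RPM (descending) and
    reports tissue RPM, each cell type's RPM, their mean, and the capped
    ratio tissue/mean (values above ``ratio_cap`` set to the cap; a zero
    cell mean reports the cap with a divide-by-zero flag).
    """
    th = th or CharacterizationThresholds()
    shared = tissue_rpm.index.intersection(cell_rpm.values.index)
    if len(shared) == 0:
        raise AtlasValidationError("tissue and cell matrices share no miRNA keys")
    t = tissue_rpm.loc[shared].sort_values(ascending=False)
    top = t.index[: th.top_k_tissue]
    cells = cell_rpm.values.loc[top]
    mean_cell = cells.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_ratio = tissue_rpm.loc[top] / mean_cell
    divzero = mean_cell == 0
    ratio = raw_ratio.where(~divzero, np.inf)
    capped = ratio > th.ratio_cap
    out = pd.DataFrame(
        {
            "tissue_rpm": tissue_rpm.loc[top],
            **{ct: cells[ct] for ct in cells.columns},
            "cell_mean_rpm": mean_cell,
            "ratio": ratio.clip(upper=th.ratio_cap),
            "capped": capped,
            "divide_by_zero": divzero,
        }
    )
    out.index.name = "mirna"
    return out
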
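"""Leave-one-study-out nearest-centroid benchmarking of normalization methods.

Each study is held out once; cell-type centroids are averaged from all other
studies and every held-out sample is assigned to the centroid minimizing
Euclidean distance.  Accuracy = matches / predictions.  By design the
normalizations are fit on the full matrix before fold splitting (a strict
per-fold refit is available for the methods that support it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .atlas_io import (
    AtlasValidationError,
    CountMatrix,
    NormalizedMatrix,
    RunMetadata,
    compute_rpm,
)
from .normalization import (
    ControlGeneCriteria,
    add_pseudocount,
    combat_adjust,
    log2_transform,
    ruv_adjust,
    select_control_genes,
    size_factors_median_of_ratios,
    vst_normalize,
)

__all__ = [
    "Centroid",
    "LOSOResult",
    "METHODS",
    "compute_centroids",
    "assign_nearest_centroid",
    "loso_crossvalidate",
    "compare_normalizations",
    "default_reference_gene",
]


@dataclass
class Centroid:
    label: str
    vector: np.ndarray
    n_training: int


@dataclass
class LOSOResult:
    """Per-sample assignments plus the derived accuracy summaries."""

    per_sample: pd.DataFrame  # sample_id, study_id, truth, prediction, distance, tie
    overall_accuracy: float
    per_class_matrix: pd.DataFrame  # truth x predicted fractions, rows sum to 1
    n_folds: int


def compute_centroids(
    matrix: NormalizedMatrix, labels: Mapping[str, str]
) -> list[Centroid]:
    """One centroid per distinct label; vector = arithmetic mean of samples."""
    if not labels:
        raise AtlasValidationError("empty label set")
    missing = [c for c in matrix.values.columns if c not in labels]
    if missing:
        raise AtlasValidationError(f"samples without a label: {missing[:5]}")
    lab = pd.Index([labels[c] for c in matrix.values.columns])
    out = []
    for value in sorted(lab.unique()):
        cols = matrix.values.columns[lab == value]
        out.append(
            Centroid(
                label=value,
                vector=matrix.values[cols].mean(axis=1).to_numpy(float),
                n_training=len(cols),
            )
        )
    return out


def assign_nearest_centroid(
    sample: np.ndarray, centroids: Sequence[Centroid]
) -> tuple[str, float, bool]:
    """Assign to the centroid minimizing Euclidean distance.

    Exact ties are broken by lexicographically smallest label and flagged in
    the third return value.
    """
    if not centroids:
        raise AtlasValidationError("need at least one centroid")
    sample = np.asarray(sample, dtype=float)
    dists = []
    for c in centroids:
        if c.vector.shape != sample.shape:
            raise AtlasValidationError(
                f"dimension mismatch: sample {sample.shape} vs centroid "
                f"{c.label!r} {c.vector.shape}"
            )
        dists.append(float(np.linalg.norm(sample - c.vector)))
    dmin = min(dists)
    winners = sorted(c.label for c, d in zip(centroids, dists) if d == dmin)
    return winners[0], dmin, len(winners) > 1


UNPREDICTABLE = "<unpredictable>"


def loso_crossvalidate(
    matrix: NormalizedMatrix,
    meta: Sequence[RunMetadata],
    target_labels: Mapping[str, str] | None = None,
) -> LOSOResult:
    """Leave-one-study-out nearest-centroid cross-validation.

    ``target_labels`` optionally maps each sample's cell type to a coarser
    label vocabulary (e.g. a 5-group benchmark); identity by default.  A truth
    label absent from a fold's training studies is recorded as
    ``<unpredictable>`` and still counts in the accuracy denominator.
    """
    mmap = {m.run_id: m for m in meta}
    missing = [c for c in matrix.values.columns if c not in mmap]
    if missing:
        raise AtlasValidationError(f"columns without metadata: {missing[:5]}")
    cols = list(matrix.values.columns)
    truth = {c: mmap[c].cell_type for c in cols}
    if target_labels is not None:
        truth = {c: target_labels.get(t, t) for c, t in truth.items()}
    studies = sorted({mmap[c].study_id for c in cols})
    if len(studies) < 2:
        raise AtlasValidationError("leave-one-study-out requires >= 2 studies")

    X = matrix.values.to_numpy(float).T  # samples x genes
    col_idx = {c: i for i, c in enumerate(cols)}
    records = []
    for study in studies:
        test = [c for c in cols if mmap[c].study_id == study]
        train = [c for c in cols if mmap[c].study_id != study]
        if not test:
            continue
        train_labels = sorted({truth[c] for c in train})
        cent = np.stack(
            [
                X[[col_idx[c] for c in train if truth[c] == lab]].mean(axis=0)
                for lab in train_labels
            ]
        )
        D = cdist(X[[col_idx[c] for c in test]], cent)
        for i, c in enumerate(test):
            row = D[i]
            dmin = row.min()
            winners = [train_labels[j] for j in np.flatnonzero(row == dmin)]
            pred = sorted(winners)[0]
            records.append(
                {
                    "sample_id": c,
                    "study_id": study,
                    "truth": truth[c],
                    "prediction": pred,
                    "predictable": truth[c] in train_labels,
                    "distance": float(dmin),
                    "tie": len(winners) > 1,
                }
            )
    per_sample = pd.DataFrame.from_records(records)
    # unpredictable truths keep their (necessarily wrong) prediction slot but
    # are marked; they count in the denominator either way
    per_sample.loc[~per_sample["predictable"], "prediction"] = UNPREDICTABLE
    correct = (per_sample["truth"] == per_sample["prediction"]).sum()
    overall = float(correct) / len(per_sample)
    per_class = (
        pd.crosstab(per_sample["truth"], per_sample["prediction"], normalize="index")
        .rename_axis(index="truth", columns="predicted")
    )
    return LOSOResult(
        per_sample=per_sample,
        overall_accuracy=overall,
        per_class_matrix=per_class,
        n_folds=len(studies),
    )


# ---------------------------------------------------------------------------
# named normalization pipelines


def default_reference_gene(rpm: NormalizedMatrix) -> str:
    """Pick a reference gene for the control-gene bracket: the feature with
    the largest 25th-percentile RPM across samples (a high, stable gene)."""
    q1 = rpm.values.quantile(0.25, axis=1)
    return str(q1.idxmax())


def _auto_controls(counts: CountMatrix, k_needed: int) -> list[str]:
    rpm = compute_rpm(counts)
    ref = default_reference_gene(rpm)
    controls = select_control_genes(rpm, ControlGeneCriteria(reference_mirnas=[ref]))
    if len(controls) < max(k_needed, 1):  # pragma: no cover - degenerate picker
        q1 = rpm.values.quantile(0.25, axis=1).sort_values(ascending=False)
        controls = list(q1.index[: max(k_needed, 10)])
    return controls


def _delog(nm: NormalizedMatrix) -> CountMatrix:
    """Back-transform a log2-scale matrix to nonnegative pseudo-counts."""
    vals = np.maximum(np.rint(2.0 ** nm.values.to_numpy(float)) - 1.0, 0.0)
    df = pd.DataFrame(
        vals.astype(np.int64), index=nm.values.index, columns=nm.values.columns
    )
    return CountMatrix(df, nm.provenance + ["delog"])


def _pipeline_registry() -> dict[str, Callable]:
    def raw(counts, meta, ctx):
        return NormalizedMatrix(
            counts.values.astype(float), "raw", counts.provenance
        )

    def log2p(counts, meta, ctx):
        return log2_transform(add_pseudocount(counts))

    def vst(counts, meta, ctx):
        c1 = add_pseudocount(counts)
        nm, _ = vst_normalize(c1, size_factors_median_of_ratios(c1))
        return nm

    def combat(counts, meta, ctx):
        lg = log2p(counts, meta, ctx)
        batch = [ctx["study"][c] for c in lg.values.columns]
        group = [ctx["group"][c] for c in lg.values.columns]
        return combat_adjust(lg, batch, group)

    def combat_vst(counts, meta, ctx):
        adj = combat(counts, meta, ctx)
        return vst(_delog(adj), meta, ctx)

    def ruvg(counts, meta, ctx):
        lg = log2p(counts, meta, ctx)
        controls = ctx.get("controls") or _auto_controls(counts, ctx["k"])
        nm, _ = ruv_adjust(lg, ctx["k"], "controls", controls=controls)
        return nm

    def ruvg_vst(counts, meta, ctx):
        return vst(_delog(ruvg(counts, meta, ctx)), meta, ctx)

    def ruvr(counts, meta, ctx):
        lg = log2p(counts, meta, ctx)
        design_key = ctx.get("ruvr_design", "batch")
        design = [ctx["study" if design_key == "batch" else "group"][c]
                  for c in lg.values.columns]
        nm, _ = ruv_adjust(lg, ctx["k"], "residuals", design=design)
        return nm

    def ruvr_vst(counts, meta, ctx):
        return vst(_delog(ruvr(counts, meta, ctx)), meta, ctx)

    return {
        "raw": raw,
        "log2": log2p,
        "vst": vst,
        "combat": combat,
        "combat+vst": combat_vst,
        "ruvg": ruvg,
        "ruvg+vst": ruvg_vst,
        "ruvr": ruvr,
        "ruvr+vst": ruvr_vst,
    }


METHODS = tuple(_pipeline_registry())


def compare_normalizations(
    counts: CountMatrix,
    meta: Sequence[RunMetadata],
    methods: Sequence[str],
    *,
    target_labels: Mapping[str, str] | None = None,
    ruv_k: int = 1,
    ruv_controls: Sequence[str] | None = None,
    ruvr_design: Literal["batch", "group"] = "batch",
) -> pd.DataFrame:
    """Score each named normalization pipeline by LOSO accuracy.

    Returns one row per method with overall accuracy and per-truth-class
    accuracy columns (diagonal of the confusion table).  Folds are identical
    across methods, so rows are directly comparable.
    """
    if not methods:
        raise ValueError("empty method list")
    registry = _pipeline_registry()
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise ValueError(f"unknown method name(s): {unknown}")
    ctx = {
        "study": {m.run_id: m.study_id for m in meta},
        "group": {m.run_id: m.cell_type for m in meta},
        "k": ruv_k,
        "controls": list(ruv_controls) if ruv_controls else None,
        "ruvr_design": ruvr_design,
    }
    rows = []
    for name in methods:
        nm = registry[name](counts, meta, ctx)
        res = loso_crossvalidate(nm, meta, target_labels=target_labels)
        row = {"method": name, "accuracy": res.overall_accuracy}
        diag = {
            t: float(res.per_class_matrix.loc[t, t])
            if t in res.per_class_matrix.columns
            else 0.0
            for t in res.per_class_matrix.index
        }
        row.update(diag)
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
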
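"""Loading, validation, merging, filtering and summarization of miRNA count atlases.

The atlas substrate is a nonnegative integer miRNA x run count matrix plus two
side tables: per-run metadata (sample, study/batch, cell type, cell class) and
a miRNA annotation table (curated-database membership, 5p/3p arm, guide/star
role, phylogenetic node of origin).  All matrices are key-addressed pandas
frames; column order is never meaningful.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_CLASSES",
    "NODES",
    "AtlasValidationError",
    "MiRNAAnnotation",
    "RunMetadata",
    "CountMatrix",
    "NormalizedMatrix",
    "load_atlas",
    "merge_technical_replicates",
    "compute_rpm",
    "filter_features",
    "summarize_by_cell_type",
    "annotation_frame",
    "metadata_frame",
    "write_counts",
    "write_metadata",
    "write_annotation",
    "write_matrix",
]

#: Closed 13-class vocabulary for ``RunMetadata.cell_class``.
CELL_CLASSES = (
    "brain",
    "endothelial",
    "epithelial",
    "fat",
    "fibroblast",
    "immune",
    "muscle",
    "other",
    "plasma",
    "platelet",
    "rbc",
    "sperm",
    "stem",
)

#: Recognized phylogenetic nodes of origin.
NODES = ("Bilateria", "Vertebrata", "Catarrhini", "HomoSapiens", "other")


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates a structural invariant."""


@dataclass(frozen=True)
class MiRNAAnnotation:
    """One mature-miRNA annotation record.

    ``hairpin_family`` links the 5p and 3p products of a single hairpin;
    ``strand_role`` (guide/star) is defined only for curated entries, i.e.
    those carrying a ``mirgenedb_id``.
    """

    mirbase_id: str
    mirgenedb_id: str | None
    arm: Literal["5p", "3p"]
    strand_role: Literal["guide", "star"] | None
    node_of_origin: str
    hairpin_family: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise AtlasValidationError(f"unknown arm {self.arm!r} for {self.mirbase_id}")
        if self.strand_role not in ("guide", "star", None):
            raise AtlasValidationError(
                f"unknown strand_role {self.strand_role!r} for {self.mirbase_id}"
            )
        if self.strand_role is not None and not self.mirgenedb_id:
            raise AtlasValidationError(
                f"strand_role set without mirgenedb_id for {self.mirbase_id}"
            )
        if self.node_of_origin not in NODES:
            raise AtlasValidationError(
                f"unknown node_of_origin {self.node_of_origin!r} for {self.mirbase_id}"
            )


@dataclass(frozen=True)
class RunMetadata:
    """Per-run labels: sample, study (= batch), cell type and cell class."""

    run_id: str
    sample_id: str
    study_id: str
    cell_type: str
    cell_class: str

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise AtlasValidationError(
                f"cell_class {self.cell_class!r} of run {self.run_id!r} is not one of "
                f"the {len(CELL_CLASSES)} known classes"
            )


def _check_keys(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise AtlasValidationError(f"duplicate row key {dup!r}")
    if values.columns.has_duplicates:
        dup = values.columns[values.columns.duplicated()][0]
        raise AtlasValidationError(f"duplicate column key {dup!r}")


@dataclass
class CountMatrix:
    """Nonnegative integer miRNA x run matrix (rows = miRNAs, columns = runs)."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_keys(self.values)
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float input only when every entry is integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                r, c = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
                raise AtlasValidationError(
                    f"non-integer count at row {self.values.index[r]!r}, "
                    f"column {self.values.columns[c]!r}"
                )
            self.values = self.values.astype(np.int64)
            arr = self.values.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise AtlasValidationError(
                f"negative count at row {self.values.index[r]!r}, "
                f"column {self.values.columns[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.provenance))


Unit = Literal["raw", "rpm", "log2", "vst", "adjusted"]


@dataclass
class NormalizedMatrix:
    """Real-valued matrix tagged with the unit it is expressed in.

    ``provenance`` is the ordered list of transformation names that produced
    the matrix; it must be non-empty unless ``unit == "raw"``.
    """

    values: pd.DataFrame
    unit: Unit
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_keys(self.values)
        if self.unit not in ("raw", "rpm", "log2", "vst", "adjusted"):
            raise AtlasValidationError(f"unknown unit {self.unit!r}")
        if self.unit != "raw" and not self.provenance:
            raise AtlasValidationError("non-raw matrix requires provenance")
        if self.unit == "rpm" and self.values.shape[0]:
            sums = self.values.sum(axis=0).to_numpy(float)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                bad = self.values.columns[int(np.argmax(np.abs(sums - 1e6)))]
                raise AtlasValidationError(
                    f"rpm column {bad!r} does not sum to 1e6 (got {sums.max():.6g})"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(self.values.copy(), self.unit, list(self.provenance))


# ---------------------------------------------------------------------------
# parsing helpers

_META_COLS = ["run_id", "sample_id", "study_id", "cell_type", "cell_class"]
_ANN_COLS = [
    "mirbase_id",
    "mirgenedb_id",
    "arm",
    "strand_role",
    "node_of_origin",
    "hairpin_family",
]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), comment="#", **kw)


def metadata_frame(meta: Sequence[RunMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by run_id."""
    df = pd.DataFrame([vars(m) for m in meta], columns=_META_COLS)
    return df.set_index("run_id", drop=False)


def annotation_frame(annotation: Sequence[MiRNAAnnotation]) -> pd.DataFrame:
    """Annotation records as a DataFrame indexed by mirbase_id."""
    df = pd.DataFrame([vars(a) for a in annotation], columns=_ANN_COLS)
    return df.set_index("mirbase_id", drop=False)


def _validate_metadata(meta: Sequence[RunMetadata]) -> None:
    seen: dict[str, RunMetadata] = {}
    per_sample: dict[str, tuple[str, str]] = {}
    for m in meta:
        if m.run_id in seen:
            raise AtlasValidationError(f"duplicate run_id {m.run_id!r} in metadata")
        seen[m.run_id] = m
        key = (m.cell_type, m.study_id)
        prev = per_sample.setdefault(m.sample_id, key)
        if prev != key:
            raise AtlasValidationError(
                f"sample {m.sample_id!r} maps to conflicting (cell_type, study): "
                f"{prev} vs {key}"
            )


def _validate_annotation(annotation: Sequence[MiRNAAnnotation]) -> None:
    seen: set[str] = set()
    arms: dict[str, set[str]] = {}
    for a in annotation:
        if a.mirbase_id in seen:
            raise AtlasValidationError(f"duplicate mirbase_id {a.mirbase_id!r}")
        seen.add(a.mirbase_id)
        fam = arms.setdefault(a.hairpin_family, set())
        if a.arm in fam:
            raise AtlasValidationError(
                f"hairpin family {a.hairpin_family!r} has two {a.arm} records"
            )
        fam.add(a.arm)


def load_atlas(
    counts_source: str | Path,
    metadata_source: str | Path,
    annotation_source: str | Path,
) -> tuple[CountMatrix, list[RunMetadata], list[MiRNAAnnotation]]:
    """Load and cross-validate a count matrix with its metadata and annotation.

    The counts table has a header row of run ids and a first column of miRNA
    ids.  Every count column must have a metadata record and vice versa;
    annotation may cover only a subset of rows (unannotated rows are retained).

    Raises
    ------
    AtlasValidationError
        On duplicate keys, negative or non-integer counts, or a run present in
        only one of counts/metadata.
    """
    # duplicate run ids in the header would be silently mangled by pandas
    with open(counts_source, newline="") as fh:
        for row in csv.reader(fh, delimiter=_sep_for(counts_source)):
            if row and not row[0].startswith("#"):
                header = row[1:]
                break
        else:  # pragma: no cover - empty file
            raise AtlasValidationError(f"empty counts file {counts_source}")
    dupes = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dupes):
        raise AtlasValidationError(f"duplicate run_id {dupes[0]!r} in counts header")

    raw = _read_table(counts_source, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    counts = CountMatrix(raw)

    mdf = _read_table(metadata_source, dtype=str)
    missing = set(_META_COLS) - set(mdf.columns)
    if missing:
        raise AtlasValidationError(f"metadata missing columns {sorted(missing)}")
    meta = [RunMetadata(**{c: row[c] for c in _META_COLS}) for _, row in mdf.iterrows()]
    _validate_metadata(meta)

    meta_runs = {m.run_id for m in meta}
    count_runs = set(counts.values.columns)
    if count_runs - meta_runs:
        raise AtlasValidationError(
            f"runs in counts missing from metadata: {sorted(count_runs - meta_runs)[:5]}"
        )
    if meta_runs - count_runs:
        raise AtlasValidationError(
            f"runs in metadata missing from counts: {sorted(meta_runs - count_runs)[:5]}"
        )

    adf = _read_table(annotation_source, dtype=str)
    missing = set(_ANN_COLS) - set(adf.columns)
    if missing:
        raise AtlasValidationError(f"annotation missing columns {sorted(missing)}")
    annotation = []
    for _, row in adf.iterrows():
        gdb = row["mirgenedb_id"]
        role = row["strand_role"]
        annotation.append(
            MiRNAAnnotation(
                mirbase_id=row["mirbase_id"],
                mirgenedb_id=None if pd.isna(gdb) or gdb == "" else gdb,
                arm=row["arm"],
                strand_role=None if pd.isna(role) or role == "" else role,
                node_of_origin=row["node_of_origin"],
                hairpin_family=row["hairpin_family"],
            )
        )
    _validate_annotation(annotation)
    return counts, meta, annotation


def merge_technical_replicates(
    counts: CountMatrix, meta: Sequence[RunMetadata]
) -> tuple[CountMatrix, list[RunMetadata]]:
    """Sum technical-replicate runs of the same sample into one column.

    Returns a matrix with one column per ``sample_id`` (columns keyed by
    sample id) and sample-level metadata.  Runs of one sample with conflicting
    cell type or study raise.
    """
    _validate_metadata(meta)
    mdf = metadata_frame(meta).loc[list(counts.values.columns)]
    merged = counts.values.T.groupby(mdf["sample_id"].to_numpy()).sum().T
    out_meta = []
    for sample_id, grp in mdf.groupby("sample_id", sort=False):
        out_meta.append(
            RunMetadata(
                run_id=str(sample_id),
                sample_id=str(sample_id),
                study_id=grp["study_id"].iloc[0],
                cell_type=grp["cell_type"].iloc[0],
                cell_class=grp["cell_class"].iloc[0],
            )
        )
    order = [m.run_id for m in out_meta]
    out = CountMatrix(merged[order], counts.provenance + ["merge_technical_replicates"])
    return out, out_meta


def compute_rpm(counts: CountMatrix) -> NormalizedMatrix:
    """Reads-per-million scaling: entry / column sum * 1e6.

    The denominator is the miRNA-mapped total of each column.  A zero-total
    column is an error naming the run.
    """
    sums = counts.values.sum(axis=0)
    if (sums == 0).any():
        run = sums.index[int(np.argmax(sums.to_numpy() == 0))]
        raise AtlasValidationError(f"column {run!r} has zero total count")
    vals = counts.values.to_numpy(float) / sums.to_numpy(float)[None, :] * 1e6
    df = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return NormalizedMatrix(df, "rpm", counts.provenance + ["compute_rpm"])


def filter_features(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: Sequence[MiRNAAnnotation],
    *,
    mirgenedb_only: bool = False,
    guide_only: bool = False,
    min_max_rpm: float | None = None,
    min_total_count: int | None = None,
    rpm: NormalizedMatrix | None = None,
    rpm_stat: Literal["max", "mean"] = "max",
) -> CountMatrix | NormalizedMatrix:
    """Drop feature rows failing any active criterion; row order preserved.

    ``min_max_rpm`` needs an RPM matrix over the same rows: either ``matrix``
    itself (unit ``rpm``) or the ``rpm`` argument — typically a cell-type-level
    summary, so the threshold reads "RPM >= t in at least one cell type".
    ``rpm_stat`` selects max (default) or mean across the RPM columns.
    """
    ann = annotation_frame(annotation)
    keep = pd.Series(True, index=matrix.values.index)
    applied: list[str] = []

    if mirgenedb_only or guide_only:
        ann = ann.reindex(matrix.values.index)
    if mirgenedb_only:
        keep &= ann["mirgenedb_id"].notna() & (ann["mirgenedb_id"] != "")
        applied.append("mirgenedb_only")
    if guide_only:
        keep &= ann["strand_role"] == "guide"
        applied.append("guide_only")
    if min_max_rpm is not None:
        if rpm is None:
            if isinstance(matrix, NormalizedMatrix) and matrix.unit == "rpm":
                rpm = matrix
            else:
                raise AtlasValidationError(
                    "min_max_rpm requires an RPM matrix (pass rpm=...)"
                )
        stat = rpm.values.max(axis=1) if rpm_stat == "max" else rpm.values.mean(axis=1)
        keep &= stat.reindex(matrix.values.index).fillna(-np.inf) >= min_max_rpm
        applied.append(f"min_{rpm_stat}_rpm>={min_max_rpm:g}")
    if min_total_count is not None:
        keep &= matrix.values.sum(axis=1) >= min_total_count
        applied.append(f"min_total_count>={min_total_count}")

    vals = matrix.values.loc[keep]
    prov = matrix.provenance + [f"filter_features[{','.join(applied) or 'none'}]"]
    if isinstance(matrix, CountMatrix):
        return CountMatrix(vals.copy(), prov)
    if matrix.unit == "rpm":
        # dropping rows breaks the column-sum invariant; result is generic
        return NormalizedMatrix(vals.copy(), "adjusted", prov)
    return NormalizedMatrix(vals.copy(), matrix.unit, prov)


def summarize_by_cell_type(
    matrix: NormalizedMatrix,
    meta: Sequence[RunMetadata],
    statistic: Literal["mean", "q3"] = "mean",
) -> NormalizedMatrix:
    """Collapse sample columns to one column per cell type.

    ``q3`` is the inclusive linear-interpolation 75th percentile over the
    type's samples; ``mean`` the arithmetic mean.  Every column of ``matrix``
    must have a known cell type.
    """
    if statistic not in ("mean", "q3"):
        raise AtlasValidationError(f"unknown statistic {statistic!r}")
    lookup = {m.run_id: m.cell_type for m in meta}
    unmapped = [c for c in matrix.values.columns if c not in lookup]
    if unmapped:
        raise AtlasValidationError(f"columns with unknown cell_type: {unmapped[:5]}")
    groups = pd.Index([lookup[c] for c in matrix.values.columns], name="cell_type")
    gb = matrix.values.T.groupby(groups)
    if statistic == "mean":
        out = gb.mean().T
    else:
        out = gb.quantile(0.75, interpolation="linear").T
    out = out.sort_index(axis=1)
    unit = matrix.unit if matrix.unit != "rpm" else "adjusted"
    return NormalizedMatrix(
        out, unit, matrix.provenance + [f"summarize_by_cell_type[{statistic}]"]
    )


# ---------------------------------------------------------------------------
# writers (same dialects as the readers; provenance as '#' comment lines)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    write_matrix(counts.values, path, provenance=counts.provenance)


def write_matrix(
    values: pd.DataFrame, path: str | Path, provenance: Iterable[str] = ()
) -> None:
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        for p in provenance:
            fh.write(f"# {p}\n")
        values.to_csv(fh, sep=sep)


def write_metadata(meta: Sequence[RunMetadata], path: str | Path) -> None:
    metadata_frame(meta).to_csv(path, sep=_sep_for(path), index=False)


def write_annotation(annotation: Sequence[MiRNAAnnotation], path: str | Path) -> None:
    df = annotation_frame(annotation).copy()
    df["mirgenedb_id"] = df["mirgenedb_id"].fillna("")
    df["strand_role"] = df["strand_role"].fillna("")
    df.to_csv(path, sep=_sep_for(path), index=False)
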
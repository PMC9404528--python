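"""Signature-based mixture deconvolution (nu-SVR with an NNLS fallback/oracle).

Builds a marker-gene signature matrix from a cell-type-level reference and
estimates nonnegative, sum-to-one cell-type proportions for mixture samples
such as plasma.  Marker candidacy uses per-gene rank-sum overexpression tests
with Benjamini-Hochberg adjustment (q threshold); the shared per-type marker
count is chosen within [g_min, g_max] to minimize the signature's 2-norm
condition number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import NuSVR

from .atlas_io import AtlasValidationError, NormalizedMatrix

__all__ = [
    "SignatureMatrix",
    "ProportionEstimate",
    "build_signature",
    "deconvolve",
    "deconvolve_cohort",
]

NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class SignatureMatrix:
    """Reference expression of selected marker genes x cell types."""

    values: pd.DataFrame
    selected_genes: list[str]
    per_type_gene_count: dict[str, int]
    condition_number: float


@dataclass
class ProportionEstimate:
    """Nonnegative cell-type proportions summing to one."""

    proportions: pd.Series
    solver: Literal["nu_svr", "nnls"]
    fit_rmse: float
    nu_selected: float | None = None
    mixture_id: str | None = None

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _one_vs_rest_pvalues(values: np.ndarray, t: int) -> np.ndarray:
    """Exact two-sided rank-sum p-value per gene for one cell-type column
    against the remaining columns (n=1 vs m design: p is a function of the
    column's rank among the T values)."""
    from scipy.stats import rankdata

    m = values.shape[1] - 1
    ranks = np.apply_along_axis(rankdata, 1, values)  # midranks for ties
    u = ranks[:, t] - 1.0  # number of others below (+0.5 per tie)
    p_low = (np.floor(u) + 1.0) / (m + 1.0)
    p_high = (m - np.ceil(u) + 1.0) / (m + 1.0)
    return np.minimum(2.0 * np.minimum(p_low, p_high), 1.0)


def build_signature(
    reference: NormalizedMatrix,
    q_threshold: float = 0.5,
    g_min: int = 50,
    g_max: int = 200,
    labels: Mapping[str, str] | None = None,
) -> SignatureMatrix:
    """Select marker genes per cell type and assemble the signature matrix.

    Candidates per type are genes overexpressed in that type versus all
    others with BH-adjusted rank-sum q below ``q_threshold``, ranked by fold
    change.  The shared per-type count G in [g_min, g_max] minimizing the
    2-norm condition number of the resulting matrix is kept.

    With ``labels`` (column -> cell type), ``reference`` holds sample-level
    replicate columns: the rank-sum test compares each type's samples against
    the rest and the signature stores per-type means.  Without labels the
    reference is already cell-type-level (one column per type); the per-gene
    rank statistic then has a single observation per group, which makes its
    p-values uniform by construction, so BH adjustment is skipped in that
    degenerate case and the exact rank p is compared to ``q_threshold``
    directly.
    """
    if labels is not None:
        missing = [c for c in reference.values.columns if c not in labels]
        if missing:
            raise AtlasValidationError(f"columns without labels: {missing[:5]}")
        groups = pd.Index([labels[c] for c in reference.values.columns])
        types = sorted(groups.unique())
        vals = reference.values.T.groupby(groups).mean().T[types]
    else:
        vals = reference.values
        types = list(vals.columns)
    if len(types) < 2:
        raise AtlasValidationError("need >= 2 cell types to build a signature")
    arr = vals.to_numpy(float)

    ranked_candidates: dict[str, list[str]] = {}
    for t, ct in enumerate(types):
        if labels is not None:
            sample_arr = reference.values.to_numpy(float)
            in_t = np.asarray(groups == ct)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.mannwhitneyu(
                    sample_arr[:, in_t], sample_arr[:, ~in_t],
                    alternative="two-sided", method="asymptotic", axis=1,
                )
            q = _bh_adjust(np.nan_to_num(res.pvalue, nan=1.0))
        else:
            q = _one_vs_rest_pvalues(arr, t)
        others = arr[:, [j for j in range(len(types)) if j != t]].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = (arr[:, t] + 1e-9) / (others + 1e-9)
        cand = (q < q_threshold) & (arr[:, t] > others)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            warnings.warn(f"cell type {ct!r} has no marker candidates", stacklevel=2)
            ranked_candidates[ct] = []
            continue
        ranked_candidates[ct] = [
            str(vals.index[i]) for i in idx[np.argsort(-fc[idx], kind="stable")]
        ]

    best: tuple[float, int, list[str]] | None = None
    max_avail = max((len(v) for v in ranked_candidates.values()), default=0)
    g_hi = min(g_max, max(max_avail, g_min))
    for G in range(g_min, g_hi + 1):
        genes: list[str] = []
        seen: set[str] = set()
        for ct in types:
            for g in ranked_candidates[ct][:G]:
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        if not genes:
            continue
        kappa = float(np.linalg.cond(vals.loc[genes].to_numpy(float)))
        # ties favor the larger marker set
        if best is None or kappa <= best[0] + 1e-12:
            best = (kappa, G, genes)
    if best is None:
        raise AtlasValidationError("no marker candidates for any cell type")
    kappa, G, genes = best
    if not np.isfinite(kappa) or kappa > 1e8:
        warnings.warn(
            f"signature is near-collinear (condition number {kappa:.3g})",
            stacklevel=2,
        )
    per_type = {ct: min(G, len(ranked_candidates[ct])) for ct in types}
    return SignatureMatrix(
        values=vals.loc[genes].copy(),
        selected_genes=genes,
        per_type_gene_count=per_type,
        condition_number=kappa,
    )


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


def _finalize(
    coefs: np.ndarray, types: pd.Index, S: np.ndarray, m: np.ndarray
) -> tuple[pd.Series, float]:
    u = np.maximum(coefs, 0.0)
    if u.sum() <= 0:
        raise AtlasValidationError("unidentifiable mixture: all coefficients zero")
    resid = m - S @ coefs  # rmse on the z-scored scale, unclipped fit
    rmse = float(np.sqrt(np.mean(resid**2)))
    props = pd.Series(u / u.sum(), index=types)
    return props, rmse


def deconvolve(
    mixture: pd.Series,
    signature: SignatureMatrix,
    solver: Literal["nu_svr", "nnls"] = "nu_svr",
) -> ProportionEstimate:
    """Estimate mixture proportions against a signature matrix.

    Mixture and signature are z-scored internally, making the result
    invariant to a common positive rescaling of the mixture.  nu-SVR sweeps
    nu over {0.25, 0.5, 0.75} and keeps the fit with the smallest RMSE;
    negative coefficients are clipped to zero and the rest renormalized to
    sum one.  NNLS solves the same regression (with a free intercept) under
    nonnegativity.
    """
    missing = [g for g in signature.selected_genes if g not in mixture.index]
    if missing:
        raise AtlasValidationError(
            f"mixture lacks signature genes: {missing[:5]}"
        )
    genes = signature.selected_genes
    S = _zscore(signature.values.loc[genes].to_numpy(float))
    m = _zscore(mixture.loc[genes].to_numpy(float))
    types = signature.values.columns

    if solver == "nnls":
        # nonnegative weights plus a free intercept soaking the z-score offset
        A = np.hstack([S, np.ones((S.shape[0], 1))])
        res = optimize.lsq_linear(
            A, m, bounds=(
                np.r_[np.zeros(S.shape[1]), -np.inf],
                np.full(S.shape[1] + 1, np.inf),
            ),
        )
        props, rmse = _finalize(res.x[:-1], types, S, m)
        return ProportionEstimate(props, "nnls", rmse, mixture_id=mixture.name)

    if solver != "nu_svr":
        raise ValueError(f"unknown solver {solver!r}")
    best: tuple[float, float, np.ndarray] | None = None
    for nu in NU_GRID:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NuSVR(kernel="linear", nu=nu, C=1.0)
                model.fit(S, m)
            coefs = model.coef_.ravel()
            resid = m - (S @ coefs + model.intercept_)
            rmse = float(np.sqrt(np.mean(resid**2)))
        except Exception:  # noqa: BLE001 - SVR failure falls back to NNLS
            continue
        if best is None or rmse < best[0]:
            best = (rmse, nu, coefs)
    if best is None:
        est = deconvolve(mixture, signature, solver="nnls")
        est.proportions.name = mixture.name
        return est
    rmse, nu, coefs = best
    props, _ = _finalize(coefs, types, S, m)
    return ProportionEstimate(
        props, "nu_svr", rmse, nu_selected=nu, mixture_id=mixture.name
    )


def deconvolve_cohort(
    mixtures: NormalizedMatrix,
    signature: SignatureMatrix,
    mode: Literal["per_sample", "averaged"] = "per_sample",
    solver: Literal["nu_svr", "nnls"] = "nu_svr",
) -> list[ProportionEstimate]:
    """Deconvolve each mixture column, or their per-gene average."""
    if mixtures.values.shape[1] < 1:
        raise AtlasValidationError("need at least one mixture column")
    if mode == "averaged":
        avg = mixtures.values.mean(axis=1)
        avg.name = "averaged"
        return [deconvolve(avg, signature, solver=solver)]
    if mode != "per_sample":
        raise ValueError(f"unknown mode {mode!r}")
    return [
        deconvolve(mixtures.values[c], signature, solver=solver)
        for c in mixtures.values.columns
    ]
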
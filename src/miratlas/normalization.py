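"""Count normalization and batch-adjustment methods, plus control-gene selection.

Implements the compared transforms: log2(counts+1), a variance-stabilizing
transformation under a fitted NB dispersion trend alpha(mu) = a0 + a1/mu,
log-space empirical-Bayes batch adjustment (ComBat-style location/scale
model), removal of unwanted variation from control genes (RUVg-style) or from
design residuals (RUVr-style), and the exclusive-quartile rule that picks
ubiquitously expressed control genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .atlas_io import AtlasValidationError, CountMatrix, NormalizedMatrix

__all__ = [
    "SizeFactors",
    "DispersionTrend",
    "ControlGeneCriteria",
    "RUVFactors",
    "add_pseudocount",
    "log2_transform",
    "size_factors_median_of_ratios",
    "vst_normalize",
    "combat_adjust",
    "exclusive_quartile",
    "select_control_genes",
    "ruv_adjust",
]


@dataclass
class SizeFactors:
    """Per-run positive scaling factors, geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class DispersionTrend:
    """NB dispersion trend alpha(mu) = a0 + a1 / mu."""

    a0: float
    a1: float
    genewise_estimates: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError(f"degenerate dispersion trend: a0={self.a0!r} <= 0")
        if self.a1 < 0:
            raise ValueError(f"a1 must be >= 0, got {self.a1!r}")

    def __call__(self, mu: np.ndarray) -> np.ndarray:
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


@dataclass
class ControlGeneCriteria:
    """Quartile-bracket rule for ubiquitous control-gene candidacy.

    A candidate passes when its exclusive quartiles over samples satisfy
    QQ1 >= TQ1 - margin and QQ3 <= TQ3 + margin, where TQ1/TQ3 are the
    exclusive quartiles of the reference aggregate.  Boundaries inclusive.
    """

    reference_mirnas: Sequence[str]
    margin: float = 1500.0
    TQ1: float | None = None  # computed from the reference when absent
    TQ3: float | None = None

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.TQ1 is not None and self.TQ3 is not None and self.TQ1 > self.TQ3:
            raise ValueError("TQ1 must be <= TQ3")


@dataclass
class RUVFactors:
    """Estimated unwanted-variation factors."""

    k: int
    W: pd.DataFrame  # samples x k, orthonormal columns
    alpha: pd.DataFrame  # k x genes
    mode: Literal["controls", "residuals"]


# ---------------------------------------------------------------------------


def add_pseudocount(matrix: CountMatrix, value: int = 1) -> CountMatrix:
    """Increment every entry by ``value`` (default 1, to clear zeros)."""
    if value < 0:
        raise ValueError("pseudocount must be >= 0")
    return CountMatrix(
        matrix.values + value, matrix.provenance + [f"add_pseudocount[{value}]"]
    )


def log2_transform(matrix: CountMatrix) -> NormalizedMatrix:
    """Entrywise base-2 logarithm; requires every entry >= 1."""
    arr = matrix.values.to_numpy()
    if arr.size and arr.min() < 1:
        raise AtlasValidationError(
            "log2_transform requires entries >= 1; apply add_pseudocount first"
        )
    df = pd.DataFrame(
        np.log2(arr.astype(float)), index=matrix.values.index,
        columns=matrix.values.columns,
    )
    return NormalizedMatrix(df, "log2", matrix.provenance + ["log2_transform"])


def size_factors_median_of_ratios(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors against the geometric-mean reference.

    Reference rows are those with all-positive counts.  Factors are rescaled
    to geometric mean 1.
    """
    arr = counts.values.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise AtlasValidationError(
            "no row with all-positive counts; consider add_pseudocount"
        )
    ref = arr[positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geomean[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(pd.Series(factors, index=counts.values.columns))


# ---------------------------------------------------------------------------
# VST


def _fit_dispersion_trend(
    q: np.ndarray, inv_sf_mean: float, index: pd.Index
) -> DispersionTrend:
    """Method-of-moments gene-wise dispersions and an IRLS fit of
    alpha(mu) = a0 + a1/mu over genes with positive raw estimates."""
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (var - mu * inv_sf_mean) / mu**2
    ok = np.isfinite(disp_raw) & (mu > 0)
    genewise = pd.Series(np.where(ok, np.maximum(disp_raw, 1e-8), np.nan), index=index)

    fit_mask = ok & (disp_raw > 0)
    if fit_mask.sum() < 2:
        raise AtlasValidationError(
            "too few genes with positive dispersion estimates to fit a trend"
        )
    y = disp_raw[fit_mask]
    x = 1.0 / mu[fit_mask]
    X = np.column_stack([np.ones_like(x), x])
    w = np.ones_like(y)
    a0 = a1 = np.nan
    for _ in range(10):
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
        a0, a1 = float(beta[0]), float(max(beta[1], 0.0))
        fitted = np.maximum(a0 + a1 * x, 1e-10)
        w = 1.0 / fitted**2
    if a0 <= 0:
        raise AtlasValidationError(
            f"degenerate dispersion trend (a0={a0:.4g} <= 0); data look "
            "under-dispersed"
        )
    return DispersionTrend(a0=a0, a1=a1, genewise_estimates=genewise)


def vst_normalize(
    counts: CountMatrix | NormalizedMatrix,
    sf: SizeFactors | None = None,
    trend: DispersionTrend | None = None,
) -> tuple[NormalizedMatrix, DispersionTrend]:
    """Closed-form NB variance-stabilizing transform with a fitted trend.

    For scaled count q = count / size_factor and trend alpha(mu) = a0 + a1/mu,

        vst(q) = log2( (1 + a1 + 2*a0*q + 2*sqrt(a0*q*(1 + a1 + a0*q)))
                       / (4*a0) )

    which approaches log2(q) + const for large q and is strictly increasing.
    When ``trend`` is absent it is fitted from gene-wise method-of-moments
    dispersions on the size-factor-normalized counts.
    """
    vals = counts.values.to_numpy(float)
    if vals.size and vals.min() < 0:
        raise AtlasValidationError("vst_normalize requires nonnegative input")
    if sf is None:
        if isinstance(counts, CountMatrix):
            sf = size_factors_median_of_ratios(counts)
        else:
            sf = SizeFactors(
                pd.Series(1.0, index=counts.values.columns)
            )
    s = sf.factors.reindex(counts.values.columns).to_numpy(float)
    q = vals / s[None, :]
    if trend is None:
        trend = _fit_dispersion_trend(q, float(np.mean(1.0 / s)), counts.values.index)
    a0, a1 = trend.a0, trend.a1
    inner = 1.0 + a1 + 2.0 * a0 * q + 2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q))
    out = np.log2(inner / (4.0 * a0))
    df = pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns)
    prov = counts.provenance + [f"vst[a0={a0:.4g},a1={a1:.4g}]"]
    return NormalizedMatrix(df, "vst", prov), trend


# ---------------------------------------------------------------------------
# ComBat (log-space empirical Bayes location/scale adjustment)


def _design_matrix(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(labels))
    idx = {v: i for i, v in enumerate(levels)}
    X = np.zeros((len(labels), len(levels)))
    for i, v in enumerate(labels):
        X[i, idx[v]] = 1.0
    return X, levels


def combat_adjust(
    matrix: NormalizedMatrix,
    batch: Sequence[str],
    group: Sequence[str] | None = None,
) -> NormalizedMatrix:
    """Parametric empirical-Bayes batch adjustment on a log-scale matrix.

    Standardizes each gene preserving group effects, shrinks per-batch
    location/scale toward their priors, removes them and back-transforms.
    A single batch returns the input unchanged; a batch with one sample is an
    error; batch perfectly confounded with group degrades to batch-only
    adjustment with a provenance warning.
    """
    Y = matrix.values.to_numpy(float)  # genes x samples
    n_genes, n_samples = Y.shape
    batch = list(batch)
    if len(batch) != n_samples:
        raise ValueError("batch labels must match sample count")
    B, batch_levels = _design_matrix(batch)
    n_batches = len(batch_levels)
    prov_extra: list[str] = []
    if n_batches == 1:
        return NormalizedMatrix(
            matrix.values.copy(), "adjusted",
            matrix.provenance + ["combat[single-batch:identity]"],
        )
    sizes = B.sum(axis=0)
    if (sizes < 2).any():
        small = batch_levels[int(np.argmax(sizes < 2))]
        raise AtlasValidationError(f"batch {small!r} has fewer than 2 samples")

    X = B
    n_group_cols = 0
    if group is not None:
        G, group_levels = _design_matrix(list(group))
        G = G[:, 1:]  # drop first level: absorbed by batch intercepts
        Xfull = np.hstack([B, G])
        if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
            prov_extra.append("combat-warning[batch-confounded-with-group]")
        else:
            X = Xfull
            n_group_cols = G.shape[1]

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, genes)
    grand = (sizes / n_samples) @ beta[:n_batches]  # genes
    resid = Y.T - X @ beta
    var_pooled = (resid**2).mean(axis=0)  # genes
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = np.tile(grand, (n_samples, 1))
    if n_group_cols:
        stand_mean = stand_mean + X[:, n_batches:] @ beta[n_batches:]
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)  # samples x genes

    gamma_hat = np.stack([Z[B[:, b] == 1].mean(axis=0) for b in range(n_batches)])
    delta_hat = np.stack(
        [Z[B[:, b] == 1].var(axis=0, ddof=1) for b in range(n_batches)]
    )
    delta_hat = np.maximum(delta_hat, 1e-12)

    # parametric priors (method of moments)
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var
    a_prior = np.where(np.isfinite(a_prior), a_prior, 2.0 + 1e-3)
    b_prior = np.where(np.isfinite(b_prior), b_prior, d_mean)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batches):
        nb = sizes[b]
        Zb = Z[B[:, b] == 1]
        g = gamma_hat[b].copy()
        d = delta_hat[b].copy()
        for _ in range(100):
            g_new = (tau2[b] * nb * gamma_hat[b] + d * gamma_bar[b]) / (
                tau2[b] * nb + d
            )
            ssq = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * ssq + b_prior[b]) / (nb / 2.0 + a_prior[b] - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            if np.max(np.abs(g_new - g)) < 1e-8 and np.max(np.abs(d_new - d)) < 1e-8:
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[b] = g
        delta_star[b] = d

    Zadj = Z.copy()
    for b in range(n_batches):
        mask = B[:, b] == 1
        Zadj[mask] = (Z[mask] - gamma_star[b][None, :]) / np.sqrt(
            delta_star[b][None, :]
        )
    out = (Zadj * np.sqrt(var_pooled) + stand_mean).T  # genes x samples
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return NormalizedMatrix(
        df, "adjusted", matrix.provenance + ["combat"] + prov_extra
    )


# ---------------------------------------------------------------------------
# quartiles & control genes


def exclusive_quartile(values: Sequence[float], which: Literal["Q1", "Q3"]) -> float:
    """Exclusive-convention quartile: interpolation position p*(n+1).

    Requires n >= 3 so that the position falls inside the data.
    """
    if which not in ("Q1", "Q3"):
        raise ValueError(f"which must be 'Q1' or 'Q3', got {which!r}")
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError(f"exclusive quartile needs n >= 3, got n={n}")
    p = 0.25 if which == "Q1" else 0.75
    pos = p * (n + 1)  # 1-based
    if pos < 1 or pos > n:  # pragma: no cover - excluded by n >= 3
        raise ValueError("quartile position outside the data")
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo == n:  # pos is exactly the largest order statistic
        return float(x[-1])
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def select_control_genes(
    rpm: NormalizedMatrix, criteria: ControlGeneCriteria
) -> list[str]:
    """Pick ubiquitous control genes by the exclusive-quartile bracket rule.

    The reference aggregate is the elementwise sum of the reference rows.
    Returns ids (reference ids always included), in matrix row order.
    """
    missing = [r for r in criteria.reference_mirnas if r not in rpm.values.index]
    if missing:
        raise AtlasValidationError(f"reference miRNAs absent from matrix: {missing}")
    ref = rpm.values.loc[list(criteria.reference_mirnas)].sum(axis=0)
    tq1 = criteria.TQ1 if criteria.TQ1 is not None else exclusive_quartile(ref, "Q1")
    tq3 = criteria.TQ3 if criteria.TQ3 is not None else exclusive_quartile(ref, "Q3")
    lo, hi = tq1 - criteria.margin, tq3 + criteria.margin

    arr = np.sort(rpm.values.to_numpy(float), axis=1)
    n = arr.shape[1]
    if n < 3:
        raise AtlasValidationError("need >= 3 samples for exclusive quartiles")

    def _q(p: float) -> np.ndarray:
        pos = p * (n + 1)
        k = int(np.floor(pos))
        frac = pos - k
        if k >= n:  # pos lands exactly on the largest order statistic
            return arr[:, n - 1]
        return arr[:, k - 1] + frac * (arr[:, k] - arr[:, k - 1])

    qq1, qq3 = _q(0.25), _q(0.75)
    keep = (qq1 >= lo) & (qq3 <= hi)
    selected = set(rpm.values.index[keep]) | set(criteria.reference_mirnas)
    return [g for g in rpm.values.index if g in selected]


# ---------------------------------------------------------------------------
# RUV


def ruv_adjust(
    logmatrix: NormalizedMatrix,
    k: int,
    mode: Literal["controls", "residuals"],
    controls: Sequence[str] | None = None,
    design: Sequence[str] | None = None,
) -> tuple[NormalizedMatrix, RUVFactors]:
    """Remove k factors of unwanted variation from a log-scale matrix.

    mode="controls": factors are the top-k left singular vectors of the
    column-centered control-gene submatrix (samples x controls).
    mode="residuals": factors come from the residuals of a per-gene least
    squares on the one-hot ``design`` labels.  In both modes every gene is
    regressed on W and the fitted unwanted component subtracted.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    Y = logmatrix.values.to_numpy(float).T  # samples x genes
    n_samples, n_genes = Y.shape
    samples = logmatrix.values.columns
    genes = logmatrix.values.index
    if k == 0:
        W = pd.DataFrame(np.zeros((n_samples, 0)), index=samples)
        alpha = pd.DataFrame(np.zeros((0, n_genes)), columns=genes)
        return (
            NormalizedMatrix(
                logmatrix.values.copy(), "adjusted",
                logmatrix.provenance + [f"ruv_{mode}[k=0:identity]"],
            ),
            RUVFactors(0, W, alpha, mode),
        )
    if k > min(n_samples, n_genes):
        raise ValueError(f"k={k} exceeds min(samples, genes)")

    if mode == "controls":
        if controls is None or len(controls) < k:
            raise ValueError(f"mode='controls' requires >= k={k} control genes")
        missing = [c for c in controls if c not in genes]
        if missing:
            raise AtlasValidationError(f"control genes absent: {missing[:5]}")
        C = logmatrix.values.loc[list(controls)].to_numpy(float).T  # samples x ctrl
        M = C - C.mean(axis=0, keepdims=True)
    elif mode == "residuals":
        if design is None or len(design) != n_samples:
            raise ValueError("mode='residuals' requires a design label per sample")
        X, _ = _design_matrix(list(design))
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        M = Y - X @ beta
    else:
        raise ValueError(f"unknown mode {mode!r}")

    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the factor matrix")
    Wm = U[:, :k]  # orthonormal
    Yc = Y - Y.mean(axis=0, keepdims=True)
    alpha_m = Wm.T @ Yc  # k x genes (least squares, W orthonormal)
    out = (Y - Wm @ alpha_m).T
    df = pd.DataFrame(out, index=genes, columns=samples)
    factors = RUVFactors(
        k,
        pd.DataFrame(Wm, index=samples, columns=[f"W{i+1}" for i in range(k)]),
        pd.DataFrame(alpha_m, index=[f"W{i+1}" for i in range(k)], columns=genes),
        mode,
    )
    nm = NormalizedMatrix(
        df, "adjusted", logmatrix.provenance + [f"ruv_{mode}[k={k}]"]
    )
    return nm, factors
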
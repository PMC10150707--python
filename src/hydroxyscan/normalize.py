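"""Count normalization: within-group quantile normalization, low-count
filtering, log2-CPM, and a voom-style mean-variance trend with precision
weights.

Quantile normalization is performed independently within each cell-type
group so that the between-group contrast of interest (including any global
shift in 5hmC abundance) is not normalized away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .quant import SiteCountMatrix


@dataclass
class FilterParams:
    min_count: float = 10.0
    min_samples: int = 3


def quantile_normalize(counts, groups: pd.Series | dict) -> pd.DataFrame:
    """Mean-of-order-statistics quantile normalization within each group.

    Within a group, each column's sorted values are replaced by the mean of
    the order statistics across that group's columns; tied values in a
    column receive the mean of their tied target values.  A group with a
    single sample is returned unchanged with a warning.
    """
    df = counts.counts if isinstance(counts, SiteCountMatrix) else counts
    groups = pd.Series(groups)
    out = df.astype(float).copy()
    for group, cols in groups.groupby(groups).groups.items():
        cols = [c for c in df.columns if c in set(cols)]
        if len(cols) == 1:
            warnings.warn(f"group {group!r} has a single sample; left unchanged")
            continue
        mat = df[cols].to_numpy(dtype=float)
        ref = np.sort(mat, axis=0).mean(axis=1)  # mean of order statistics
        res = np.empty_like(mat)
        for j in range(mat.shape[1]):
            x = mat[:, j]
            order = np.argsort(x, kind="stable")
            target = np.empty_like(ref)
            target[order] = ref
            # ties share the mean of their assigned target quantiles
            uniq, inv = np.unique(x, return_inverse=True)
            sums = np.bincount(inv, weights=target)
            cnts = np.bincount(inv)
            res[:, j] = (sums / cnts)[inv]
        out[cols] = res
    return out


def filter_low_counts(
    normalized: pd.DataFrame, groups: pd.Series | dict, params: FilterParams | None = None
) -> pd.Index:
    """Retain sites with >= min_count in >= min_samples samples of any group."""
    params = params or FilterParams()
    groups = pd.Series(groups)
    keep = np.zeros(len(normalized), dtype=bool)
    for _, cols in groups.groupby(groups).groups.items():
        cols = [c for c in normalized.columns if c in set(cols)]
        enough = (normalized[cols] >= params.min_count).sum(axis=1) >= params.min_samples
        keep |= enough.to_numpy()
    return normalized.index[keep]


def log_cpm(
    counts,
    library_sizes: pd.Series | None = None,
    prior_count: float = 0.5,
    libsize_adjust: float = 1.0,
) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + prior) / (libsize + adjust) * 1e6).

    ``library_sizes`` defaults to the matrix's recorded library sizes (column
    totals of the unfiltered counts), so that site filtering does not change
    the CPM scale.
    """
    if isinstance(counts, SiteCountMatrix):
        df, libs = counts.counts, counts.library_sizes
    else:
        df, libs = counts, library_sizes
    if libs is None:
        libs = df.sum(axis=0)
    libs = pd.Series(libs).reindex(df.columns).astype(float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"non-positive library sizes for samples: {bad}")
    denom = (libs + libsize_adjust).to_numpy()
    vals = np.log2((df.to_numpy(dtype=float) + prior_count) / denom[None, :] * 1e6)
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


@dataclass
class MeanVarianceTrend:
    """Fitted voom-style trend: lowess of sqrt residual-sd vs mean log2-count."""

    x: np.ndarray  # mean log2-count (sorted)
    y: np.ndarray  # sqrt residual sd at x
    residual_sd: pd.Series
    weights: pd.DataFrame


def _check_design(design: np.ndarray, names: list[str] | None) -> None:
    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        # identify the first column linearly dependent on its predecessors
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                label = names[j] if names else f"column {j}"
                raise ValueError(f"design matrix is collinear at {label}")
        raise ValueError("design matrix is collinear")


def fit_mean_variance_trend(
    logcpm: pd.DataFrame,
    design: np.ndarray | pd.DataFrame,
    library_sizes: pd.Series | None = None,
    span: float = 0.5,
) -> MeanVarianceTrend:
    """Per-observation precision weights from the empirical mean-variance trend.

    Per-site least-squares fits under ``design`` give residual standard
    deviations; a lowess curve of sqrt(sd) against mean log2-count is
    interpolated at each observation's fitted log2-count and the weight is
    the inverse fourth power of the interpolated value.
    """
    names = list(design.columns) if isinstance(design, pd.DataFrame) else None
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n != logcpm.shape[1]:
        raise ValueError("design rows must align with samples")
    if n - p < 1:
        raise ValueError("residual degrees of freedom < 1 under this design")
    _check_design(X, names)

    Y = logcpm.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    s = np.sqrt((resid**2).sum(axis=1) / (n - p))

    if library_sizes is None:
        lib_offset = np.log2(1e6)  # fall back to the CPM scale itself
        obs_logcount = fitted
        mean_logcount = Y.mean(axis=1)
    else:
        libs = pd.Series(library_sizes).reindex(logcpm.columns).astype(float).to_numpy()
        shift = np.log2(libs + 1.0) - np.log2(1e6)
        obs_logcount = fitted + shift[None, :]
        mean_logcount = Y.mean(axis=1) + shift.mean()

    sx = mean_logcount
    sy = np.sqrt(s)
    ok = s > 0
    if ok.sum() < 2:
        raise ValueError("too few sites with positive residual variance to fit a trend")
    fit = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    interp = np.interp(obs_logcount, fx, fy)
    interp = np.clip(interp, 1e-6, None)
    w = interp**-4.0
    return MeanVarianceTrend(
        x=fx,
        y=fy,
        residual_sd=pd.Series(s, index=logcpm.index, name="residual_sd"),
        weights=pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns),
    )


def design_matrix(
    sheet: pd.DataFrame, samples: list[str], covariates: list[str] = ("cell_type",)
) -> pd.DataFrame:
    """Intercept + dummy-coded covariates from the sample sheet, row per sample."""
    sub = sheet.set_index("sample").loc[list(samples)]
    cols = {"intercept": np.ones(len(sub))}
    for cov in covariates:
        vals = sub[cov]
        if vals.dtype.kind in "if":
            cols[cov] = vals.to_numpy(dtype=float)
        else:
            levels = sorted(vals.unique())
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (vals == lv).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=sub.index)
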
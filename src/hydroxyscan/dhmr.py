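"""Differentially hydroxymethylated region (DhMR) detection.

Windows of k sequential 5hmC sites (default nine) slide one site at a time
along each chromosome; each window combines the member sites' one-sided
t-test p-values with Fisher's method, X2 = -2 * sum(ln p), chi-square on 2k
degrees of freedom.  Windows wider than the span bound (default 50 kb,
exclusive) are skipped.  Genome-wide significance uses a Bonferroni
denominator of ceil(n_sites / k) non-overlapping bins, and overlapping
discovery windows can be collapsed to disjoint loci keeping the smallest
combined p per chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS = ("lower", "higher", "best")


@dataclass
class DhmrParams:
    k: int = 9
    max_span: int = 50_000  # exclusive bound on last-first+1 (bp)
    direction: str = "lower"
    p_floor: float = 1e-300

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


def one_sided_p(t, df, direction: str, degenerate=None) -> np.ndarray:
    """One-sided t-tail probability per site.

    ``lower`` is evidence that the contrast effect is negative (P[T <= t]);
    ``higher`` the upper tail.  Degenerate (zero-variance) sites get p = 0.5.
    """
    t = np.asarray(t, dtype=float)
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr < 1):
        raise ValueError("degrees of freedom must be >= 1")
    if direction == "lower":
        p = stats.t.cdf(t, df_arr)
    elif direction == "higher":
        p = stats.t.sf(t, df_arr)
    else:
        raise ValueError("direction must be 'lower' or 'higher'")
    if degenerate is not None:
        p = np.where(np.asarray(degenerate, dtype=bool), 0.5, p)
    return p


def fisher_combine(p: np.ndarray, p_floor: float = 1e-300) -> tuple[float, float]:
    """Fisher's combined probability of one p-vector: (X2, combined p)."""
    p = np.clip(np.asarray(p, dtype=float), p_floor, 1.0)
    x2 = -2.0 * np.log(p).sum()
    return float(x2), float(stats.chi2.sf(x2, 2 * len(p)))


def fisher_windows(
    sites: pd.DataFrame,
    p_lower: np.ndarray | None = None,
    p_higher: np.ndarray | None = None,
    params: DhmrParams | None = None,
) -> pd.DataFrame:
    """Slide k-site windows per chromosome and combine one-sided p-values.

    ``sites`` must carry ``chrom`` and ``pos`` columns sorted by
    (chromosome, position); p-vectors align with its rows.  Direction
    ``best`` evaluates both tracks and keeps the smaller combined p with its
    label.  Returns one row per admissible window plus a ``skipped_wide``
    count in ``DataFrame.attrs``.
    """
    params = params or DhmrParams()
    need = {"lower": ("p_lower",), "higher": ("p_higher",), "best": ("p_lower", "p_higher")}
    tracks = {}
    for name in need[params.direction]:
        vec = {"p_lower": p_lower, "p_higher": p_higher}[name]
        if vec is None:
            raise ValueError(f"direction {params.direction!r} requires {name}")
        vec = np.asarray(vec, dtype=float)
        if len(vec) != len(sites):
            raise ValueError("p-vector length does not match the site table")
        tracks[name.replace("p_", "")] = np.clip(vec, params.p_floor, 1.0)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    keys = (
        sites.index.to_numpy()
        if sites.index.dtype == object
        else (sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)).to_numpy()
    )
    k = params.k
    rows = []
    skipped = 0
    for chrom in dict.fromkeys(chrom_arr):  # preserve input chromosome order
        mask = chrom_arr == chrom
        pos = pos_arr[mask]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom!r} are not sorted by position")
        idx = np.flatnonzero(mask)
        n = len(pos)
        if n < k:
            continue
        spans = pos[k - 1 :] - pos[: n - k + 1] + 1
        per_track = {}
        for label, pvec in tracks.items():
            cum = np.concatenate([[0.0], np.cumsum(-2.0 * np.log(pvec[mask]))])
            per_track[label] = cum[k:] - cum[:-k]
        for w in range(n - k + 1):
            if spans[w] >= params.max_span:
                skipped += 1
                continue
            # pick the better-supported direction when both tracks are scanned
            best_label, best_x2 = max(
                ((lab, x2s[w]) for lab, x2s in per_track.items()), key=lambda t: t[1]
            )
            combined_p = float(stats.chi2.sf(best_x2, 2 * k))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[w]),
                    "end": int(pos[w + k - 1]),
                    "span_bp": int(spans[w]),
                    "start_index": int(idx[w]),
                    "x2": float(best_x2),
                    "df": 2 * k,
                    "combined_p": combined_p,
                    "direction": best_label,
                    "member_sites": ",".join(map(str, keys[idx[w] : idx[w] + k])),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "span_bp", "start_index",
            "x2", "df", "combined_p", "direction", "member_sites",
        ],
    )
    out.attrs["skipped_wide"] = skipped
    out.attrs["k"] = k
    return out


def bonferroni_bins(n_sites: int, k: int = 9, alpha: float = 0.05) -> tuple[int, float]:
    """Non-overlapping bin count ceil(n/k) and the Bonferroni threshold."""
    if n_sites < k:
        raise ValueError("n_sites must be at least k")
    bins = math.ceil(n_sites / k)
    return bins, alpha / bins


def collapse_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Collapse chains of member-sharing windows to disjoint loci.

    Windows sharing at least one member site (same chromosome, overlapping
    k-site index ranges) form a chain; the chain's representative is the
    window with the smallest combined p (ties -> leftmost).  Output is
    sorted by combined p.
    """
    if windows.empty:
        return windows.copy()
    k = windows.attrs.get("k", windows["df"].iloc[0] // 2)
    df = windows.sort_values(["chrom", "start_index"], kind="stable").reset_index(drop=True)
    reps = []
    cur: list[int] = []
    cur_chrom = None
    cur_max_end = -1
    for row in df.itertuples():
        s = row.start_index
        if cur and row.chrom == cur_chrom and s <= cur_max_end:
            cur.append(row.Index)
            cur_max_end = max(cur_max_end, s + k - 1)
        else:
            if cur:
                reps.append(cur)
            cur = [row.Index]
            cur_chrom = row.chrom
            cur_max_end = s + k - 1
    if cur:
        reps.append(cur)
    keep = []
    for chain in reps:
        sub = df.loc[chain]
        best = sub.sort_values(["combined_p", "start"], kind="stable").index[0]
        keep.append(best)
    out = df.loc[keep].sort_values(["combined_p", "chrom", "start"], kind="stable")
    out.attrs.update(windows.attrs)
    return out.reset_index(drop=True)


def dhmr_scan(
    diff_result: pd.DataFrame,
    sites: pd.DataFrame,
    params: DhmrParams | None = None,
    collapse: bool = True,
) -> pd.DataFrame:
    """One-call DhMR scan from a per-site differential table.

    ``diff_result`` needs columns t, df, degenerate; ``sites`` the aligned
    chrom/pos table.
    """
    params = params or DhmrParams()
    t = diff_result["t"].to_numpy()
    df_arr = diff_result["df"].to_numpy()
    degen = diff_result["degenerate"].to_numpy() if "degenerate" in diff_result else None
    p_lo = one_sided_p(t, df_arr, "lower", degen) if params.direction in ("lower", "best") else None
    p_hi = one_sided_p(t, df_arr, "higher", degen) if params.direction in ("higher", "best") else None
    windows = fisher_windows(sites, p_lo, p_hi, params)
    return collapse_windows(windows) if collapse else windows
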
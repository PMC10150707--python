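"""Per-site differential hydroxymethylation statistics.

Provides the classical paired t-test on log2-CPM values (the primary,
conservative statistic), log2 fold changes with an explicit contrast
orientation, empirical-Bayes moderated t-statistics that shrink per-site
variances toward a common prior and add prior degrees of freedom,
Benjamini-Hochberg FDR, the volcano classification rule
(|log2 FC| > 1 and p < 0.05), and direction summaries.

Sites whose paired differences have zero variance are flagged degenerate and
carry p = 1 (t = 0) rather than NaN, so window statistics downstream stay
well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EBPrior:
    """Scaled inverse-chi-square prior on per-site variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float


def paired_t(values: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Classical paired t-test per site on log2-CPM values.

    ``pairs`` lists (sample_A, sample_B); differences are B - A, so the
    reported log2_fc is the mean within-pair contrast of B relative to A.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    flat = [s for ab in pairs for s in ab]
    if len(set(flat)) != len(flat):
        raise ValueError("each sample may appear in exactly one pair")
    missing = [s for s in flat if s not in values.columns]
    if missing:
        raise ValueError(f"samples absent from the value matrix: {missing}")

    a = values[[p[0] for p in pairs]].to_numpy(dtype=float)
    b = values[[p[1] for p in pairs]].to_numpy(dtype=float)
    d = b - a
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    t = np.zeros(len(mean))
    np.divide(mean, sd / math.sqrt(n), out=t, where=~degenerate)
    df = n - 1
    p = np.ones(len(mean))
    p[~degenerate] = 2 * stats.t.sf(np.abs(t[~degenerate]), df)
    return pd.DataFrame(
        {
            "log2_fc": mean,
            "t": t,
            "df": float(df),
            "p_value": p,
            "degenerate": degenerate,
        },
        index=values.index,
    )


def unpaired_t(
    values: pd.DataFrame, group_b: list[str], group_a: list[str], pooled: bool = False
) -> pd.DataFrame:
    """Two-sample alternative for designs whose pairing is unknown (B vs A)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    res = stats.ttest_ind(b, a, axis=1, equal_var=pooled)
    fc = b.mean(axis=1) - a.mean(axis=1)
    degenerate = ~np.isfinite(res.statistic)
    t = np.where(degenerate, 0.0, res.statistic)
    p = np.where(degenerate, 1.0, res.pvalue)
    df = getattr(res, "df", np.full(len(fc), a.shape[1] + b.shape[1] - 2))
    return pd.DataFrame(
        {"log2_fc": fc, "t": t, "df": df, "p_value": p, "degenerate": degenerate},
        index=values.index,
    )


def log2_fold_change(
    values: pd.DataFrame, group_b: list[str], group_a: list[str]
) -> pd.Series:
    """mean(log2-CPM in B) - mean(log2-CPM in A); orientation B vs A."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    fc = values[group_b].mean(axis=1) - values[group_a].mean(axis=1)
    fc.name = "log2_fc"
    fc.attrs["contrast"] = f"{'+'.join(group_b)} vs {'+'.join(group_a)}"
    return fc


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def fit_eb_prior(s_sq: np.ndarray, df: float) -> EBPrior:
    """Moment-match a scaled-F model for per-site sample variances.

    Works on log variances: for s^2 ~ s0^2 * F(df, d0), e = log(s^2)
    - digamma(df/2) + log(df/2) has mean log(s0^2) + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(df/2).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if len(s_sq) < 2:
        raise ValueError("need at least two sites to estimate the prior")
    if len(pos) == 0:
        raise ValueError("all variances are zero; prior is unidentifiable")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if len(e) > 1 else 0.0
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # observed spread at or below pure chi-square sampling noise: the
        # variances are treated as exchangeable draws from a point prior at
        # their geometric mean (so identical inputs shrink to themselves)
        d0 = math.inf
        s0_sq = math.exp(z.mean())
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    s_sq: np.ndarray,
    df: float,
    effects: np.ndarray,
    stderr_scale: float,
    prior: EBPrior | None = None,
) -> tuple[pd.DataFrame, EBPrior]:
    """Empirical-Bayes moderated t-statistics.

    Posterior variance s_post^2 = (d0*s0^2 + df*s^2) / (d0 + df); the
    moderated t is effect / (s_post * stderr_scale) on df + d0 degrees of
    freedom (normal in the d0 -> inf limit).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    effects = np.asarray(effects, dtype=float)
    prior = prior or fit_eb_prior(s_sq, df)
    if math.isinf(prior.d0):
        s_post = np.full_like(s_sq, prior.s0_sq)
        df_total = math.inf
    else:
        s_post = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = df + prior.d0
    t = effects / (np.sqrt(s_post) * stderr_scale)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({"t_mod": t, "df_total": df_total, "p_mod": p})
    return out, prior


def moderated_paired_t(values: pd.DataFrame, pairs: list[tuple[str, str]]) -> tuple[pd.DataFrame, EBPrior]:
    """Moderated variant of :func:`paired_t` (same contrast orientation)."""
    base = paired_t(values, pairs)
    n = len(pairs)
    a = values[[p[0] for p in pairs]].to_numpy(dtype=float)
    b = values[[p[1] for p in pairs]].to_numpy(dtype=float)
    d = b - a
    s_sq = d.var(axis=1, ddof=1)
    mod, prior = moderated_t(s_sq, n - 1, base["log2_fc"].to_numpy(), 1.0 / math.sqrt(n))
    mod.index = values.index
    out = base.join(mod)
    return out, prior


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_volcano(
    log2_fc, p, fc_thresh: float = 1.0, p_thresh: float = 0.05
) -> pd.Series:
    """down / up / ns by the strict volcano rule (|FC| > fc_thresh, p < p_thresh)."""
    fc = np.asarray(log2_fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    out = np.full(fc.shape, "ns", dtype=object)
    out[(fc < -fc_thresh) & (pv < p_thresh)] = "down"
    out[(fc > fc_thresh) & (pv < p_thresh)] = "up"
    idx = log2_fc.index if isinstance(log2_fc, pd.Series) else None
    return pd.Series(out, index=idx, name="volcano_class")


def diff_table(
    values: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    contrast_label: str = "B vs A",
) -> pd.DataFrame:
    """Full per-site differential table: paired t + FDR + volcano class."""
    res = paired_t(values, pairs)
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    res["volcano_class"] = classify_volcano(
        res["log2_fc"], res["p_value"], fc_thresh, p_thresh
    )
    res.attrs["contrast"] = contrast_label
    return res


def summarize_direction(result: pd.DataFrame, p_thresh: float = 0.05) -> dict:
    """Fractions of negative fold changes overall and among nominal hits."""
    if len(result) == 0:
        raise ValueError("empty result set")
    fc = result["log2_fc"].to_numpy()
    p = result["p_value"].to_numpy()
    sig = p < p_thresh
    out = {
        "n_sites": int(len(result)),
        "frac_negative": float((fc < 0).mean()),
        "n_significant": int(sig.sum()),
        "frac_negative_significant": float((fc[sig] < 0).mean()) if sig.any() else float("nan"),
    }
    if "volcano_class" in result:
        counts = result["volcano_class"].value_counts()
        for cls in ("down", "up", "ns"):
            out[f"n_{cls}"] = int(counts.get(cls, 0))
    return out
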
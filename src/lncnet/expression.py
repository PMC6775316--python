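"""Count normalization and differential expression.

Normalization is median-of-ratios size factors followed by a shifted
log2 transform (``log2(count / sf + 1)``); this is a documented
stand-in for a regularized-log transform — the network stage needs
variance-stabilized values, not bit-compatibility with any particular
DE package.  Testing is a negative-binomial Wald test with per-transcript
method-of-moments dispersion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    sf_j = median over transcripts g (with positive geometric mean) of
    counts_gj / geomean_g.  Requires at least one transcript with
    positive counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.isfinite(logs).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "median-of-ratios normalization needs at least one — "
            "filter samples or supply size factors explicitly"
        )
    log_geomean = logs[all_positive].mean(axis=1)
    ratios = np.exp(logs[all_positive] - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """x_gj = log2(counts_gj / sf_j + 1)."""
    if list(counts.columns) != list(sf.index):
        raise ValueError("size-factor index must match count matrix columns")
    if (sf.to_numpy() <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(sf, axis=1) + 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def nb_wald_test(
    counts: pd.DataFrame, sample_table: pd.DataFrame, group: str | None = None
) -> pd.DataFrame:
    """Per-transcript NB Wald test of treated (trait 1) vs control (trait 0).

    Dispersion is method-of-moments on size-factor-normalized counts,
    alpha = max(0, (s^2 - xbar) / xbar^2), floored at 1e-8 and estimated
    within condition (pooled by degrees of freedom).  The Wald statistic
    is the log2 fold change of group means (pseudo-count 0.5) over its
    delta-method standard error; two-sided p from a t reference with
    n1 + n2 - 2 degrees of freedom.  All-zero transcripts get p = 1,
    log2fc = 0 by contract.

    Returns a DataFrame indexed like *counts* with columns baseMean,
    log2fc, pvalue, fdr.
    """
    st = sample_table
    if group is not None:
        st = st[st["group"] == group]
    st = st.set_index("sample_id")
    missing = [s for s in st.index if s not in counts.columns]
    if missing:
        raise ValueError(f"samples absent from counts: {missing[:5]}")
    cols = [c for c in counts.columns if c in st.index]
    st = st.loc[cols]
    sub = counts[cols]
    trait = st["trait"].to_numpy()
    n_trt, n_ctl = int((trait == 1).sum()), int((trait == 0).sum())
    if n_trt < 2 or n_ctl < 2:
        raise ValueError("need >= 2 samples per condition")

    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    x_t, x_c = norm[:, trait == 1], norm[:, trait == 0]
    m_t, m_c = x_t.mean(axis=1), x_c.mean(axis=1)

    # pooled within-condition method-of-moments dispersion
    xbar = norm.mean(axis=1)
    pooled_var = (
        x_t.var(axis=1, ddof=1) * (n_trt - 1) + x_c.var(axis=1, ddof=1) * (n_ctl - 1)
    ) / (n_trt + n_ctl - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(xbar > 0, (pooled_var - xbar) / xbar**2, 0.0)
    alpha = np.clip(alpha, DISPERSION_FLOOR, None)

    mt, mc = m_t + PSEUDOCOUNT, m_c + PSEUDOCOUNT
    log2fc = np.log2(mt / mc)
    var_t = (mt + alpha * mt**2) / n_trt
    var_c = (mc + alpha * mc**2) / n_ctl
    se = np.sqrt(var_t / mt**2 + var_c / mc**2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    df = n_trt + n_ctl - 2
    pvalue = 2.0 * stats.t.sf(np.abs(z), df)
    pvalue = np.clip(pvalue, 0.0, 1.0)

    all_zero = (sub.to_numpy() == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    pvalue[all_zero] = 1.0

    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
        },
        index=sub.index,
    )


def call_significant(
    de: pd.DataFrame, p_cut: float = 0.05, fc_cut: float = 2.0, use_fdr: bool = False
) -> pd.DataFrame:
    """Flag transcripts with p < p_cut (strict) and |log2fc| > log2(fc_cut).

    Adds boolean ``significant`` and a ``direction`` column
    ("up"/"down"/"ns").  ``use_fdr`` switches the p column to BH FDR.
    """
    p = de["fdr"] if use_fdr else de["pvalue"]
    lfc_cut = np.log2(fc_cut)
    sig = (p < p_cut) & (de["log2fc"].abs() > lfc_cut)
    out = de.copy()
    out["significant"] = sig
    out["direction"] = np.where(
        sig, np.where(de["log2fc"] > 0, "up", "down"), "ns"
    )
    return out


def common_direction(calls: dict[str, pd.DataFrame], direction: str) -> set[str]:
    """Transcripts significant in the given direction in every group."""
    sets = [
        set(df.index[(df["significant"]) & (df["direction"] == direction)])
        for df in calls.values()
    ]
    return set.intersection(*sets) if sets else set()
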
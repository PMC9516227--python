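"""Empirical-Bayes moderated two-group differential expression.

Per protein a pooled-variance two-sample linear model is fit on log2
ratios; residual variances are shrunk toward a common prior estimated by
moment matching on the log variances (the scaled-F hierarchical model of
the limma framework, re-implemented here): if s_g^2 ~ s0^2 * F(d_g, d0),
then log s_g^2 has closed-form mean and variance in terms of digamma /
trigamma functions, which yields (d0, s0^2) from the observed spread of
log variances. The moderated statistic

    t~_g = (mean_case - mean_control) / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution on d0 + d_g degrees of freedom. Calls use
Benjamini-Hochberg adjusted p < alpha with at least an fc_min fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantTable


def trigamma_inverse(y: float | np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing, so the iteration on 1/trigamma converges from the
    asymptotic start x0 = 0.5 + 1/y. Very small y maps to ~1/y, very large
    y to ~1/sqrt(y).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y <= 0):
        raise ValueError("trigamma_inverse requires positive input")
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    small = y < 1e-6
    x = np.where(small, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(-dif / x) < 1e-10:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior by
    moment matching on log variances; returns d0 = inf when the observed
    spread is no wider than sampling alone explains."""
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    half = df / 2.0
    e = np.log(s2) - special.digamma(half) + np.log(half)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(np.mean(special.polygamma(1, half)))
    if excess <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = float(2.0 * trigamma_inverse(excess)[0])
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


def _t_pvalue(t: np.ndarray, df: float | np.ndarray) -> np.ndarray:
    if np.isscalar(df) and np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def moderated_t(
    table: ProteinQuantTable, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated t-statistics per protein (case minus control).

    Proteins with fewer than 2 observed values in either group are dropped.
    prior_df overrides the estimated d0 (0 recovers the ordinary pooled
    t-test; inf fixes every posterior variance at s0^2). Returns a frame
    with columns logFC, s2, df, s2_post, df_total, t, p indexed by
    protein_id.
    """
    case = table.values[table.samples_in("case")].to_numpy()
    ctrl = table.values[table.samples_in("control")].to_numpy()
    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    index = table.values.index[ok]
    case, ctrl, n1, n2 = case[ok], ctrl[ok], n1[ok], n2[ok]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(case, axis=1)
        m2 = np.nanmean(ctrl, axis=1)
        v1 = np.nanvar(case, axis=1, ddof=1)
        v2 = np.nanvar(ctrl, axis=1, ddof=1)
    logfc = m1 - m2
    df = (n1 + n2 - 2).astype(float)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    if prior_df is None:
        try:
            d0, s0_sq = fit_variance_prior(s2, df)
        except ValueError:
            warnings.warn(
                "too few proteins to estimate the variance prior; "
                "falling back to the ordinary t-test",
                stacklevel=2,
            )
            d0, s0_sq = 0.0, float("nan")
    else:
        d0 = float(prior_df)
        if d0 < 0:
            raise ValueError("prior_df must be nonnegative")
        if d0 == 0:
            s0_sq = float("nan")
        else:
            # s0^2 consistent with the forced d0 under the same moment match
            ok2 = np.isfinite(s2) & (s2 > 0)
            half = df[ok2] / 2.0
            e_mean = float(
                np.mean(np.log(s2[ok2]) - special.digamma(half) + np.log(half))
            )
            if np.isinf(d0):
                s0_sq = float(np.exp(e_mean))
            else:
                s0_sq = float(
                    np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
                )

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total: float | np.ndarray = float("inf")
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    t = np.where(se == 0, np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf), t)
    p = np.where(np.isinf(t), 0.0, _t_pvalue(np.where(np.isinf(t), 0.0, t), df_total))
    p = np.where((se == 0) & (logfc == 0), 1.0, p)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "df": df,
            "s2_post": s2_post,
            "df_total": df_total,
            "t": t,
            "p": p,
        },
        index=index,
    )
    out.index.name = "protein_id"
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and up/down/ns calls.

    A protein is 'up' when adj_p < alpha and logFC >= log2(fc_min), 'down'
    when adj_p < alpha and logFC <= -log2(fc_min), otherwise 'ns'. The
    returned frame is volcano-ready (logFC vs -log10 p).
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    out = results.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    lfc_min = np.log2(fc_min)
    call = np.where(
        (out["adj_p"] < alpha) & (out["logFC"] >= lfc_min),
        "up",
        np.where(
            (out["adj_p"] < alpha) & (out["logFC"] <= -lfc_min), "down", "ns"
        ),
    )
    out["call"] = call
    return out


def de_analysis(
    table: ProteinQuantTable,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t followed by BH adjustment and calling."""
    return call_de(moderated_t(table, prior_df=prior_df), alpha=alpha, fc_min=fc_min)
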
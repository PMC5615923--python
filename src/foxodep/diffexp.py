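"""Moderated linear models for the four-genotype design.

Each protein is fit with a one-way layout over the genotype factor
(A wild type, B foxo-null, C ablated, D ablated foxo-null).  Per-protein
residual variances are shrunk toward a common prior by empirical Bayes: the
sample variances are modelled as scaled F-distributed around a prior variance
``s0^2`` with prior degrees of freedom ``d0``, both estimated by matching the
first two moments of ``log s^2`` (digamma/trigamma equations).  The posterior
variance

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces the raw variance in the t-statistics, which then carry ``d0 + d_g``
degrees of freedom.  Three contrasts matter downstream:

* ``CvsA``        — ablation response in the wild-type background,
* ``DvsB``        — ablation response in the foxo-null background,
* ``interaction`` — (C - A) - (D - B), whether the response needs foxo.

Multiplicity is handled by Benjamini-Hochberg, with significance at an
adjusted p of 0.1 by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import IntensityMatrix

__all__ = [
    "CONTRASTS",
    "GroupFit",
    "ModerationFit",
    "fit_group_means",
    "moderate_variances",
    "contrast_test",
    "adjust_bh",
    "run_contrasts",
]

#: The study's three contrasts as coefficient maps over genotype levels.
CONTRASTS: dict[str, dict[str, float]] = {
    "CvsA": {"C": 1.0, "A": -1.0},
    "DvsB": {"D": 1.0, "B": -1.0},
    "interaction": {"C": 1.0, "A": -1.0, "D": -1.0, "B": 1.0},
}


@dataclass
class GroupFit:
    """OLS group means of the one-way layout, with pooled residual variance."""

    means: pd.DataFrame  # proteins x groups
    n: pd.Series  # samples per group
    s2: pd.Series  # per-protein pooled residual variance
    df: float  # residual degrees of freedom (n_samples - n_groups)


@dataclass
class ModerationFit:
    prior_df: float  # d0; +inf when log-variances are under-dispersed
    prior_var: float  # s0^2
    posterior_var: pd.Series


def fit_group_means(matrix: IntensityMatrix) -> GroupFit:
    """Per-protein group means and pooled residual variance.

    Equivalent to ordinary least squares on the cell-means parametrization;
    invariant to row and column order.  Requires a complete matrix.
    """
    if not matrix.is_complete():
        raise ValueError("matrix contains missing values; impute first")
    genotype = matrix.samples["genotype"]
    groups = sorted(genotype.unique())
    n = pd.Series({g: int((genotype == g).sum()) for g in groups})
    if (n < 1).any():
        raise ValueError("every genotype group needs at least one sample")
    df = matrix.n_samples - len(groups)
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    means = pd.DataFrame(index=matrix.proteins, columns=groups, dtype=float)
    rss = np.zeros(matrix.n_proteins)
    for g in groups:
        cols = genotype.index[genotype == g]
        block = matrix.values[cols].to_numpy()
        mu = block.mean(axis=1)
        means[g] = mu
        rss += ((block - mu[:, None]) ** 2).sum(axis=1)
    s2 = pd.Series(rss / df, index=matrix.proteins)
    return GroupFit(means=means, n=n, s2=s2, df=float(df))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) / x < 1e-10:
            break
    return x


def moderate_variances(s2, df) -> ModerationFit:
    """Empirical-Bayes shrinkage of per-protein variances.

    Fits the scaled-F model for the sample variances by matching moments of
    ``log s^2``; returns the prior ``(d0, s0^2)`` and the per-protein
    posterior variances.  When the observed spread of log-variances is no
    larger than expected from sampling alone, ``d0`` is infinite and every
    posterior variance equals the common prior value.  Zero variances are
    excluded from moment estimation (they still receive a posterior).
    """
    index = s2.index if isinstance(s2, pd.Series) else pd.RangeIndex(len(s2))
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        raise ValueError("all variances are zero; cannot moderate")

    z = np.log(s2[ok])
    half_df = df[ok] / 2.0
    e = z - digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    n = e.size
    rhs = float(((e - e_mean) ** 2).sum() / max(n - 1, 1) - polygamma(1, half_df).mean())
    if n > 1 and rhs > 0:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
        posterior = (d0 * s02 + df * s2) / (d0 + df)
    else:
        # under-dispersed log-variances: no evidence of heterogeneity
        d0 = math.inf
        s02 = float(np.mean(s2))
        posterior = np.full_like(s2, s02)
    return ModerationFit(
        prior_df=d0,
        prior_var=s02,
        posterior_var=pd.Series(posterior, index=index),
    )


def contrast_test(
    fit: GroupFit,
    moderation: ModerationFit,
    contrast: str | dict[str, float],
    conf: float = 0.95,
) -> pd.DataFrame:
    """Moderated t-test of one contrast of group means.

    The estimate is the contrast applied to the group means; its standard
    error uses the posterior variance and the group sizes; the statistic is
    referred to a t distribution on ``d0 + d_g`` degrees of freedom (normal
    when ``d0`` is infinite).  The confidence interval uses the same df.
    Zero-SE proteins get p = 0 when the estimate is nonzero (else 1) and are
    flagged in the ``zero_se`` column.
    """
    if isinstance(contrast, str):
        contrast = CONTRASTS[contrast]
    missing = set(contrast) - set(fit.means.columns)
    if missing:
        raise ValueError(f"contrast uses unfitted groups: {sorted(missing)}")
    c = np.array([contrast.get(g, 0.0) for g in fit.means.columns])
    estimate = fit.means.to_numpy() @ c
    unscaled = float(np.sum(c**2 / fit.n.to_numpy()))
    se = np.sqrt(moderation.posterior_var.to_numpy() * unscaled)

    df_total = moderation.prior_df + fit.df
    if math.isinf(df_total):
        dist = stats.norm()
        tq = float(stats.norm.ppf(0.5 + conf / 2.0))
    else:
        dist = stats.t(df_total)
        tq = float(stats.t.ppf(0.5 + conf / 2.0, df_total))

    zero_se = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_se, np.where(estimate == 0, 0.0, np.sign(estimate) * np.inf), estimate / np.where(zero_se, 1.0, se))
        p = np.where(zero_se, np.where(estimate == 0, 1.0, 0.0), 2.0 * dist.sf(np.abs(t)))
    out = pd.DataFrame(
        {
            "estimate": estimate,
            "se": se,
            "t": t,
            "df": df_total,
            "prior_df": moderation.prior_df,
            "p": p,
            "ci_low": estimate - tq * se,
            "ci_high": estimate + tq * se,
            "zero_se": zero_se,
        },
        index=fit.means.index,
    )
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are propagated (with a warning) and excluded from the number of
    tests; ties share an adjusted value; output is monotone in p.
    """
    p = np.asarray(p, dtype=float)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through BH adjustment", stacklevel=2)
    ps = p[~nan]
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = ps.size
    if m:
        order = np.argsort(ps, kind="mergesort")
        scaled = ps[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.clip(adj, 0.0, 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[~nan] = restored
    return out


def run_contrasts(
    matrix: IntensityMatrix,
    fdr: float = 0.1,
    contrasts: dict[str, dict[str, float]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit, moderate and test all contrasts; append BH-adjusted significance."""
    contrasts = contrasts or CONTRASTS
    fit = fit_group_means(matrix)
    moderation = moderate_variances(fit.s2, fit.df)
    results = {}
    for name, c in contrasts.items():
        table = contrast_test(fit, moderation, c)
        table["adj_p"] = adjust_bh(table["p"].to_numpy())
        table["significant"] = table["adj_p"] <= fdr
        results[name] = table
    return results
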
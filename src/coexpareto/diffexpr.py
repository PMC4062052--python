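"""Empirical-Bayes moderated-t differential expression for two groups.

Per gene, a two-group linear model gives the mean difference (post - pre)
and a pooled residual variance s_g^2 on d_g = n - 2 degrees of freedom.
An inverse-chi-square prior on the true variances, with hyperparameters
(d0, s0^2) fit by method of moments on log s_g^2, yields the posterior
variance

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

and a moderated t statistic referred to a t distribution with d0 + d_g
degrees of freedom (standard normal when d0 is infinite).  Genes with a
Benjamini-Hochberg q-value below the FDR threshold (default 5%) are called
differentially expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy


@dataclass
class GeneStats:
    """Per-gene two-group linear-model summaries (vectorized over genes)."""

    gene_id: np.ndarray       # str array
    mean_diff: np.ndarray     # post - pre, log units
    s2: np.ndarray            # pooled residual variance
    df: float                 # residual degrees of freedom, n - 2
    v: float                  # unscaled variance factor 1/n_pre + 1/n_post


@dataclass
class EBPrior:
    d0: float                 # prior degrees of freedom, may be math.inf
    s02: float                # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s02 > 0):
            raise ValueError(f"invalid prior: d0={self.d0}, s02={self.s02}")


def fit_gene_stats(study: ExpressionStudy) -> GeneStats:
    """Two-group mean difference and pooled residual variance per gene."""
    pre = study.subset("pre").to_numpy()
    post = study.subset("post").to_numpy()
    n1, n2 = pre.shape[1], post.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each condition needs >= 2 samples, got {n1} pre / {n2} post")
    mean_diff = post.mean(axis=1) - pre.mean(axis=1)
    ss = ((pre - pre.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((post - post.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    return GeneStats(gene_id=np.asarray(study.genes, dtype=object),
                     mean_diff=mean_diff, s2=ss / df, df=float(df),
                     v=1.0 / n1 + 1.0 / n2)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(gstats: GeneStats) -> EBPrior:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    With true variance sigma^2 and s^2 ~ sigma^2 * chi2_d / d, the statistic
    e = log s^2 - digamma(d/2) + log(d/2) has mean log sigma^2 and variance
    trigamma(d/2); excess dispersion of e across genes identifies d0 via the
    trigamma equation.  No positive solution (no excess) means no evidence of
    variance heterogeneity and d0 is reported as infinite.
    """
    s2 = np.asarray(gstats.s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 10:
        raise ValueError("need at least 10 genes with positive variance")
    s2 = s2[positive]
    half_d = gstats.df / 2.0
    e = np.log(s2) - special.digamma(half_d) + math.log(half_d)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, half_d))
    if excess <= 0:
        return EBPrior(d0=math.inf, s02=math.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    s02 = math.exp(e_mean + special.digamma(half_d0) - math.log(half_d0))
    return EBPrior(d0=2.0 * half_d0, s02=s02)


def moderated_t(gstats: GeneStats, prior: EBPrior) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values per gene."""
    d0, s02, dg = prior.d0, prior.s02, gstats.df
    if math.isinf(d0):
        s2_post = np.full_like(gstats.s2, s02)
    else:
        s2_post = (d0 * s02 + dg * gstats.s2) / (d0 + dg)
    se = np.sqrt(s2_post * gstats.v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, gstats.mean_diff / np.where(se > 0, se, 1.0),
                     np.where(gstats.mean_diff == 0, 0.0,
                              np.sign(gstats.mean_diff) * np.inf))
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + dg)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (gstats.mean_diff == 0), 1.0, p)
    return pd.DataFrame({"gene_id": gstats.gene_id,
                         "mean_diff": gstats.mean_diff,
                         "t": t, "p": np.clip(p, 0.0, 1.0)})


def ordinary_t(gstats: GeneStats) -> pd.DataFrame:
    """Plain pooled two-sample t (the d0 = 0 limit of the moderated t)."""
    se = np.sqrt(gstats.s2 * gstats.v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, gstats.mean_diff / np.where(se > 0, se, 1.0),
                     np.where(gstats.mean_diff == 0, 0.0,
                              np.sign(gstats.mean_diff) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df=gstats.df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (gstats.mean_diff == 0), 1.0, p)
    return pd.DataFrame({"gene_id": gstats.gene_id,
                         "mean_diff": gstats.mean_diff,
                         "t": t, "p": np.clip(p, 0.0, 1.0)})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(study: ExpressionStudy, fdr: float = 0.05,
           moderated: bool = True) -> pd.DataFrame:
    """Full DE analysis: statistics, BH q-values and the 'is_de' call."""
    gstats = fit_gene_stats(study)
    if moderated:
        result = moderated_t(gstats, estimate_prior(gstats))
    else:
        result = ordinary_t(gstats)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["is_de"] = result["q"] < fdr
    return result


def select_de_genes(results: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Gene ids with BH q-value below the FDR threshold."""
    if len(results) == 0:
        return set()
    return set(results.loc[results["q"] < fdr, "gene_id"])
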
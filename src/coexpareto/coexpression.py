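"""Condition-specific coexpression networks from first-order Spearman
partial correlations.

For every pair of genes (i, j) in the analysis universe, the screen
computes the zero-order Spearman correlation rho0 and, for every other
gene z, the first-order partial correlation

    rho_ij.z = (rho_ij - rho_iz * rho_jz) / sqrt((1 - rho_iz^2)(1 - rho_jz^2)).

A pair that owes its marginal correlation to a single common regulator has
a near-zero partial given that regulator, so the pair-level p-value is, by
default, the LEAST significant of the zero-order test and the test of the
minimum-magnitude first-order partial: an edge must survive marginally and
given every single conditioner.  P-values use the Fisher z transform with
standard error 1/sqrt(n - k - 3) for a partial of order k.  Edges are
retained at a Benjamini-Hochberg FDR threshold (default alpha = 0.01)
across all pairs of the condition, and the edge sign is the sign of rho0.

A permutation test (independently shuffling each gene's values across
samples within the condition) provides an empirical null for the total
significant-edge count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

PAIR_P_CONVENTIONS = ("max", "partial_only")


@dataclass
class CoexpressionNetwork:
    condition: str
    genes: list[str]                      # analysis universe (non-constant genes)
    edges: pd.DataFrame = field(repr=False)
    alpha: float = 0.01

    # edge table columns
    COLUMNS = ("gene_i", "gene_j", "rho0", "min_partial", "argmin_conditioner",
               "pair_p", "q", "sign")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.edges.columns:
                raise ValueError(f"edge table lacks column {col!r}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_i"], self.edges["gene_j"]))

    def signs(self) -> dict[tuple[str, str], int]:
        return {(i, j): s for i, j, s in
                zip(self.edges["gene_i"], self.edges["gene_j"], self.edges["sign"])}


def spearman_matrix(expr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Spearman correlation matrix (Pearson correlation of average ranks).

    Genes with constant expression have undefined correlations and are
    excluded from the returned universe with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    values = expr.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = list(expr.index[constant])
        logger.warning("excluding %d constant gene(s) from the universe: %s",
                       len(dropped), dropped[:5])
        values = values[~constant]
    genes = list(expr.index[~constant])
    if len(genes) == 0:
        return np.empty((0, 0)), []
    ranks = stats.rankdata(values, axis=1)
    corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0), genes


def first_order_partial(rho_xy, rho_xz, rho_yz):
    """First-order partial correlation of (x, y) given z (recursion formula)."""
    rho_xy, rho_xz, rho_yz = (np.asarray(r, dtype=float)
                              for r in (rho_xy, rho_xz, rho_yz))
    den2 = (1.0 - rho_xz ** 2) * (1.0 - rho_yz ** 2)
    if np.any(den2 <= 0):
        raise ZeroDivisionError("conditioner perfectly correlated with x or y")
    out = (rho_xy - rho_xz * rho_yz) / np.sqrt(den2)
    return float(out) if out.ndim == 0 else out


def partial_p_value(r, n: int, k: int = 0):
    """Two-sided p-value for a (partial) correlation of order k via Fisher z."""
    if n <= k + 3:
        raise ValueError(f"need n > k + 3, got n={n}, k={k}")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    se = 1.0 / np.sqrt(n - k - 3)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    p = 2.0 * stats.norm.sf(np.abs(z) / se)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


def _pairwise_stats(corr: np.ndarray, n: int,
                    convention: str = "max") -> dict[str, np.ndarray]:
    """Vectorized zero-order + weakest-first-order statistics for all pairs.

    Returns square matrices: rho0, min_partial (the signed partial with the
    smallest magnitude over single conditioners), argmin (conditioner index,
    -1 when there is none) and pair_p.
    """
    if convention not in PAIR_P_CONVENTIONS:
        raise ValueError(f"unknown pair-p convention {convention!r}")
    m = corr.shape[0]
    p0 = partial_p_value(corr, n, k=0)
    min_abs = np.full((m, m), np.inf)
    min_val = np.full((m, m), np.nan)
    argmin = np.full((m, m), -1, dtype=int)
    degenerate = np.abs(corr) >= 1.0 - 1e-12
    for z in range(m):
        rz = corr[:, z]
        den2 = np.outer(1.0 - rz ** 2, 1.0 - rz ** 2)
        valid = den2 > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            partial = (corr - np.outer(rz, rz)) / np.sqrt(np.where(valid, den2, 1.0))
        # a conditioner collinear with either endpoint is skipped
        valid &= ~np.outer(degenerate[:, z], np.ones(m, bool))
        valid &= ~np.outer(np.ones(m, bool), degenerate[:, z])
        valid[z, :] = valid[:, z] = False
        update = valid & (np.abs(partial) < min_abs)
        min_abs = np.where(update, np.abs(partial), min_abs)
        min_val = np.where(update, partial, min_val)
        argmin = np.where(update, z, argmin)
    has_conditioner = np.isfinite(min_abs)
    p1 = np.ones((m, m))
    p1[has_conditioner] = partial_p_value(
        np.clip(min_val[has_conditioner], -1.0, 1.0), n, k=1)
    if convention == "max":
        pair_p = np.where(has_conditioner, np.maximum(p0, p1), p0)
    else:
        pair_p = np.where(has_conditioner, p1, p0)
    return {"rho0": corr, "min_partial": min_val, "argmin": argmin,
            "pair_p": pair_p, "has_conditioner": has_conditioner}


def pair_significance(corr: np.ndarray, i: int, j: int, n: int,
                      convention: str = "max") -> tuple[float, float, int]:
    """(pair_p, min_partial, argmin_conditioner) for a single gene pair."""
    s = _pairwise_stats(corr, n, convention)
    mp = s["min_partial"][i, j]
    return (float(s["pair_p"][i, j]),
            float(mp) if np.isfinite(mp) else float("nan"),
            int(s["argmin"][i, j]))


def build_network(study: ExpressionStudy, condition: str,
                  universe: set[str] | list[str] | None = None,
                  alpha: float = 0.01,
                  convention: str = "max") -> CoexpressionNetwork:
    """Coexpression network of one condition over a gene universe.

    Pair p-values for all C(m, 2) pairs are BH-adjusted jointly and edges
    with q < alpha retained.
    """
    expr = study.subset(condition)
    if universe is not None:
        unknown = set(universe) - set(expr.index)
        if unknown:
            raise ValueError(f"universe genes missing from expression: "
                             f"{sorted(unknown)[:5]}")
        expr = expr.loc[[g for g in expr.index if g in set(universe)]]
    if len(expr) < 2:
        logger.warning("fewer than 2 genes in universe; empty %s network", condition)
        return CoexpressionNetwork(condition=condition, genes=list(expr.index),
                                   edges=_empty_edges(), alpha=alpha)
    corr, genes = spearman_matrix(expr)
    n = expr.shape[1]
    return _network_from_corr(corr, genes, n, condition, alpha, convention)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CoexpressionNetwork.COLUMNS,
        (str, str, float, float, str, float, float, int))})


def _network_from_corr(corr: np.ndarray, genes: list[str], n: int,
                       condition: str, alpha: float,
                       convention: str) -> CoexpressionNetwork:
    m = len(genes)
    if m < 2:
        return CoexpressionNetwork(condition=condition, genes=genes,
                                   edges=_empty_edges(), alpha=alpha)
    s = _pairwise_stats(corr, n, convention)
    iu, ju = np.triu_indices(m, k=1)
    pair_p = s["pair_p"][iu, ju]
    q = bh_adjust(pair_p)
    keep = q < alpha
    gene_arr = np.asarray(genes, dtype=object)
    argmin = s["argmin"][iu, ju][keep]
    edges = pd.DataFrame({
        "gene_i": gene_arr[iu[keep]],
        "gene_j": gene_arr[ju[keep]],
        "rho0": s["rho0"][iu, ju][keep],
        "min_partial": s["min_partial"][iu, ju][keep],
        "argmin_conditioner": [genes[z] if z >= 0 else "" for z in argmin],
        "pair_p": pair_p[keep],
        "q": q[keep],
        "sign": np.where(s["rho0"][iu, ju][keep] >= 0, 1, -1),
    })
    # canonical i < j lexicographic ordering for stable output
    flip = edges["gene_i"] > edges["gene_j"]
    if flip.any():  # pragma: no cover - triu already yields sorted indices
        edges.loc[flip, ["gene_i", "gene_j"]] = \
            edges.loc[flip, ["gene_j", "gene_i"]].to_numpy()
    edges = edges.sort_values(["gene_i", "gene_j"], ignore_index=True)
    return CoexpressionNetwork(condition=condition, genes=genes,
                               edges=edges, alpha=alpha)


@dataclass
class PermutationNull:
    B: int
    null_counts: np.ndarray
    observed_count: int
    statistic: str = "raw"

    @property
    def empirical_p(self) -> float:
        return (1 + int((self.null_counts >= self.observed_count).sum())) / (self.B + 1)


def _significant_pair_count(expr_values: np.ndarray, alpha: float,
                            convention: str, statistic: str) -> int:
    """Count of significant pairs in one matrix (genes x samples).

    statistic="raw": pairs with pair_p < alpha.  This is the permutation
    test statistic of choice: it is a fixed function of the data, so the
    empirical p is calibrated.  statistic="bh": pairs surviving the BH
    screen at q < alpha (the main analysis's edge count; under a true null
    it is almost always zero, making the permutation p conservative).
    """
    keep = expr_values.std(axis=1) > 0
    values = expr_values[keep]
    m, n = values.shape
    if m < 2:
        return 0
    ranks = stats.rankdata(values, axis=1)
    corr = np.clip(np.corrcoef(ranks), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    s = _pairwise_stats(corr, n, convention)
    iu, ju = np.triu_indices(m, k=1)
    pair_p = s["pair_p"][iu, ju]
    if statistic == "raw":
        return int((pair_p < alpha).sum())
    if statistic == "bh":
        return int((bh_adjust(pair_p) < alpha).sum())
    raise ValueError(f"unknown permutation statistic {statistic!r}")


def permutation_null(study: ExpressionStudy, condition: str,
                     universe: set[str] | list[str] | None = None,
                     alpha: float = 0.01, B: int = 1000, seed: int = 0,
                     convention: str = "max",
                     statistic: str = "raw") -> PermutationNull:
    """Empirical null for the significant-pair count.

    Each replicate independently permutes every gene's expression values
    across samples within the condition, destroying all gene-gene dependence
    while preserving marginals, then recomputes the count of pairs meeting
    the significance threshold (see _significant_pair_count for the two
    count statistics).  One seeded substream per replicate keeps results
    reproducible independent of parallelization.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    expr = study.subset(condition)
    if universe is not None:
        unknown = set(universe) - set(expr.index)
        if unknown:
            raise ValueError(f"universe genes missing from expression: "
                             f"{sorted(unknown)[:5]}")
        expr = expr.loc[[g for g in expr.index if g in set(universe)]]
    values = expr.to_numpy(dtype=float)
    observed = _significant_pair_count(values, alpha, convention, statistic)
    counts = np.zeros(B, dtype=int)
    children = np.random.SeedSequence(seed).spawn(B)
    for b, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        permuted = np.take_along_axis(
            values, np.argsort(rng.random(values.shape), axis=1), axis=1)
        counts[b] = _significant_pair_count(permuted, alpha, convention,
                                            statistic)
    return PermutationNull(B=B, null_counts=counts, observed_count=observed,
                           statistic=statistic)


def write_edges_tsv(net: CoexpressionNetwork, path) -> None:
    out = net.edges.copy()
    out["sign"] = np.where(out["sign"] > 0, "+", "-")
    out["condition"] = net.condition
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edges_tsv(path, alpha: float = 0.01) -> CoexpressionNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    condition = df["condition"].iloc[0] if len(df) else "pre"
    df = df.drop(columns=["condition"], errors="ignore")
    df["sign"] = np.where(df["sign"].astype(str) == "+", 1, -1) if len(df) else \
        pd.Series(dtype=int)
    if "argmin_conditioner" in df.columns:
        df["argmin_conditioner"] = df["argmin_conditioner"].fillna("")
    genes = sorted(set(df["gene_i"]) | set(df["gene_j"]))
    return CoexpressionNetwork(condition=condition, genes=genes,
                               edges=df, alpha=alpha)
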
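"""Differential coexpression: set algebra between two condition networks.

Edges are keyed by unordered gene pair (sign ignored for membership).  A
pair significant in both conditions is "common"; common pairs whose signs
differ between conditions are flagged as sign flips rather than treated as
exclusive.  Common edges are removed before the gene-wise essentiality
analysis, leaving the condition-exclusive (differential) networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork, _empty_edges


@dataclass
class DifferentialCoexpression:
    universe: list[str]
    alpha: float
    exclusive_pre: pd.DataFrame = field(repr=False)   # edge rows from the pre net
    exclusive_post: pd.DataFrame = field(repr=False)  # edge rows from the post net
    common: pd.DataFrame = field(repr=False)          # pair, signs, conserved flag

    @property
    def n_union(self) -> int:
        return len(self.exclusive_pre) + len(self.exclusive_post) + len(self.common)

    @property
    def exclusivity_fraction(self) -> float:
        if self.n_union == 0:
            return float("nan")
        return (len(self.exclusive_pre) + len(self.exclusive_post)) / self.n_union

    @property
    def ratio_post_over_pre(self) -> float:
        n_pre = len(self.exclusive_pre) + len(self.common)
        n_post = len(self.exclusive_post) + len(self.common)
        if n_pre == 0:
            return float("nan")
        return n_post / n_pre

    def summary(self) -> dict[str, float]:
        return {
            "n_edges_pre": len(self.exclusive_pre) + len(self.common),
            "n_edges_post": len(self.exclusive_post) + len(self.common),
            "n_exclusive_pre": len(self.exclusive_pre),
            "n_exclusive_post": len(self.exclusive_post),
            "n_common": len(self.common),
            "n_common_conserved": int(self.common["conserved"].sum())
            if len(self.common) else 0,
            "exclusivity_fraction": self.exclusivity_fraction,
            "ratio_post_over_pre": self.ratio_post_over_pre,
        }


def classify_edges(net_pre: CoexpressionNetwork,
                   net_post: CoexpressionNetwork) -> DifferentialCoexpression:
    """Partition the union of both networks' pairs into pre-exclusive,
    post-exclusive and common edges."""
    if set(net_pre.genes) != set(net_post.genes):
        diff = sorted(set(net_pre.genes) ^ set(net_post.genes))
        raise ValueError(f"networks have different gene universes; "
                         f"symmetric difference: {diff[:10]}")
    pairs_pre = net_pre.pairs()
    pairs_post = net_post.pairs()
    common_pairs = pairs_pre & pairs_post

    def _subset(net: CoexpressionNetwork, keep: set[tuple[str, str]]) -> pd.DataFrame:
        if not len(net.edges):
            return net.edges.copy()
        mask = [
            (i, j) in keep
            for i, j in zip(net.edges["gene_i"], net.edges["gene_j"])
        ]
        return net.edges[mask].reset_index(drop=True)

    exclusive_pre = _subset(net_pre, pairs_pre - pairs_post)
    exclusive_post = _subset(net_post, pairs_post - pairs_pre)

    sign_pre = net_pre.signs()
    sign_post = net_post.signs()
    common_rows = [
        {"gene_i": i, "gene_j": j,
         "sign_pre": sign_pre[(i, j)], "sign_post": sign_post[(i, j)],
         "conserved": sign_pre[(i, j)] == sign_post[(i, j)]}
        for i, j in sorted(common_pairs)
    ]
    common = pd.DataFrame(
        common_rows,
        columns=["gene_i", "gene_j", "sign_pre", "sign_post", "conserved"])
    return DifferentialCoexpression(
        universe=sorted(set(net_pre.genes)), alpha=net_pre.alpha,
        exclusive_pre=exclusive_pre, exclusive_post=exclusive_post,
        common=common)


def sign_conservation(dc: DifferentialCoexpression) -> tuple[pd.DataFrame,
                                                             pd.DataFrame]:
    """Split common edges into sign-conserved and sign-flipped subsets."""
    conserved = dc.common[dc.common["conserved"]].reset_index(drop=True)
    flipped = dc.common[~dc.common["conserved"]].reset_index(drop=True)
    return conserved, flipped


def differential_networks(dc: DifferentialCoexpression
                          ) -> tuple[CoexpressionNetwork, CoexpressionNetwork]:
    """The condition-exclusive edge sets as networks over the shared universe.

    These are the inputs to the Pareto essentiality analysis: common edges
    have been removed, leaving only differential coexpression.
    """
    pre = CoexpressionNetwork(condition="pre", genes=list(dc.universe),
                              edges=dc.exclusive_pre.copy(), alpha=dc.alpha)
    post = CoexpressionNetwork(condition="post", genes=list(dc.universe),
                               edges=dc.exclusive_post.copy(), alpha=dc.alpha)
    return pre, post


def empty_differential(universe: list[str],
                       alpha: float = 0.01) -> DifferentialCoexpression:
    """A DifferentialCoexpression with no edges (degenerate-input helper)."""
    return DifferentialCoexpression(
        universe=sorted(universe), alpha=alpha,
        exclusive_pre=_empty_edges(), exclusive_post=_empty_edges(),
        common=pd.DataFrame(columns=["gene_i", "gene_j", "sign_pre",
                                     "sign_post", "conserved"]))


def write_diffcoex_tsvs(dc: DifferentialCoexpression, out_dir) -> dict[str, str]:
    """Write exclusive/common edge tables and the summary; returns paths."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("exclusive_pre", dc.exclusive_pre),
                     ("exclusive_post", dc.exclusive_post),
                     ("common", dc.common)):
        p = out / f"{name}.tsv"
        dump = df.copy()
        for col in ("sign", "sign_pre", "sign_post"):
            if col in dump.columns:
                dump[col] = np.where(dump[col].astype(int) > 0, "+", "-") \
                    if len(dump) else dump[col]
        dump.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = str(p)
    summary = pd.DataFrame([dc.summary()])
    p = out / "diffcoex_summary.tsv"
    summary.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["summary"] = str(p)
    return paths
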
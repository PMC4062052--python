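"""Double-connectivity profiles and Pareto-optimal gene selection.

Essential genes tend to sustain many positive AND many negative interaction
partners ("double connectivity").  Maximizing both partner counts at once is
a two-objective problem, so instead of a single winner we report the Pareto
front: the genes not dominated by any other gene, where gene h dominates
gene g when h has at least as many positive and negative partners and
strictly more of at least one kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import CoexpressionNetwork


def connectivity_profiles(net: CoexpressionNetwork) -> pd.DataFrame:
    """Per-gene counts of positively and negatively connected partners.

    Every gene of the universe appears, including isolated genes at (0, 0).
    """
    counts = {g: [0, 0] for g in net.genes}
    for i, j, s in zip(net.edges["gene_i"], net.edges["gene_j"],
                       net.edges["sign"]):
        idx = 0 if s > 0 else 1
        counts[i][idx] += 1
        counts[j][idx] += 1
    profiles = pd.DataFrame(
        [(g, c[0], c[1]) for g, c in counts.items()],
        columns=["gene_id", "n_pos", "n_neg"])
    return profiles.sort_values("gene_id", ignore_index=True)


@dataclass
class ParetoResult:
    front: list[str]                      # sorted by (n_pos desc, n_neg desc, id)
    dominated: list[str]
    profiles: pd.DataFrame = field(repr=False)  # + on_front, n_dominators columns


def pareto_front(profiles: pd.DataFrame) -> ParetoResult:
    """Non-dominated genes under (n_pos, n_neg) maximization.

    Uses a sort-and-sweep over the distinct coordinate points: a point
    (a, b) is dominated iff some point with a' > a has b' >= b, or some
    point with a' = a has b' > b; genes sharing a coordinate point share
    front membership.  Dominance counts are retained for diagnostics.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one connectivity profile")
    pts = profiles[["n_pos", "n_neg"]].to_numpy(dtype=int)
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    # group max of n_neg per n_pos value, swept from the largest n_pos down
    order = np.lexsort((-uniq[:, 1], -uniq[:, 0]))
    on_front_uniq = np.zeros(len(uniq), dtype=bool)
    best_higher = -1          # max n_neg among points with strictly larger n_pos
    k = 0
    while k < len(order):
        a = uniq[order[k], 0]
        group = [order[k]]
        while k + 1 < len(order) and uniq[order[k + 1], 0] == a:
            k += 1
            group.append(order[k])
        group_max_b = uniq[group[0], 1]   # sorted desc within group
        for idx in group:
            b = uniq[idx, 1]
            on_front_uniq[idx] = (b == group_max_b) and (b > best_higher)
        best_higher = max(best_higher, group_max_b)
        k += 1

    # dominance counts (diagnostic): number of genes strictly dominating each
    a, b = pts[:, 0], pts[:, 1]
    ge = (a[None, :] >= a[:, None]) & (b[None, :] >= b[:, None])
    strict = (a[None, :] > a[:, None]) | (b[None, :] > b[:, None])
    n_dominators = (ge & strict).sum(axis=1)

    out = profiles.copy()
    out["on_front"] = on_front_uniq[inverse]
    out["n_dominators"] = n_dominators
    front_rows = out[out["on_front"]].sort_values(
        ["n_pos", "n_neg", "gene_id"], ascending=[False, False, True])
    dominated_rows = out[~out["on_front"]].sort_values("gene_id")
    return ParetoResult(front=list(front_rows["gene_id"]),
                        dominated=list(dominated_rows["gene_id"]),
                        profiles=out)


def pareto_front_bruteforce(profiles: pd.DataFrame) -> set[str]:
    """O(n^2) dominance scan, kept as an independent oracle for the sweep."""
    pts = profiles[["n_pos", "n_neg"]].to_numpy(dtype=int)
    genes = list(profiles["gene_id"])
    front = set()
    for g in range(len(genes)):
        dominated = False
        for h in range(len(genes)):
            if h == g:
                continue
            if (pts[h, 0] >= pts[g, 0] and pts[h, 1] >= pts[g, 1]
                    and (pts[h, 0] > pts[g, 0] or pts[h, 1] > pts[g, 1])):
                dominated = True
                break
        if not dominated:
            front.add(genes[g])
    return front


def ego_subnetwork(gene_id: str, net_pre: CoexpressionNetwork,
                   net_post: CoexpressionNetwork
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All edges incident to a focal gene in each condition network,
    for side-by-side reporting of how its partner set changes."""
    universe = set(net_pre.genes) | set(net_post.genes)
    if gene_id not in universe:
        raise ValueError(f"gene {gene_id!r} not in the network universe")

    def _incident(net: CoexpressionNetwork) -> pd.DataFrame:
        if not len(net.edges):
            return net.edges.copy()
        mask = (net.edges["gene_i"] == gene_id) | (net.edges["gene_j"] == gene_id)
        return net.edges[mask].reset_index(drop=True)

    return _incident(net_pre), _incident(net_post)


def write_profiles_tsv(result: ParetoResult, path) -> None:
    result.profiles.to_csv(path, sep="\t", index=False)
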
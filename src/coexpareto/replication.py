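"""Two-cohort replication of treatment-induced coexpression.

The replication analysis restricts both cohorts to the genes differentially
expressed in each, rebuilds the condition networks, and reports the
treatment-induced (post-exclusive) edges that appear in BOTH cohorts with
the same correlation sign.  Requiring post-exclusivity in both cohorts (not
merely significance in the replication post network) mirrors the stricter
reading in which a replicated induced edge must be absent from both
untreated networks; a looser criterion is available via ``require_exclusive``.
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotation import AnnotationTable, FunctionalNetwork, pair_shared_terms
from .diffcoex import DifferentialCoexpression

logger = logging.getLogger(__name__)


def intersect_de(de_a: set[str], de_b: set[str]) -> set[str]:
    """Genes differentially expressed in both cohorts."""
    shared = set(de_a) & set(de_b)
    if de_a and de_b and not shared:
        logger.warning("DE gene sets from the two cohorts do not overlap; "
                       "check that they share an identifier namespace")
    logger.info("DE intersection: %d genes (%d and %d per cohort)",
                len(shared), len(de_a), len(de_b))
    return shared


def _post_pairs(dc: DifferentialCoexpression,
                require_exclusive: bool) -> pd.DataFrame:
    if require_exclusive:
        return dc.exclusive_post
    extra = dc.common.rename(columns={"sign_post": "sign"})
    cols = ["gene_i", "gene_j", "sign"]
    return pd.concat([dc.exclusive_post[["gene_i", "gene_j", "sign", "rho0"]]
                      if len(dc.exclusive_post) else
                      pd.DataFrame(columns=["gene_i", "gene_j", "sign", "rho0"]),
                      extra.reindex(columns=cols + ["rho0"])],
                     ignore_index=True)


def replicate_induced_edges(dc_discovery: DifferentialCoexpression,
                            dc_replication: DifferentialCoexpression,
                            de_discovery: pd.DataFrame | None = None,
                            tables: tuple[AnnotationTable, ...] = (),
                            fnet: FunctionalNetwork | None = None,
                            require_exclusive: bool = True) -> pd.DataFrame:
    """Treatment-induced edges present in both cohorts with matching sign.

    Returns one row per replicated edge with the expression-change direction
    of each gene (from the discovery DE table, if given), the retained
    correlation coefficient in each cohort, shared annotation terms per
    source and the functional-network probability.
    """
    if set(dc_discovery.universe) != set(dc_replication.universe):
        diff = sorted(set(dc_discovery.universe) ^ set(dc_replication.universe))
        raise ValueError(f"differential objects built on different universes; "
                         f"symmetric difference: {diff[:10]}")
    disc = _post_pairs(dc_discovery, require_exclusive)
    repl = _post_pairs(dc_replication, require_exclusive)
    repl_idx = {(i, j): (s, r) for i, j, s, r in zip(
        repl["gene_i"], repl["gene_j"], repl["sign"], repl["rho0"])}

    directions: dict[str, str] = {}
    if de_discovery is not None:
        directions = {g: ("up" if d > 0 else "down") for g, d in zip(
            de_discovery["gene_id"], de_discovery["mean_diff"])}

    rows = []
    for i, j, s, r in zip(disc["gene_i"], disc["gene_j"], disc["sign"],
                          disc["rho0"]):
        hit = repl_idx.get((i, j))
        if hit is None or hit[0] != s:
            continue
        row = {"gene_1": i, "gene_2": j,
               "dir_1": directions.get(i, ""), "dir_2": directions.get(j, ""),
               "coef_discovery": r, "coef_replication": hit[1],
               "sign": "+" if s > 0 else "-"}
        for t in tables:
            row[f"shared_{t.source}"] = "|".join(sorted(pair_shared_terms(i, j, t)))
        row["functional_probability"] = (fnet.probability(i, j)
                                         if fnet is not None else "")
        rows.append(row)
    columns = ["gene_1", "gene_2", "dir_1", "dir_2", "coef_discovery",
               "coef_replication", "sign"]
    columns += [f"shared_{t.source}" for t in tables] + ["functional_probability"]
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(["gene_1", "gene_2"], ignore_index=True)
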
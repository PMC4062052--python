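"""External biological support for coexpressed gene pairs.

Two kinds of evidence are combined: (1) curated gene-set annotations (GMT
files, e.g. GO biological process, KEGG, Reactome) scored by intersecting
the two genes' term sets, and (2) a pairwise functional-evidence network
whose edge weights are posterior probabilities of a functional relationship,
thresholded at 0.70 by default.  An edge counts as supported when the genes
share at least one term in any source or exceed the probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PROB_THRESHOLD = 0.70


@dataclass
class AnnotationTable:
    source: str
    gene_terms: dict[str, set[str]] = field(repr=False)
    term_names: dict[str, str] = field(default_factory=dict, repr=False)

    _warned: set[str] = field(default_factory=set, repr=False)

    def terms(self, gene: str) -> set[str]:
        t = self.gene_terms.get(gene)
        if t is None:
            if gene not in self._warned:
                logger.info("gene %s has no %s annotations", gene, self.source)
                self._warned.add(gene)
            return set()
        return t

    def annotation_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, len(t)) for g, t in sorted(self.gene_terms.items())],
            columns=["gene_id", "n_terms"])


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationTable:
    """Parse a GMT gene-set file (term <tab> description <tab> genes...)."""
    path = Path(path)
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
        term, description, genes = fields[0], fields[1], fields[2:]
        term_names[term] = description
        for gene in genes:
            if gene:
                gene_terms.setdefault(gene, set()).add(term)
    return AnnotationTable(source=source or path.stem,
                           gene_terms=gene_terms, term_names=term_names)


def write_gmt(table: AnnotationTable, path: str | Path) -> None:
    by_term: dict[str, list[str]] = {}
    for gene, terms in table.gene_terms.items():
        for t in terms:
            by_term.setdefault(t, []).append(gene)
    lines = [
        "\t".join([t, table.term_names.get(t, ""), *sorted(genes)])
        for t, genes in sorted(by_term.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FunctionalNetwork:
    """Unordered gene pair -> posterior probability; missing pairs are 0."""

    probabilities: dict[tuple[str, str], float] = field(repr=False)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.probabilities.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"probabilities outside [0, 1]: "
                             f"{list(bad.items())[:3]}")

    def probability(self, gene_i: str, gene_j: str) -> float:
        key = (gene_i, gene_j) if gene_i <= gene_j else (gene_j, gene_i)
        return self.probabilities.get(key, 0.0)


def read_functional_network(path: str | Path) -> FunctionalNetwork:
    """3-column TSV: gene_i, gene_j, probability."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    probs = {}
    for i, j, p in zip(df["gene_i"], df["gene_j"], df["probability"]):
        key = (i, j) if i <= j else (j, i)
        probs[key] = float(p)
    return FunctionalNetwork(probabilities=probs)


def pair_shared_terms(gene_i: str, gene_j: str,
                      table: AnnotationTable) -> set[str]:
    """Terms annotated to both genes (empty if either gene is unannotated)."""
    return table.terms(gene_i) & table.terms(gene_j)


def evidence_support(edges: pd.DataFrame,
                     tables: list[AnnotationTable] | tuple = (),
                     fnet: FunctionalNetwork | None = None,
                     prob_threshold: float = DEFAULT_PROB_THRESHOLD
                     ) -> tuple[pd.DataFrame, float]:
    """Per-edge support flags and the overall supported fraction.

    An edge is supported iff the pair shares >= 1 term in some table OR the
    functional-network probability reaches the threshold.  With no edges the
    fraction is undefined (NaN).
    """
    rows = []
    for i, j in zip(edges["gene_i"], edges["gene_j"]):
        shared = {t.source: sorted(pair_shared_terms(i, j, t)) for t in tables}
        prob = fnet.probability(i, j) if fnet is not None else 0.0
        supported = any(shared.values()) or prob >= prob_threshold
        row = {"gene_i": i, "gene_j": j, "functional_probability": prob,
               "supported": supported}
        for t in tables:
            row[f"shared_{t.source}"] = "|".join(shared[t.source])
        rows.append(row)
    support = pd.DataFrame(rows)
    if len(support) == 0:
        return support, float("nan")
    return support, float(support["supported"].mean())


def exclusive_shared_terms(edges_post_only: pd.DataFrame,
                           edges_pre_only: pd.DataFrame,
                           table: AnnotationTable) -> pd.DataFrame:
    """Terms shared by >= 1 post-exclusive pair and by no pre-exclusive pair,
    sorted by the number of supporting post-only edges."""

    def term_edge_counts(edges: pd.DataFrame) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i, j in zip(edges["gene_i"], edges["gene_j"]):
            for t in pair_shared_terms(i, j, table):
                counts[t] = counts.get(t, 0) + 1
        return counts

    post_counts = term_edge_counts(edges_post_only)
    pre_terms = set(term_edge_counts(edges_pre_only))
    rows = [
        {"term": t, "name": table.term_names.get(t, ""), "n_edges": c}
        for t, c in post_counts.items() if t not in pre_terms
    ]
    out = pd.DataFrame(rows, columns=["term", "name", "n_edges"])
    return out.sort_values(["n_edges", "term"], ascending=[False, True],
                           ignore_index=True)


def toy_annotation_fixture(modules: dict[str, list[str]],
                           source: str = "toy") -> AnnotationTable:
    """Build a small in-memory annotation table (term -> gene list)."""
    gene_terms: dict[str, set[str]] = {}
    for term, genes in modules.items():
        for g in genes:
            gene_terms.setdefault(g, set()).add(term)
    return AnnotationTable(source=source, gene_terms=gene_terms,
                           term_names={t: t for t in modules})
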
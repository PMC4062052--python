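"""Expression study container and plain-text IO.

Expression data are held as a pandas DataFrame of shape (genes, samples)
on a log scale, with a sample-to-condition mapping.  The two conditions
are labelled ``pre`` (untreated / baseline) and ``post`` (treated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CONDITIONS = ("pre", "post")


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with per-sample condition labels."""

    expr: pd.DataFrame            # index: gene ids, columns: sample ids
    condition: pd.Series = field(repr=False)  # index: sample ids, values in CONDITIONS

    def __post_init__(self) -> None:
        missing = [s for s in self.expr.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without condition labels: {missing[:5]}")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self.condition = self.condition.reindex(self.expr.columns)
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    def samples(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset(self, condition: str) -> pd.DataFrame:
        """Expression submatrix (genes x samples) for one condition."""
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        return self.expr[self.samples(condition)]

    def n_samples(self) -> dict[str, int]:
        return {c: int((self.condition == c).sum()) for c in CONDITIONS}


def read_expression_tsv(expr_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    """Load a study from a TSV matrix (first column ``gene_id``) and a
    metadata TSV with columns ``sample_id`` and ``condition``."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in meta.columns:
            raise ValueError(f"metadata file {meta_path} lacks column {col!r}")
    condition = meta.set_index("sample_id")["condition"]
    return ExpressionStudy(expr=expr.astype(float), condition=condition)


def write_expression_tsv(study: ExpressionStudy, expr_path: str | Path,
                         meta_path: str | Path, float_format: str = "%.6g") -> None:
    study.expr.to_csv(expr_path, sep="\t", index_label="gene_id",
                      float_format=float_format)
    meta = pd.DataFrame({"sample_id": study.condition.index,
                         "condition": study.condition.values})
    meta.to_csv(meta_path, sep="\t", index=False)
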
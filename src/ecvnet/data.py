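"""Expression-matrix container and text I/O.

Expression data are held samples x genes (``n`` x ``p``) with log2-scale
values, optionally carrying per-sample annotations (condition, cell line,
cohort). Files are plain TSV with a header row and an identifier column;
both orientations are accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values plus optional sample annotations."""

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup}")
        bad = v.columns[~v.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            raise ValueError(f"non-numeric expression columns: {bad.tolist()}")
        if v.isna().any().any():
            n_na = int(v.isna().sum().sum())
            offenders = v.columns[v.isna().any()].tolist()
            raise ValueError(f"{n_na} missing values in genes {offenders}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("expression matrix must be non-empty")
        if self.annotations is not None:
            self.annotations = self.annotations.loc[v.index]

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def gene(self, name: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        if name not in self.values.columns:
            raise KeyError(f"unknown gene {name!r}")
        return self.values[name].to_numpy()

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(genes)].copy(), self.annotations)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        ann = self.annotations.loc[list(samples)] if self.annotations is not None else None
        return ExpressionMatrix(self.values.loc[list(samples)].copy(), ann)


def read_expression(path, orientation: str = "genes_in_rows", log2: bool = False,
                    annotations=None) -> ExpressionMatrix:
    """Read an expression TSV/CSV into a samples x genes matrix.

    ``orientation`` names where genes live in the *file*; the result is
    always samples x genes. ``log2=True`` applies log2(x + 1).
    ``annotations`` may be a path to a TSV with a sample-id index.
    """
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes_in_rows":
        df = df.T
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dup}")
    non_numeric = [c for c, dt in df.dtypes.items()
                   if not np.issubdtype(dt, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in genes {non_numeric}")
    if log2:
        if (df.to_numpy() < 0).any():
            raise ValueError("negative values: data appear already log-scaled")
        df = np.log2(df + 1.0)
    ann = None
    if annotations is not None:
        ann = pd.read_csv(annotations, sep="\t", index_col=0)
        ann.index = ann.index.astype(str)
    return ExpressionMatrix(df, ann)


def write_expression(X: ExpressionMatrix, path, orientation: str = "genes_in_rows") -> None:
    df = X.values.T if orientation == "genes_in_rows" else X.values
    df.to_csv(path, sep="\t")


def write_annotations(X: ExpressionMatrix, path) -> None:
    if X.annotations is None:
        raise ValueError("matrix carries no annotations")
    X.annotations.to_csv(path, sep="\t")


def filter_genes_by_mean_percentile(X: ExpressionMatrix, percentile: float) -> ExpressionMatrix:
    """Drop genes whose mean expression is strictly below the given
    percentile of all gene means (low-expression filter)."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    if percentile == 0:
        return X
    means = X.values.mean(axis=0)
    cutoff = np.percentile(means.to_numpy(), percentile)
    # strict "lower than": genes exactly at the cutoff stay
    keep = means.index[~(means.to_numpy() < cutoff)]
    return ExpressionMatrix(X.values[keep].copy(), X.annotations)
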
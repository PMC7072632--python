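"""Edge Contribution values (ECv), ΔECv, differential-edge extraction,
cohort transfer, and edge-wise significance tests.

The ECv of edge ``parent -> child`` in sample ``i`` is the fitted additive
component of the child's regression evaluated at that sample's parent
expression: it quantifies how much that edge contributes to the child's
predicted expression in that particular sample. Stacking ECvs over all
samples and all network edges gives the n x m ECv matrix.

ΔECv is the absolute difference of mean ECv between two sample groups (each
group may be a single sample); edges whose ΔECv exceeds a threshold in every
comparison group form the condition-differential edge set. Because additive
components are identified only up to constants, raw ECvs carry an arbitrary
per-edge offset; ΔECv and the edge-wise tests difference it out.

ECv transfer evaluates the *original* trained edge models on a new cohort's
expression values (no refitting, no renormalization); parent values outside
the training range are clamped to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix
from .local_model import ModelSet

EDGE_SEP = "→"  # arrow used in "parent→child" edge identifiers


def edge_id(edge: tuple[str, str]) -> str:
    return f"{edge[0]}{EDGE_SEP}{edge[1]}"


def parse_edge_id(eid: str) -> tuple[str, str]:
    p, _, c = eid.partition(EDGE_SEP)
    if not c:
        raise ValueError(f"not an edge identifier: {eid!r}")
    return (p, c)


@dataclass
class EcvMatrix:
    """n samples x m edges matrix of edge contributions.

    ``values`` is a DataFrame indexed by sample with one column per edge id
    ("parent→child"), in the provenance ModelSet's edge enumeration order.
    """

    values: pd.DataFrame
    edges: tuple[tuple[str, str], ...]
    provenance: ModelSet | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != [edge_id(e) for e in self.edges]:
            raise ValueError("column order must match the edge enumeration")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("ECv matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, provenance: ModelSet | None = None) -> "EcvMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        edges = tuple(parse_edge_id(c) for c in df.columns)
        return cls(values=df, edges=edges, provenance=provenance)


def compute_ecv_matrix(models: ModelSet, X: ExpressionMatrix) -> EcvMatrix:
    """ECv of every model edge for every sample of ``X``.

    Requires every parent gene to be present; use :func:`transfer_ecv` for
    cohorts with partial gene coverage.
    """
    cols = {}
    edges = tuple(models.edges)
    for parent, child in edges:
        if parent not in X.values.columns:
            raise KeyError(
                f"gene {parent!r} missing from expression matrix; "
                "use transfer_ecv for partial gene sets"
            )
        model = models[child]
        k = model.parents.index(parent) + 1
        cols[edge_id((parent, child))] = model.component_value(k, X.gene(parent))
    values = pd.DataFrame(cols, index=X.values.index)
    return EcvMatrix(values=values, edges=edges, provenance=models)


def delta_ecv(E: EcvMatrix, S, T) -> pd.Series:
    """|mean ECv over S - mean ECv over T| per edge (always >= 0).

    ``S`` and ``T`` are sample-identifier collections; singletons are fine.
    """
    S, T = list(S), list(T)
    if not S or not T:
        raise ValueError("sample groups S and T must be non-empty")
    mS = E.values.loc[S].mean(axis=0)
    mT = E.values.loc[T].mean(axis=0)
    return (mS - mT).abs()


@dataclass
class DeltaEcvTable:
    """Per-edge ΔECv, one column per comparison group (e.g. per cell line)."""

    values: pd.DataFrame  # index: edge ids, columns: group names
    groups: dict  # group name -> (S sample list, T sample list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("ΔECv values must be >= 0")
        for name, (S, T) in self.groups.items():
            if set(S) & set(T):
                raise ValueError(f"groups of comparison {name!r} overlap")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(parse_edge_id(e) for e in self.values.index)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("edge").to_csv(path, sep="\t")


def delta_ecv_table(E: EcvMatrix, groups: dict) -> DeltaEcvTable:
    """ΔECv for several group pairings, e.g. treated-vs-control per line.

    ``groups`` maps a comparison name to a ``(S, T)`` pair of sample lists.
    """
    cols = {name: delta_ecv(E, S, T) for name, (S, T) in groups.items()}
    return DeltaEcvTable(values=pd.DataFrame(cols), groups=dict(groups))


def condition_groups_by_line(X: ExpressionMatrix, condition_col: str = "condition",
                             line_col: str = "line",
                             treated: str = "treated",
                             control: str = "control") -> dict:
    """Build per-line (treated, control) sample groupings from annotations."""
    if X.annotations is None:
        raise ValueError("expression matrix carries no sample annotations")
    ann = X.annotations
    groups = {}
    for line in sorted(ann[line_col].unique()):
        sub = ann[ann[line_col] == line]
        S = sub.index[sub[condition_col] == treated].tolist()
        T = sub.index[sub[condition_col] == control].tolist()
        if S and T:
            groups[str(line)] = (S, T)
    return groups


def extract_differential_edges(table: DeltaEcvTable, threshold: float = 1.0,
                               mode: str = "all") -> pd.DataFrame:
    """Edges whose ΔECv exceeds ``threshold`` in every group (``mode='all'``,
    the conservative intersection rule) or in at least one (``mode='any'``).

    Returns the ΔECv sub-table of surviving edges (index: edge id), sorted by
    the minimum ΔECv across groups, descending.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    exceed = table.values > threshold
    keep = exceed.all(axis=1) if mode == "all" else exceed.any(axis=1)
    out = table.values[keep].copy()
    out = out.loc[out.min(axis=1).sort_values(ascending=False).index]
    return out


@dataclass
class TransferReport:
    """Accounting of an ECv transfer onto a cohort with partial gene overlap."""

    n_requested_edges: int
    computed_edges: tuple[tuple[str, str], ...]
    dropped_edges: tuple[tuple[str, str], ...]
    missing_genes: tuple[str, ...]
    n_shared_genes: int

    def to_dict(self) -> dict:
        return {
            "n_requested_edges": self.n_requested_edges,
            "n_computed_edges": len(self.computed_edges),
            "n_dropped_edges": len(self.dropped_edges),
            "dropped_edges": [edge_id(e) for e in self.dropped_edges],
            "missing_genes": list(self.missing_genes),
            "n_shared_genes": self.n_shared_genes,
        }


def transfer_ecv(models: ModelSet, newX: ExpressionMatrix, edges=None,
                 zscale: bool = False) -> tuple[EcvMatrix, TransferReport]:
    """Evaluate trained edge models on a new cohort (ECv transfer).

    An edge is computable iff both its parent and child genes are columns of
    ``newX``; the original training models are used unchanged and parent
    values are clamped to the training range. ``zscale`` optionally z-scores
    each shared gene of the new cohort first (off by default: the canonical
    workflow plugs the new values straight in).
    """
    requested = tuple(edges) if edges is not None else tuple(models.edges)
    new_genes = set(newX.genes)
    model_genes = {g for e in requested for g in e}
    shared = sorted(model_genes & new_genes)
    missing = tuple(sorted(model_genes - new_genes))
    computable = tuple(e for e in requested if e[0] in new_genes and e[1] in new_genes)
    dropped = tuple(e for e in requested if e not in set(computable))
    if not computable:
        raise ValueError("no transferable edges: cohort shares no complete edge")
    Xv = newX.values
    if zscale:
        Xv = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0, ddof=0).replace(0.0, 1.0)
    cols = {}
    for parent, child in computable:
        model = models[child]
        k = model.parents.index(parent) + 1
        cols[edge_id((parent, child))] = model.component_value(
            k, Xv[parent].to_numpy()
        )
    E = EcvMatrix(values=pd.DataFrame(cols, index=Xv.index), edges=computable,
                  provenance=models)
    report = TransferReport(
        n_requested_edges=len(requested),
        computed_edges=computable,
        dropped_edges=dropped,
        missing_genes=missing,
        n_shared_genes=len(shared),
    )
    return E, report


def ecv_edge_tests(E: EcvMatrix, S, T) -> pd.DataFrame:
    """Welch two-sample t-test of ECv between groups S and T per edge, with
    Benjamini-Hochberg adjustment across the tested edges.

    Returns a DataFrame indexed by edge id with columns t, p, q. Degenerate
    edges (zero variance in both groups) get p = 1 when the means agree and
    p = 0 when they differ.
    """
    S, T = list(S), list(T)
    if len(S) < 2 or len(T) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    A = E.values.loc[S].to_numpy()
    B = E.values.loc[T].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    # degenerate-variance guard
    varA, varB = A.var(axis=0), B.var(axis=0)
    degenerate = (varA == 0) & (varB == 0)
    same_mean = np.isclose(A.mean(axis=0), B.mean(axis=0))
    t = np.where(degenerate, np.where(same_mean, 0.0, np.inf), t)
    p = np.where(degenerate, np.where(same_mean, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=E.values.columns)
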
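"""Sample stratification by ECv pattern and survival comparison.

Samples (or edges) are clustered hierarchically with the ward.D2 convention:
Euclidean distances, squared inside the Lance-Williams update, merge heights
reported on the original distance scale. The resulting two patient groups
are compared with the standard two-group log-rank test and Kaplan-Meier
curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import SurvivalRecord


@dataclass
class ClusterResult:
    """Flat labels plus the merge tree from agglomerative clustering."""

    items: tuple[str, ...]
    labels: np.ndarray  # int labels 1..k, renumbered by first appearance
    linkage: np.ndarray  # scipy linkage matrix (merge heights in col 2)
    k: int

    def label_of(self, item: str) -> int:
        return int(self.labels[self.items.index(item)])

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, lab in zip(self.items, self.labels):
            out.setdefault(int(lab), []).append(item)
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame({"item": self.items, "cluster": self.labels}).to_csv(
            path, sep="\t", index=False
        )


def ward_cluster(matrix, k: int = 2, axis: str = "samples") -> ClusterResult:
    """Ward (ward.D2) agglomerative clustering of an items x features matrix.

    ``matrix`` may be an :class:`~ecvnet.ecv.EcvMatrix`, a DataFrame, or any
    numeric array; ``axis='features'`` clusters columns instead of rows.
    Labels are renumbered 1..k in order of first appearance, so they are
    deterministic for a fixed input.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else getattr(matrix, "values", matrix)
    if isinstance(values, pd.DataFrame):
        items = values.index if axis == "samples" else values.columns
        data = values.to_numpy(dtype=float)
    else:
        data = np.asarray(values, dtype=float)
        n_items = data.shape[0] if axis == "samples" else data.shape[1]
        items = pd.Index([str(i) for i in range(n_items)])
    if axis == "features":
        data = data.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    # scipy's 'ward' on raw observations is the ward.D2 convention: squared
    # Euclidean distances inside the recurrence, heights on the original scale
    Z = linkage(data, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel, labels = {}, np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return ClusterResult(items=tuple(str(i) for i in items), labels=labels,
                         linkage=Z, k=k)


def _two_group_arrays(records, labels):
    labs = list(labels)
    if len(labs) != len(records):
        raise ValueError("labels and records differ in length")
    uniq = sorted(set(labs))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    groups = []
    for u in uniq:
        idx = [i for i, l in enumerate(labs) if l == u]
        if not idx:
            raise ValueError(f"group {u} is empty")
        t = np.array([records[i].time for i in idx])
        e = np.array([records[i].event for i in idx])
        groups.append((t, e))
    return groups


def logrank_test(records, labels) -> tuple[float, float]:
    """Standard two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the pooled risk set; the
    squared standardized sum is referred to chi-square with 1 df. Subjects
    censored at an event time are counted in that time's risk set
    (censored-after-events convention).
    """
    (t1, e1), (t2, e2) = _two_group_arrays(records, labels)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        n = n1 + n2
        d1 = float(((t1 == t) & (e1 == 1)).sum())
        d2 = float(((t2 == t) & (e2 == 1)).sum())
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if V == 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def km_curve(records, labels) -> dict:
    """Kaplan-Meier product-limit curve per group.

    Returns {group label: (times, survival)} where both arrays start at
    (0, 1.0) and survival is non-increasing.
    """
    labs = list(labels)
    out = {}
    for u in sorted(set(labs)):
        idx = [i for i, l in enumerate(labs) if l == u]
        if not idx:
            raise ValueError(f"group {u} is empty")
        t = np.array([records[i].time for i in idx])
        e = np.array([records[i].event for i in idx])
        times = [0.0]
        surv = [1.0]
        s = 1.0
        for tt in np.unique(t[e == 1]):
            n_at_risk = float((t >= tt).sum())
            d = float(((t == tt) & (e == 1)).sum())
            s *= 1.0 - d / n_at_risk
            times.append(float(tt))
            surv.append(s)
        out[u] = (np.array(times), np.array(surv))
    return out


# ---------------------------------------------------------------------------
# survival-table I/O and cohort preprocessing


def read_survival_tsv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_days", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return [
        SurvivalRecord(sample=str(r.sample), time=float(r.time_days), event=int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival_tsv(records, path) -> None:
    pd.DataFrame(
        [(r.sample, r.time, r.event) for r in records],
        columns=["sample", "time_days", "event"],
    ).to_csv(path, sep="\t", index=False)


def filter_followup(records, max_days: float = 2000.0) -> list[SurvivalRecord]:
    """Drop subjects whose recorded follow-up exceeds ``max_days``."""
    return [r for r in records if r.time <= max_days]


def plot_km(records, labels, path) -> None:
    """Optional Kaplan-Meier step plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = km_curve(records, labels)
    chi2, p = logrank_test(records, labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for u, (t, s) in curves.items():
        ax.step(t, s, where="post", label=f"group {u}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(title=f"log-rank p = {p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
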
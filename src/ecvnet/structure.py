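"""Basal-network structure learning.

Three estimators share one decomposable score (the sum of per-child local
log marginal likelihoods from :mod:`ecvnet.local_model`):

* ``exhaustive_search`` — exact optimum over all DAGs for <= 5 genes, used
  as an oracle for the greedy search.
* ``greedy_hill_climb`` — add/delete/reverse hill climbing from the empty
  graph with acyclicity and parent-count constraints.
* ``nnsr_estimate`` — an iterated-subnetwork edge-frequency estimator in the
  spirit of neighbor-node-sampling-and-repeat: many times over, grow a small
  gene subset around a random seed gene by absolute-correlation-weighted
  sampling, learn a subnetwork on it greedily, and record which edges
  appear. Edge frequency = times estimated / times both endpoints were
  co-sampled. Thresholding the frequencies yields the basal network.

The thresholded union may contain cycles; that is deliberate. Everything
downstream (model fitting, ECv) only needs per-child parent sets, so global
acyclicity is not re-imposed after aggregation.

All randomness flows from one integer seed through iteration-indexed
substreams, so results are reproducible regardless of execution order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .local_model import ScoreConfig, local_log_score

_SCORE_TOL = 1e-9  # floats this close count as tied


@dataclass(frozen=True)
class BasalNetwork:
    """A directed gene network: the substrate of all ECv computation."""

    genes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # (parent, child)
    edge_freq: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        seen = set()
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop {p}->{c}")
            if (p, c) in seen:
                raise ValueError(f"duplicate edge {p}->{c}")
            if p not in gene_set or c not in gene_set:
                raise ValueError(f"edge {p}->{c} uses unknown gene")
            seen.add((p, c))

    def parents(self, gene: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == gene)

    @property
    def parent_map(self) -> dict[str, tuple[str, ...]]:
        pm = {g: [] for g in self.genes}
        for p, c in self.edges:
            pm[c].append(p)
        return {g: tuple(v) for g, v in pm.items()}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class EdgeFrequencyNetwork:
    """Per-edge estimation frequencies from the iterated-subnetwork run."""

    genes: tuple[str, ...]
    edge_freq: dict  # (parent, child) -> frequency in [0, 1]
    cosample_count: dict  # frozenset({a, b}) -> times co-sampled
    T_iter: int
    subset_size: int
    seed: int

    def __post_init__(self) -> None:
        for e, f in self.edge_freq.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency of {e} outside [0,1]: {f}")


class LocalScoreCache:
    """Memoized local scores for one expression matrix and config."""

    def __init__(self, X, cfg: ScoreConfig):
        self.X = X
        self.cfg = cfg
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def score(self, child: str, parents) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = local_log_score(self.X, child, key[1], self.cfg)
        return self._cache[key]


def _best_parent_subset(cache: LocalScoreCache, child: str, pool, max_parents: int):
    """Best-scoring parent subset from ``pool``; ties prefer fewer parents,
    then lexicographic order."""
    best_score, best_set = cache.score(child, ()), ()
    for size in range(1, min(max_parents, len(pool)) + 1):
        for combo in itertools.combinations(sorted(pool), size):
            s = cache.score(child, combo)
            if s > best_score + _SCORE_TOL:
                best_score, best_set = s, combo
    return best_score, best_set


def exhaustive_search(X, cfg: ScoreConfig | None = None, max_nodes: int = 5) -> BasalNetwork:
    """Exact highest-scoring DAG by enumeration over topological orders.

    Feasible only for small gene sets (the optimal-DAG problem is NP-hard);
    serves as the oracle the greedy search is validated against.
    """
    cfg = cfg or ScoreConfig()
    genes = tuple(X.genes)
    if len(genes) > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} genes, got {len(genes)}")
    cache = LocalScoreCache(X, cfg)
    best_total, best_edges = -np.inf, None
    memo: dict[tuple[str, tuple[str, ...]], tuple[float, tuple[str, ...]]] = {}
    for order in itertools.permutations(genes):
        total, edges = 0.0, []
        for i, child in enumerate(order):
            preds = tuple(sorted(order[:i]))
            key = (child, preds)
            if key not in memo:
                memo[key] = _best_parent_subset(cache, child, preds, cfg.max_parents)
            s, parents = memo[key]
            total += s
            edges.extend((p, child) for p in parents)
        edges = tuple(sorted(edges))
        if total > best_total + _SCORE_TOL or (
            abs(total - best_total) <= _SCORE_TOL
            and best_edges is not None
            and edges < best_edges
        ):
            best_total, best_edges = total, edges
    return BasalNetwork(genes=genes, edges=best_edges)


def _creates_cycle(parent_map: dict, src: str, dst: str) -> bool:
    """Would adding src -> dst close a cycle? (is src reachable from dst)"""
    stack, seen = [src], set()
    while stack:
        g = stack.pop()
        if g == dst:
            return True
        if g in seen:
            continue
        seen.add(g)
        stack.extend(parent_map[g])
    return False


def greedy_hill_climb(X, cfg: ScoreConfig | None = None, seed: int = 0,
                      genes=None, cache: LocalScoreCache | None = None) -> BasalNetwork:
    """Score hill climbing over add/delete/reverse moves from the empty graph.

    Deterministic: moves are enumerated in sorted order and the best strictly
    improving move is applied until none remains. ``genes`` restricts the
    search to a subset of the matrix's columns (used by ``nnsr_estimate``).
    """
    cfg = cfg or ScoreConfig()
    genes = tuple(sorted(genes if genes is not None else X.genes))
    cache = cache if cache is not None else LocalScoreCache(X, cfg)
    parent_map: dict[str, tuple[str, ...]] = {g: () for g in genes}
    child_score = {g: cache.score(g, ()) for g in genes}

    def with_parent(ps, p):
        return tuple(sorted(set(ps) | {p}))

    def without_parent(ps, p):
        return tuple(sorted(set(ps) - {p}))

    while True:
        best_delta, best_apply = _SCORE_TOL, None
        for p, c in itertools.permutations(genes, 2):
            if p in parent_map[c]:
                # delete p -> c
                new_ps = without_parent(parent_map[c], p)
                delta = cache.score(c, new_ps) - child_score[c]
                if delta > best_delta:
                    best_delta, best_apply = delta, ((c, new_ps),)
                # reverse p -> c into c -> p
                if len(parent_map[p]) < cfg.max_parents:
                    pm2 = dict(parent_map)
                    pm2[c] = new_ps
                    if not _creates_cycle(pm2, c, p):
                        ps_p = with_parent(parent_map[p], c)
                        delta = (
                            cache.score(c, new_ps) - child_score[c]
                            + cache.score(p, ps_p) - child_score[p]
                        )
                        if delta > best_delta:
                            best_delta = delta
                            best_apply = ((c, new_ps), (p, ps_p))
            else:
                # add p -> c
                if len(parent_map[c]) >= cfg.max_parents:
                    continue
                if _creates_cycle(parent_map, p, c):
                    continue
                new_ps = with_parent(parent_map[c], p)
                delta = cache.score(c, new_ps) - child_score[c]
                if delta > best_delta:
                    best_delta, best_apply = delta, ((c, new_ps),)
        if best_apply is None:
            break
        for child, ps in best_apply:
            parent_map[child] = ps
            child_score[child] = cache.score(child, ps)
    edges = tuple(sorted((p, c) for c, ps in parent_map.items() for p in ps))
    return BasalNetwork(genes=genes, edges=edges)


def nnsr_estimate(X, T_iter: int, subset_size: int,
                  cfg: ScoreConfig | None = None, seed: int = 0) -> EdgeFrequencyNetwork:
    """Iterated-subnetwork edge-frequency estimation.

    Each iteration samples a seed gene uniformly, grows a gene subset by
    absolute-Pearson-correlation-weighted sampling (genes strongly correlated
    with the current subset are preferentially recruited), learns a
    subnetwork on the subset by greedy hill climbing, and records its edges.
    The frequency of an edge is the fraction of subsets containing both its
    endpoints in which it was estimated.
    """
    cfg = cfg or ScoreConfig()
    if T_iter < 1:
        raise ValueError("T_iter must be >= 1")
    genes = tuple(X.genes)
    p = len(genes)
    if not 2 <= subset_size:
        raise ValueError("subset_size must be >= 2")
    subset_size = min(subset_size, p)
    V = X.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(V.T))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    cache = LocalScoreCache(X, cfg)
    edge_count: dict[tuple[str, str], int] = {}
    cosample: dict[frozenset, int] = {}
    for t in range(T_iter):
        rng = np.random.default_rng([seed, t])  # iteration-indexed substream
        members = [int(rng.integers(p))]
        in_set = np.zeros(p, dtype=bool)
        in_set[members[0]] = True
        while len(members) < subset_size:
            w = corr[:, members].mean(axis=1)
            w[in_set] = 0.0
            tot = w.sum()
            if tot <= 0:
                w = (~in_set).astype(float)
                tot = w.sum()
            nxt = int(rng.choice(p, p=w / tot))
            members.append(nxt)
            in_set[nxt] = True
        subset = [genes[i] for i in members]
        for a, b in itertools.combinations(sorted(subset), 2):
            key = frozenset((a, b))
            cosample[key] = cosample.get(key, 0) + 1
        subnet = greedy_hill_climb(X, cfg, seed=seed, genes=subset, cache=cache)
        for e in subnet.edges:
            edge_count[e] = edge_count.get(e, 0) + 1
    edge_freq = {
        e: cnt / cosample[frozenset(e)] for e, cnt in edge_count.items()
    }
    return EdgeFrequencyNetwork(
        genes=genes, edge_freq=edge_freq, cosample_count=cosample,
        T_iter=T_iter, subset_size=subset_size, seed=seed,
    )


def threshold_network(freq_net: EdgeFrequencyNetwork, cutoff: float) -> BasalNetwork:
    """Keep edges with frequency > cutoff; a bidirectional pair collapses to
    its higher-frequency direction (lexicographic on ties)."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    surviving = {e: f for e, f in freq_net.edge_freq.items() if f > cutoff}
    edges = []
    for e in sorted(surviving):
        rev = (e[1], e[0])
        if rev in surviving:
            f, fr = surviving[e], surviving[rev]
            if f < fr or (f == fr and rev < e):
                continue
        edges.append(e)
    return BasalNetwork(
        genes=freq_net.genes,
        edges=tuple(edges),
        edge_freq={e: surviving[e] for e in edges},
    )


def concordance(netA: BasalNetwork, netB: BasalNetwork) -> float:
    """Fraction of edges shared by two networks: |A ∩ B| / |A ∪ B|
    (direction-sensitive). Two empty networks count as fully concordant."""
    if set(netA.genes) != set(netB.genes):
        raise ValueError("networks are over different gene universes")
    A, B = set(netA.edges), set(netB.edges)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


# ---------------------------------------------------------------------------
# text I/O


def write_edge_freq_tsv(freq_net: EdgeFrequencyNetwork, path) -> None:
    rows = [
        (p, c, f, freq_net.cosample_count[frozenset((p, c))])
        for (p, c), f in sorted(freq_net.edge_freq.items())
    ]
    pd.DataFrame(rows, columns=["parent", "child", "frequency", "cosample_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_freq_tsv(path, genes, T_iter: int = 0, subset_size: int = 0,
                       seed: int = 0) -> EdgeFrequencyNetwork:
    df = pd.read_csv(path, sep="\t")
    edge_freq, cosample = {}, {}
    for row in df.itertuples(index=False):
        edge_freq[(row.parent, row.child)] = float(row.frequency)
        cosample[frozenset((row.parent, row.child))] = int(row.cosample_count)
    return EdgeFrequencyNetwork(
        genes=tuple(genes), edge_freq=edge_freq, cosample_count=cosample,
        T_iter=T_iter, subset_size=subset_size, seed=seed,
    )


def write_network_tsv(net: BasalNetwork, path) -> None:
    rows = [(p, c, net.edge_freq.get((p, c), "")) for p, c in sorted(net.edges)]
    pd.DataFrame(rows, columns=["parent", "child", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_network_tsv(path, genes=None) -> BasalNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = tuple(sorted((str(r.parent), str(r.child)) for r in df.itertuples(index=False)))
    freq = {}
    if "frequency" in df.columns:
        for r in df.itertuples(index=False):
            if pd.notna(r.frequency) and r.frequency != "":
                freq[(str(r.parent), str(r.child))] = float(r.frequency)
    if genes is None:
        genes = tuple(sorted({g for e in edges for g in e}))
    return BasalNetwork(genes=tuple(genes), edges=edges, edge_freq=freq)


def write_network_sif(net: BasalNetwork, path, relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for p, c in sorted(net.edges):
            fh.write(f"{p}\t{relation}\t{c}\n")
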
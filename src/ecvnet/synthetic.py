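"""Seeded generators of ground-truth networks, expression data, condition
perturbations, and survival outcomes.

The default design mirrors a small in vitro perturbation experiment: three
cell lines x two conditions (control / treated) x three replicates = 18
samples, with log2-scale expression values. Children are generated by
additive nonlinear parent->child functions plus Gaussian noise, sampled in
topological order.

Perturbations model a condition-induced change of a regulator: for each
designated ("perturbed") edge, the expression of its *parent* gene is
shifted by a fixed magnitude in the treated condition. The shift then
propagates to the child through the edge's function, so the edge's
contribution differs between conditions — the signal the ΔECv statistic is
designed to detect. (A shift applied to the edge function itself, with the
parent's distribution unchanged, would be absorbed into the child's
residual and be invisible to any contribution measure evaluated at the
observed parent values.)

All generators take one integer seed; nothing reads the clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

FUNCTION_FAMILIES = ("linear", "sigmoid", "sine", "quadratic")


def _edge_function(family: str, params: dict):
    a = params.get("a", 1.0)
    b = params.get("b", 1.0)
    c = params.get("c", 0.0)
    if family == "linear":
        return lambda x: a * (x - c)
    if family == "sigmoid":
        return lambda x: a / (1.0 + np.exp(-b * (x - c)))
    if family == "sine":
        return lambda x: a * np.sin(b * (x - c))
    if family == "quadratic":
        return lambda x: a * (x - c) ** 2
    raise ValueError(f"unknown function family {family!r}")


@dataclass
class GroundTruth:
    """A known data-generating system for testing the whole pipeline."""

    genes: tuple[str, ...]
    dag: tuple[tuple[str, str], ...]  # (parent, child), acyclic
    functions: dict  # edge -> {"family": str, params...}
    noise_sd: dict  # gene -> sigma > 0
    base_mean: dict  # gene -> baseline log2-scale level
    perturbed: dict  # edge -> shift magnitude (applied to the parent gene
    #                  in the treated condition)
    n_lines: int = 3
    n_conditions: int = 2
    n_replicates: int = 3
    line_sd: float = 0.2
    root_sd: float = 0.3  # exogenous sample-to-sample variability of roots
    seed: int = 0

    def __post_init__(self) -> None:
        edge_set = set(self.dag)
        if not set(self.perturbed) <= edge_set:
            raise ValueError("perturbed edges must be a subset of the dag")
        if any(s <= 0 for s in self.noise_sd.values()):
            raise ValueError("all noise standard deviations must be > 0")
        order = topological_order(self.genes, self.dag)  # raises on cycles
        self._topo = order

    @property
    def perturbed_parents(self) -> set[str]:
        return {p for p, _ in self.perturbed}

    def to_json(self, path=None) -> str:
        doc = {
            "genes": list(self.genes),
            "dag": [list(e) for e in self.dag],
            "functions": {f"{p}\t{c}": d for (p, c), d in self.functions.items()},
            "noise_sd": self.noise_sd,
            "base_mean": self.base_mean,
            "perturbed": {f"{p}\t{c}": s for (p, c), s in self.perturbed.items()},
            "design": [self.n_lines, self.n_conditions, self.n_replicates],
            "line_sd": self.line_sd,
            "root_sd": self.root_sd,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            genes=tuple(doc["genes"]),
            dag=tuple(tuple(e) for e in doc["dag"]),
            functions={tuple(k.split("\t")): v for k, v in doc["functions"].items()},
            noise_sd=doc["noise_sd"],
            base_mean=doc["base_mean"],
            perturbed={tuple(k.split("\t")): v for k, v in doc["perturbed"].items()},
            n_lines=doc["design"][0],
            n_conditions=doc["design"][1],
            n_replicates=doc["design"][2],
            line_sd=doc["line_sd"],
            root_sd=doc.get("root_sd", 0.3),
            seed=doc["seed"],
        )


def topological_order(genes, edges):
    """Kahn's algorithm; raises on cycles."""
    genes = list(genes)
    indeg = {g: 0 for g in genes}
    children = {g: [] for g in genes}
    for p, c in edges:
        indeg[c] += 1
        children[p].append(c)
    ready = sorted(g for g in genes if indeg[g] == 0)
    order = []
    while ready:
        g = ready.pop(0)
        order.append(g)
        newly = []
        for c in children[g]:
            indeg[c] -= 1
            if indeg[c] == 0:
                newly.append(c)
        ready = sorted(ready + newly)
    if len(order) != len(genes):
        raise ValueError("graph contains a cycle")
    return order


def random_dag(p: int, max_parents: int = 3, edge_prob: float = 0.25,
               seed: int = 0) -> tuple[tuple[str, str], ...]:
    """Random DAG over genes g00..g{p-1}: edges go from lower to higher
    topological index, then gene labels are shuffled."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(p)  # label shuffle keeps index order != name order
    names = [f"g{perm[i]:02d}" for i in range(p)]
    edges = []
    for j in range(1, p):
        candidates = [i for i in range(j) if rng.random() < edge_prob]
        if len(candidates) > max_parents:
            candidates = list(rng.choice(candidates, size=max_parents, replace=False))
        for i in sorted(candidates):
            edges.append((names[i], names[j]))
    return tuple(sorted(edges))


def random_ground_truth(p: int = 10, max_parents: int = 3, edge_prob: float = 0.3,
                        n_perturbed: int = 3, shift: float = 2.0,
                        noise_sd: float = 0.3, root_sd: float = 0.3,
                        gain: float = 1.0, seed: int = 0,
                        n_lines: int = 3, n_conditions: int = 2,
                        n_replicates: int = 3) -> GroundTruth:
    """Random network with random edge functions and a planted perturbation.

    Each planted perturbation gets a dedicated regulator -> target pair: the
    regulator is made a root gene, the target's only parent is the
    regulator, and the edge function is linear with near-unit slope, so a
    regulator shift of ``shift`` moves the edge's contribution by about the
    same amount. Background edges get damped functions (absolute slope well
    below 1) so the perturbation does not cascade downstream at full
    strength — mirroring the empirical pattern that a condition affects a
    handful of regulators strongly and the rest of the network weakly.
    """
    rng = np.random.default_rng(seed)
    dag = random_dag(p, max_parents, edge_prob, seed)
    genes = tuple(sorted({g for e in dag for g in e} | {f"g{i:02d}" for i in range(p)}))
    if 2 * n_perturbed > p:
        raise ValueError("need at least 2 genes per planted perturbation")

    # carve out regulator/target pairs: regulators lose incoming edges,
    # targets keep exactly the planted edge as their only incoming edge
    special = [genes[i] for i in rng.permutation(len(genes))[: 2 * n_perturbed]]
    regulators, targets = special[:n_perturbed], special[n_perturbed:]
    edges = set(dag)
    for r in regulators:
        edges -= {e for e in edges if e[1] == r}
    chosen = []
    for r, c in zip(regulators, targets):
        edges -= {e for e in edges if e[1] == c}
        edges.add((r, c))
        chosen.append((r, c))
    dag = tuple(sorted(edges))

    functions = {}
    for e in dag:
        if e in chosen:
            functions[e] = {"family": "linear",
                            "a": float(rng.uniform(0.9, 1.1)), "c": 8.0}
        else:
            fam = FUNCTION_FAMILIES[rng.integers(len(FUNCTION_FAMILIES))]
            # background gain kept under ~1/3 of the planted unit slope so a
            # perturbation cascades downstream at well below threshold level
            if fam == "linear":
                params = {"a": float(rng.uniform(0.2, 0.35) * rng.choice([-1, 1])), "c": 8.0}
            elif fam == "sigmoid":  # max slope a*b/4 <= 0.3
                params = {"a": float(rng.uniform(0.8, 1.2)),
                          "b": float(rng.uniform(0.6, 1.0)), "c": 8.0}
            elif fam == "sine":
                params = {"a": float(rng.uniform(0.3, 0.6)),
                          "b": float(rng.uniform(0.7, 1.0)), "c": 8.0}
            else:  # quadratic
                params = {"a": float(rng.uniform(0.02, 0.04) * rng.choice([-1, 1])), "c": 8.0}
            params["a"] = float(params["a"] * gain)
            functions[e] = {"family": fam, **params}
    return GroundTruth(
        genes=genes,
        dag=dag,
        functions=functions,
        noise_sd={g: noise_sd for g in genes},
        base_mean={g: float(rng.uniform(6.0, 10.0)) for g in genes},
        perturbed={e: shift for e in chosen},
        n_lines=n_lines, n_conditions=n_conditions, n_replicates=n_replicates,
        root_sd=root_sd, seed=seed,
    )


CONDITIONS = ("control", "treated")


def simulate_expression(gt: GroundTruth, n_per_cell: int | None = None,
                        seed: int = 0) -> ExpressionMatrix:
    """Ancestral sampling from the ground truth over the full design.

    Returns a samples x genes matrix with annotations ``condition`` and
    ``line``. ``n_per_cell`` overrides the ground truth's replicate count.
    In the treated condition, parents of perturbed edges are shifted by the
    planted magnitude before their children are generated, so the
    perturbation propagates downstream.
    """
    R = n_per_cell if n_per_cell is not None else gt.n_replicates
    rng = np.random.default_rng(seed)
    order = topological_order(gt.genes, gt.dag)
    parents_of = {g: [(p, gt.functions[(p, g)]) for p, c in gt.dag if c == g]
                  for g in gt.genes}
    # a perturbed edge shifts its parent gene; one shift per gene
    shift_of = {p: s for (p, _c), s in gt.perturbed.items()}
    line_eff = {
        (l, g): float(rng.normal(0.0, gt.line_sd))
        for l in range(gt.n_lines) for g in gt.genes
    }
    rows, names, conds, lines = [], [], [], []
    for l in range(gt.n_lines):
        for ci in range(min(gt.n_conditions, 2)):
            cond = CONDITIONS[ci]
            for r in range(R):
                vals: dict[str, float] = {}
                for g in order:
                    ps = parents_of[g]
                    if not ps:
                        # roots carry exogenous biological variability on top
                        # of the shared noise term
                        v = gt.base_mean[g] + rng.normal(0.0, gt.root_sd)
                    else:
                        v = gt.base_mean[g] + sum(
                            _edge_function(d["family"], d)(vals[p]) for p, d in ps
                        )
                    v += line_eff[(l, g)] + rng.normal(0.0, gt.noise_sd[g])
                    if cond == "treated" and g in shift_of:
                        v += shift_of[g]
                    vals[g] = v
                rows.append([vals[g] for g in gt.genes])
                names.append(f"L{l+1}_{cond}_R{r+1}")
                conds.append(cond)
                lines.append(f"L{l+1}")
    values = pd.DataFrame(rows, index=names, columns=list(gt.genes))
    ann = pd.DataFrame({"condition": conds, "line": lines}, index=names)
    return ExpressionMatrix(values, ann)


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in days and event flag (1 = deceased)."""

    sample: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def simulate_survival(group_labels, baseline_hazard: float = 1e-3,
                      hazard_ratio: float = 2.0, censor_rate: float = 0.0,
                      seed: int = 0) -> list[SurvivalRecord]:
    """Exponential survival with a group-dependent hazard.

    Group 0 has hazard ``baseline_hazard``; any other group has
    ``baseline_hazard * hazard_ratio``. Censoring times are independent
    exponentials with rate ``censor_rate`` (0 = no censoring).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    labels = np.asarray(list(group_labels))
    rng = np.random.default_rng(seed)
    records = []
    for i, lab in enumerate(labels):
        h = baseline_hazard * (hazard_ratio if lab not in (0, "0") else 1.0)
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate)
        else:
            t_cens = np.inf
        t = min(t_event, t_cens)
        records.append(SurvivalRecord(sample=f"P{i:04d}", time=float(t),
                                      event=int(t_event <= t_cens)))
    return records
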
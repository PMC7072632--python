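# ecvnet

Sample-specific edge contributions in nonparametric Bayesian gene networks:
differential subnetwork extraction and cohort stratification.

## The problem

Gene-network estimation from expression data yields hundreds of thousands of
putative regulatory edges, and with only a handful of samples per condition
(e.g. three replicates of control and treated cells) it is impossible to
estimate a separate network per condition and compare structures. `ecvnet`
takes the opposite route: estimate **one** network from all samples, then
quantify how much each edge contributes to each individual sample, and
compare those per-sample contributions between conditions. This extracts a
condition-differential subnetwork from a large basal network even when each
condition has as few as one sample, and the trained edge models can be
re-evaluated on an entirely new cohort (e.g. tumor RNA-seq) to stratify
patients by their network state.

## The model

Expression is modeled as a Bayesian network whose local conditional
distributions are additive B-spline regressions. For child gene *j* with
parents pa<sub>1</sub>…pa<sub>q</sub>,

x<sub>ij</sub> = m<sub>1</sub><sup>(j)</sup>(pa<sub>i1</sub>) + … +
m<sub>q</sub><sup>(j)</sup>(pa<sub>iq</sub>) + ε<sub>j</sub>,  ε<sub>j</sub> ~
N(0, σ<sub>j</sub>²),

where each m<sub>k</sub><sup>(j)</sup>(x) = Σ<sub>l</sub>
γ<sub>lk</sub><sup>(j)</sup> b<sub>lk</sub><sup>(j)</sup>(x) is a cubic
B-spline expansion (M = 20 basis functions spanning the observed range of
the parent). Parent sets are scored by a penalized log marginal likelihood
and the structure is searched greedily; for genome-scale inputs, an
iterated-subnetwork estimator repeatedly learns small subnetworks on
correlation-sampled gene subsets and aggregates per-edge estimation
frequencies, which are thresholded (default 0.1) into the **basal network**.

The **Edge Contribution value** of edge j<sub>k</sub>→j in sample *i* is

ECv<sup>(i)</sup>(j<sub>k</sub>→j) = m<sub>k</sub><sup>(j)</sup>(pa<sub>ik</sub><sup>(j)</sup>),

the fitted contribution of that parent to the child's expression in that
sample. **ΔECv** is the absolute difference of mean ECv between two sample
groups; edges with ΔECv above a threshold (default 1.0, i.e. a two-fold
change on log2 data) in every comparison group form the differential edge
set, which is assembled into a subnetwork together with the basal edges
connecting its genes. Transferred ECv profiles of a new cohort are clustered
(ward.D2 / Euclidean) and the resulting groups compared with a log-rank
survival test.

## Worked example

Simulate the default benchmark — ten genes, three cell lines × two
conditions × three replicates, with three planted regulator→target
perturbations of magnitude 2 — then fit the network models, compute the ECv
matrix, and extract the differential edges:

```python
from ecvnet import (random_ground_truth, simulate_expression, fit_all_models,
                    BasalNetwork, ScoreConfig, compute_ecv_matrix)
from ecvnet.ecv import (condition_groups_by_line, delta_ecv_table,
                        extract_differential_edges)

gt = random_ground_truth(p=10, seed=1001)
X = simulate_expression(gt, seed=2001)
print("planted edges:", sorted(f"{p}->{c}" for p, c in gt.perturbed))

models = fit_all_models(X, BasalNetwork(genes=gt.genes, edges=gt.dag),
                        ScoreConfig())
E = compute_ecv_matrix(models, X)
table = delta_ecv_table(E, condition_groups_by_line(X))
print(extract_differential_edges(table, threshold=1.0, mode="all").round(2))
```

Output:

```
planted edges: ['g01->g05', 'g07->g06', 'g09->g04']
           L1    L2    L3
g01→g05  2.22  1.64  2.34
g09→g04  1.33  1.87  1.63
g07→g06  2.07  1.77  1.10
```

Exactly the three planted edges exceed ΔECv 1.0 in all three lines: their
regulators were shifted by 2 in the treated condition and the near-unit-slope
edge functions carry that shift into the edge contributions, while unshifted
edges stay near 0.

The same workflow is scriptable from the shell (`ecvnet simulate`,
`ecvnet estimate`, `ecvnet ecv`, `ecvnet delta`, `ecvnet extract`,
`ecvnet subnet`, `ecvnet transfer`, `ecvnet cluster`, `ecvnet survival`) or
driven end to end from a YAML config with `ecvnet run -c config.yaml`, which
writes every intermediate (edge frequencies, basal network, models, ECv and
ΔECv tables, subnetwork SIF/GraphML, cluster labels, survival test) plus a
run manifest to an artifact directory.

## Layout

- `src/ecvnet/splines.py` — clamped cubic B-spline bases
- `src/ecvnet/local_model.py` — penalized additive regression, scoring, model sets
- `src/ecvnet/structure.py` — exact/greedy/iterated-frequency structure search
- `src/ecvnet/ecv.py` — ECv matrices, ΔECv, extraction, transfer, edge tests
- `src/ecvnet/subnetwork.py` — subnetwork assembly, hubs, components, export
- `src/ecvnet/cohort.py` — ward.D2 clustering, log-rank, Kaplan-Meier
- `src/ecvnet/synthetic.py` — seeded ground-truth and cohort generators
- `src/ecvnet/data.py`, `src/ecvnet/workflow.py`, `src/ecvnet/cli.py` — I/O,
  pipeline, command line

See `docs/methods.md` for the modeling choices and their rationale.
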
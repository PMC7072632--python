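"""Config-driven end-to-end pipeline.

Stages (each optional pieces of one run):

    simulate/load -> estimate (edge frequencies + threshold) -> fit models
    -> ECv matrix -> ΔECv per line -> extract differential edges
    -> subnetwork assembly -> edge t-tests -> [transfer to cohort]
    -> cluster samples -> survival comparison

Every intermediate is written as plain text (TSV / SIF / GraphML / JSON) in
the artifact directory, plus a run manifest recording the seed, parameters
and library versions. Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (logrank_test, read_survival_tsv, ward_cluster,
                     write_survival_tsv)
from .data import (ExpressionMatrix, filter_genes_by_mean_percentile,
                   read_expression, write_annotations, write_expression)
from .ecv import (compute_ecv_matrix, condition_groups_by_line,
                  delta_ecv_table, ecv_edge_tests, edge_id,
                  extract_differential_edges, parse_edge_id, transfer_ecv)
from .local_model import ModelSet, ScoreConfig, fit_all_models
from .structure import (nnsr_estimate, threshold_network, write_edge_freq_tsv,
                        write_network_sif, write_network_tsv)
from .subnetwork import (build_subnetwork, components, hub_nodes,
                         write_subnetwork_graphml, write_subnetwork_sif,
                         write_subnetwork_tsv)
from .synthetic import random_ground_truth, simulate_expression, simulate_survival

DEFAULT_CONFIG = {
    "seed": 0,
    # data: either "expression" (+ optional "annotations") paths, or synthetic
    "expression": None,
    "annotations": None,
    "orientation": "genes_in_columns",
    "log2_transform": False,
    "mean_percentile_filter": 0.0,
    "synthetic": None,  # dict of random_ground_truth kwargs to simulate
    # structure estimation
    "iterations": 200,
    "subset_size": 6,
    "cutoff": 0.1,
    # local models
    "M": 20,
    "lambda_grid": [0.1, 1.0, 10.0, 100.0],
    "max_parents": 3,
    # differential extraction
    "delta_threshold": 1.0,
    "delta_mode": "all",
    # subnetwork
    "hub_fraction": 0.05,
    # optional transfer + survival
    "transfer_expression": None,
    "survival": None,  # TSV path, or "simulate" with synthetic cohorts
    "cluster_k": 2,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(source) -> dict:
    """Merge a YAML file or dict over the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _score_config(cfg: dict) -> ScoreConfig:
    return ScoreConfig(M=int(cfg["M"]),
                       lambda_grid=tuple(float(x) for x in cfg["lambda_grid"]),
                       max_parents=int(cfg["max_parents"]))


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return run
    return wrap


def run_pipeline(config=None, outdir="ecvnet_run") -> Path:
    """Execute the configured stages and write all artifacts to ``outdir``."""
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    scfg = _score_config(cfg)

    X = _stage("data")(_load_data)(cfg, out, seed)
    basal, freq_net = _stage("estimate")(_estimate)(X, cfg, scfg, out, seed)
    models = _stage("models")(_fit_models)(X, basal, scfg, out)
    E = _stage("ecv")(lambda: compute_ecv_matrix(models, X))()
    E.to_tsv(out / "ecv_matrix.tsv")
    extracted, table = _stage("delta_extract")(_delta_extract)(X, E, cfg, out)
    _stage("subnetwork")(_subnetwork)(basal, extracted, table, cfg, out)
    _stage("edge_tests")(_edge_tests)(X, E, out)
    Et = _stage("transfer")(_transfer)(models, extracted, cfg, out)
    _stage("cluster_survival")(_cluster_survival)(Et if Et is not None else E, cfg, out, seed)
    _stage("manifest")(_manifest)(cfg, out)
    return out


def _load_data(cfg, out, seed):
    if cfg["synthetic"] is not None:
        syn = dict(cfg["synthetic"])
        gt = random_ground_truth(seed=seed, **syn)
        gt.to_json(out / "ground_truth.json")
        X = simulate_expression(gt, seed=seed + 1)
    elif cfg["expression"] is not None:
        X = read_expression(cfg["expression"], orientation=cfg["orientation"],
                            log2=bool(cfg["log2_transform"]),
                            annotations=cfg["annotations"])
    else:
        raise ValueError("config must set either 'expression' or 'synthetic'")
    if cfg["mean_percentile_filter"]:
        X = filter_genes_by_mean_percentile(X, float(cfg["mean_percentile_filter"]))
    write_expression(X, out / "expression.tsv", orientation="genes_in_rows")
    if X.annotations is not None:
        write_annotations(X, out / "sample_annotations.tsv")
    return X


def _estimate(X, cfg, scfg, out, seed):
    freq_net = nnsr_estimate(X, T_iter=int(cfg["iterations"]),
                             subset_size=int(cfg["subset_size"]),
                             cfg=scfg, seed=seed)
    write_edge_freq_tsv(freq_net, out / "edge_frequencies.tsv")
    basal = threshold_network(freq_net, float(cfg["cutoff"]))
    write_network_tsv(basal, out / "basal_network.tsv")
    write_network_sif(basal, out / "basal_network.sif")
    return basal, freq_net


def _fit_models(X, basal, scfg, out):
    models = fit_all_models(X, basal, scfg)
    models.to_json(out / "models.json")
    return models


def _delta_extract(X, E, cfg, out):
    groups = condition_groups_by_line(X) if X.annotations is not None else {}
    if not groups:
        return None, None
    table = delta_ecv_table(E, groups)
    table.to_tsv(out / "delta_ecv.tsv")
    extracted_df = extract_differential_edges(table, float(cfg["delta_threshold"]),
                                              cfg["delta_mode"])
    extracted_df.rename_axis("edge").to_csv(out / "extracted_edges.tsv", sep="\t")
    report = {
        "threshold": float(cfg["delta_threshold"]),
        "mode": cfg["delta_mode"],
        "n_edges_tested": int(table.values.shape[0]),
        "n_edges_extracted": int(extracted_df.shape[0]),
        "groups": sorted(table.groups),
    }
    (out / "extraction_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return [parse_edge_id(e) for e in extracted_df.index], table


def _subnetwork(basal, extracted, table, cfg, out):
    if not extracted:
        return
    delta = {
        parse_edge_id(eid): row.to_dict()
        for eid, row in table.values.iterrows()
        if parse_edge_id(eid) in set(extracted)
    }
    net = build_subnetwork(basal, extracted, delta=delta)
    write_subnetwork_tsv(net, out / "subnetwork.tsv")
    write_subnetwork_sif(net, out / "subnetwork.sif")
    write_subnetwork_graphml(net, out / "subnetwork.graphml",
                             hub_fraction=float(cfg["hub_fraction"]))
    hubs = hub_nodes(net, float(cfg["hub_fraction"]))
    comps = components(net)
    summary = {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_extracted": net.n_extracted,
        "n_basal_fill": net.n_fill,
        "hubs": hubs,
        "component_sizes": [len(c) for c in comps],
    }
    (out / "subnetwork_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def _edge_tests(X, E, out):
    if X.annotations is None or "condition" not in X.annotations.columns:
        return
    ann = X.annotations
    S = ann.index[ann["condition"] == "treated"].tolist()
    T = ann.index[ann["condition"] == "control"].tolist()
    if len(S) < 2 or len(T) < 2:
        return
    ecv_edge_tests(E, S, T).rename_axis("edge").to_csv(out / "edge_tests.tsv", sep="\t")


def _transfer(models, extracted, cfg, out):
    if cfg["transfer_expression"] is None:
        return None
    newX = read_expression(cfg["transfer_expression"], orientation=cfg["orientation"],
                           log2=bool(cfg["log2_transform"]))
    Et, report = transfer_ecv(models, newX, edges=extracted or None)
    Et.to_tsv(out / "transfer_ecv_matrix.tsv")
    (out / "transfer_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True)
    )
    return Et


def _cluster_survival(E, cfg, out, seed):
    if cfg["survival"] is None:
        return
    res = ward_cluster(E, k=int(cfg["cluster_k"]), axis="samples")
    res.to_tsv(out / "cluster_labels.tsv")
    if cfg["survival"] == "simulate":
        records = simulate_survival(res.labels - 1, seed=seed + 2)
        records = [r.__class__(sample=s, time=r.time, event=r.event)
                   for r, s in zip(records, res.items)]
        write_survival_tsv(records, out / "survival.tsv")
    else:
        records = read_survival_tsv(cfg["survival"])
        by_sample = {r.sample: r for r in records}
        missing = [s for s in res.items if s not in by_sample]
        if missing:
            raise ValueError(f"no survival record for samples {missing[:5]}...")
        records = [by_sample[s] for s in res.items]
    chi2, p = logrank_test(records, res.labels.tolist())
    (out / "survival_test.json").write_text(
        json.dumps({"logrank_chi2": chi2, "logrank_p": p,
                    "group_sizes": {str(k): len(v) for k, v in res.groups().items()}},
                   indent=1, sort_keys=True)
    )


def _manifest(cfg, out):
    import networkx
    import scipy
    manifest = {
        "config": {k: v for k, v in sorted(cfg.items())},
        "versions": {
            "ecvnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
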
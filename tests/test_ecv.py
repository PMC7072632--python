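import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecvnet.ecv import (DeltaEcvTable, EcvMatrix, compute_ecv_matrix,
                        condition_groups_by_line, delta_ecv, delta_ecv_table,
                        ecv_edge_tests, edge_id, extract_differential_edges,
                        parse_edge_id, transfer_ecv)
from ecvnet.data import ExpressionMatrix
from ecvnet.local_model import ScoreConfig, fit_all_models
from ecvnet.structure import BasalNetwork
from ecvnet.synthetic import (random_ground_truth, simulate_expression)

from conftest import make_matrix


@pytest.fixture(scope="module")
def chain_models():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 3, 100)
    b = 2.0 * a
    c = 0.5 * b + rng.normal(0, 0.1, 100)
    X = make_matrix({"a": a, "b": b, "c": c})
    net = BasalNetwork(genes=("a", "b", "c"), edges=(("a", "b"), ("b", "c")))
    return X, fit_all_models(X, net, ScoreConfig())


class TestEcvMatrix:
    def test_shape_and_column_order(self, chain_models):
        X, models = chain_models
        E = compute_ecv_matrix(models, X)
        assert (E.n, E.m) == (100, 2)
        assert list(E.values.columns) == [edge_id(e) for e in models.edges]

    def test_matches_direct_component_evaluation(self, chain_models):
        X, models = chain_models
        E = compute_ecv_matrix(models, X)
        m_b = models["b"]
        direct = m_b.component_value(1, X.gene("a"))
        np.testing.assert_array_equal(E.values[edge_id(("a", "b"))].to_numpy(), direct)

    def test_noise_free_linear_edge_value(self, chain_models):
        X, models = chain_models
        # b = 2a exactly, so the a->b contribution at a=0.5 is 1.0
        assert models["b"].component_value(1, 0.5) == pytest.approx(1.0, abs=1e-6)

    def test_missing_parent_gene_points_to_transfer(self, chain_models):
        _, models = chain_models
        bad = make_matrix({"a": np.linspace(0, 1, 5)})
        with pytest.raises(KeyError, match="transfer_ecv"):
            compute_ecv_matrix(models, bad)

    def test_tsv_round_trip(self, chain_models, tmp_path):
        X, models = chain_models
        E = compute_ecv_matrix(models, X)
        path = tmp_path / "ecv.tsv"
        E.to_tsv(path)
        back = EcvMatrix.from_tsv(path)
        assert back.edges == E.edges
        np.testing.assert_allclose(back.values.to_numpy(), E.values.to_numpy())


def _toy_ecv(values: dict, samples) -> EcvMatrix:
    edges = tuple(parse_edge_id(c) for c in values)
    return EcvMatrix(values=pd.DataFrame(values, index=samples), edges=edges)


class TestDeltaEcv:
    def test_identical_groups_give_zero(self):
        E = _toy_ecv({"a→b": [1.0, 2.0, 3.0]}, ["s0", "s1", "s2"])
        d = delta_ecv(E, ["s0", "s1"], ["s0", "s1"])
        assert d["a→b"] == 0.0

    def test_singleton_groups_arithmetic(self):
        E = _toy_ecv({"a→b": [2.0, 0.5]}, ["s0", "s1"])
        assert delta_ecv(E, ["s0"], ["s1"])["a→b"] == pytest.approx(1.5)

    def test_empty_group_rejected(self):
        E = _toy_ecv({"a→b": [1.0, 2.0]}, ["s0", "s1"])
        with pytest.raises(ValueError):
            delta_ecv(E, [], ["s0"])

    @given(st.floats(min_value=-50, max_value=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance(self, c):
        # adding a constant to an edge's ECv in every sample leaves ΔECv intact
        base = np.array([1.0, 4.0, 2.0, 0.5])
        E1 = _toy_ecv({"a→b": base}, list("wxyz"))
        E2 = _toy_ecv({"a→b": base + c}, list("wxyz"))
        d1 = delta_ecv(E1, ["w", "x"], ["y", "z"])
        d2 = delta_ecv(E2, ["w", "x"], ["y", "z"])
        assert d1["a→b"] == pytest.approx(d2["a→b"], abs=1e-9)

    def test_delta_always_nonnegative(self):
        rng = np.random.default_rng(0)
        E = _toy_ecv({f"g{i}→h{i}": rng.normal(0, 3, 6) for i in range(10)},
                     [f"s{i}" for i in range(6)])
        d = delta_ecv(E, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (d >= 0).all()


class TestExtraction:
    def _table(self):
        vals = pd.DataFrame(
            {"L1": [1.2, 1.2, 0.4], "L2": [1.1, 0.9, 0.2], "L3": [1.3, 1.3, 0.1]},
            index=["a→b", "c→d", "e→f"],
        )
        return DeltaEcvTable(values=vals, groups={g: ([], []) for g in vals.columns})

    def test_mode_all_requires_every_group(self):
        kept = extract_differential_edges(self._table(), 1.0, "all")
        assert list(kept.index) == ["a→b"]

    def test_mode_any_takes_union(self):
        kept = extract_differential_edges(self._table(), 1.0, "any")
        assert set(kept.index) == {"a→b", "c→d"}

    def test_nothing_above_threshold(self):
        assert extract_differential_edges(self._table(), 5.0, "all").empty

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            extract_differential_edges(self._table(), 0.0, "all")
        with pytest.raises(ValueError):
            extract_differential_edges(self._table(), 1.0, "most")


class TestPlantedPerturbationRecovery:
    def test_perturbed_edges_rank_top3_by_min_line_delta(self):
        """Across seeded replicates of the 3-line x 2-condition x 3-replicate
        design, the three planted regulator->target edges carry the three
        largest min-over-lines ΔECv values."""
        hits = 0
        reps = 25
        for s in range(reps):
            gt = random_ground_truth(p=10, seed=1000 + s)
            X = simulate_expression(gt, seed=2000 + s)
            models = fit_all_models(X, BasalNetwork(genes=gt.genes, edges=gt.dag),
                                    ScoreConfig())
            E = compute_ecv_matrix(models, X)
            table = delta_ecv_table(E, condition_groups_by_line(X))
            ranked = table.values.min(axis=1).sort_values(ascending=False)
            hits += set(ranked.index[:3]) == {edge_id(e) for e in gt.perturbed}
        assert hits >= 0.9 * reps

    def test_unperturbed_deltas_concentrate_versus_log2fc(self):
        """Background-edge ΔECv stays near zero while per-gene expression
        fold changes spread much wider on the same simulation."""
        gt = random_ground_truth(p=10, seed=1234)
        X = simulate_expression(gt, seed=1235)
        models = fit_all_models(X, BasalNetwork(genes=gt.genes, edges=gt.dag),
                                ScoreConfig())
        E = compute_ecv_matrix(models, X)
        table = delta_ecv_table(E, condition_groups_by_line(X))
        planted = {edge_id(e) for e in gt.perturbed}
        bg = table.values.min(axis=1).drop(index=[e for e in planted
                                                  if e in table.values.index])
        ann = X.annotations
        treated = X.values.loc[ann.condition == "treated"].mean()
        control = X.values.loc[ann.condition == "control"].mean()
        log2fc = (treated - control).abs()
        assert bg.quantile(0.9) < log2fc.quantile(0.9)


class TestTransfer:
    def test_full_gene_cohort_matches_direct_computation(self, chain_models):
        X, models = chain_models
        E = compute_ecv_matrix(models, X)
        Et, report = transfer_ecv(models, X)
        assert Et.edges == E.edges
        np.testing.assert_array_equal(Et.values.to_numpy(), E.values.to_numpy())
        assert report.dropped_edges == ()
        assert report.missing_genes == ()

    def test_missing_parent_drops_exactly_its_edges(self, chain_models):
        X, models = chain_models
        partial = ExpressionMatrix(X.values[["b", "c"]].copy())
        Et, report = transfer_ecv(models, partial)
        assert Et.edges == (("b", "c"),)
        assert report.dropped_edges == (("a", "b"),)
        assert report.missing_genes == ("a",)
        assert report.n_shared_genes == 2

    def test_out_of_range_values_clamped_to_training_boundary(self, chain_models):
        X, models = chain_models
        hi = X.gene("a").max()
        wild = make_matrix({"a": np.array([hi + 10.0]), "b": np.array([0.0]),
                            "c": np.array([0.0])}, prefix="p")
        Et, _ = transfer_ecv(models, wild)
        expected = models["b"].component_value(1, hi)
        assert Et.values.iloc[0][edge_id(("a", "b"))] == pytest.approx(expected)

    def test_no_transferable_edges_rejected(self, chain_models):
        _, models = chain_models
        alien = make_matrix({"zz": np.linspace(0, 1, 4)})
        with pytest.raises(ValueError):
            transfer_ecv(models, alien)


class TestEdgeTests:
    def test_identical_groups_give_p_one(self):
        E = _toy_ecv({"a→b": [1.0, 2.0, 1.0, 2.0]}, list("wxyz"))
        res = ecv_edge_tests(E, ["w", "x"], ["y", "z"])
        assert res.loc["a→b", "p"] == pytest.approx(1.0)
        assert res.loc["a→b", "q"] == pytest.approx(1.0)

    def test_benjamini_hochberg_step_up_hand_example(self):
        # q_i = min_{j>=i} p_(j) * m / j computed by hand:
        # (0.01, 0.02, 0.03, 0.5) -> (0.04, 0.04, 0.04, 0.5)
        # checks the adjustment ecv_edge_tests delegates to
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_degenerate_variance_guard(self):
        E = _toy_ecv({"a→b": [1.0, 1.0, 2.0, 2.0], "c→d": [3.0, 3.0, 3.0, 3.0]},
                     list("wxyz"))
        res = ecv_edge_tests(E, ["w", "x"], ["y", "z"])
        assert res.loc["a→b", "p"] == 0.0  # zero variance, different means
        assert res.loc["c→d", "p"] == 1.0  # zero variance, equal means
        assert np.isfinite(res["q"]).all()

    def test_group_size_guard(self):
        E = _toy_ecv({"a→b": [1.0, 2.0, 3.0]}, list("xyz"))
        with pytest.raises(ValueError):
            ecv_edge_tests(E, ["x"], ["y", "z"])

    def test_pooled_conditions_flag_planted_edges(self):
        gt = random_ground_truth(p=10, seed=321)
        X = simulate_expression(gt, seed=322)
        models = fit_all_models(X, BasalNetwork(genes=gt.genes, edges=gt.dag),
                                ScoreConfig())
        E = compute_ecv_matrix(models, X)
        ann = X.annotations
        S = ann.index[ann.condition == "treated"].tolist()
        T = ann.index[ann.condition == "control"].tolist()
        res = ecv_edge_tests(E, S, T)
        for e in gt.perturbed:
            assert res.loc[edge_id(e), "q"] < 0.01
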
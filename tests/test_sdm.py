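import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import vectorshift as vs
from vectorshift.sdm import (
    ModelEvaluation,
    SREModel,
    TrainingTable,
    auc_score,
    build_ensemble,
    cross_validate,
    evaluate,
    fit_algorithm,
    max_sens_spec_threshold,
    null_model_test,
    pseudo_absence_count,
    sample_pseudo_absences,
    summarize_evaluations,
    tss_score,
)


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney counting: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def brute_force_tss(scores, labels):
    best = -np.inf
    for t in sorted(set(scores)):
        sens = np.mean([s >= t for s, l in zip(scores, labels) if l == 1])
        spec = np.mean([s < t for s, l in zip(scores, labels) if l == 0])
        best = max(best, sens + spec - 1)
    return best


class TestPseudoAbsences:
    def test_count_rule(self):
        # equal numbers above 1000 presences, else 1000; 1000 itself is "not over"
        assert pseudo_absence_count(7239) == 7239
        assert pseudo_absence_count(367) == 1000
        assert pseudo_absence_count(1000) == 1000

    def test_sampling_excludes_presence_cells(self, small_landscape):
        cfg, stack = small_landscape
        suit = np.ones(stack.grid.shape)
        occ = vs.sample_occurrences(suit, stack.grid, 50, seed=0)
        domain = np.ones(stack.grid.shape, dtype=bool)
        tables = sample_pseudo_absences(
            occ, domain, stack.grid, stack, stack.names, replicates=3, seed=1
        )
        assert len(tables) == 3
        pres_rows, pres_cols = stack.grid.cell_index(occ.lon, occ.lat)
        pres_env = {tuple(v) for v in stack.values_at(occ.lon, occ.lat)}
        for t in tables:
            assert t.y.sum() == 50
            assert (t.y == 0).sum() == 1000  # 50 presences -> 1000 PAs
            pa_env = {tuple(v) for v in t.X[t.y == 0]}
            assert not (pa_env & pres_env)

    def test_insufficient_free_cells_error(self):
        grid = vs.GridSpec(5, 5, 1.0)
        stack = vs.PredictorStack(grid, {"a": np.ones(grid.shape)})
        occ = vs.sample_occurrences(np.ones(grid.shape), grid, 5, seed=0)
        with pytest.raises(ValueError, match="free cells"):
            sample_pseudo_absences(occ, np.ones(grid.shape, bool), grid, stack,
                                   ["a"], replicates=1, seed=0)


class TestAlgorithms:
    def test_sre_minmax_envelope(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [5.0, 0.5]])
        y = np.array([1, 1, 1, 0])
        sre = SREModel(q=0.0).fit(X, y)
        inside = np.array([[1.0, 1.5], [0.0, 2.0]])
        outside = np.array([[3.0, 1.0], [1.0, 2.5]])
        np.testing.assert_array_equal(sre.predict(inside), [1.0, 1.0])
        np.testing.assert_array_equal(sre.predict(outside), [0.0, 0.0])

    def test_sre_quantile_coverage(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1000, 1))
        y = np.ones(1000, int)
        y[0] = 0  # envelope fit ignores absences
        sre = SREModel(q=0.025).fit(X, y)
        coverage = sre.predict(X[y == 1]).mean()
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_glm_separable_training_auc_is_one(self):
        X = np.vstack([np.full((20, 1), -2.0), np.full((20, 1), 2.0)])
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        model = fit_algorithm("GLM", TrainingTable(X, y, ["x"]), seed=0)
        assert auc_score(model.predict(X), y) == 1.0

    def test_unknown_algorithm_and_single_class_errors(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit_algorithm("SVM", TrainingTable(X, np.array([0, 1, 0, 1]), ["x"]))
        with pytest.raises(ValueError, match="both classes"):
            fit_algorithm("GLM", TrainingTable(X, np.ones(4, int), ["x"]))

    def test_all_registry_algorithms_fit_and_predict_in_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 120) > 0).astype(int)
        table = TrainingTable(X, y, ["a", "b", "c"])
        for name in vs.ALGORITHMS:
            model = fit_algorithm(name, table, seed=2)
            s = model.predict(X)
            assert s.shape == (120,)
            assert np.all(s >= 0) and np.all(s <= 1), name


class TestEvaluation:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(scores, labels) == 1.0
        tss, _ = tss_score(scores, labels)
        assert tss == 1.0

    def test_worked_example_auc(self):
        # pos {0.9, 0.3}, neg {0.5, 0.2}: 3 wins out of 4 pairs
        scores = np.array([0.9, 0.3, 0.5, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(scores, labels) == pytest.approx(0.75)

    def test_worked_example_tss(self):
        scores = np.array([0.9, 0.3, 0.5, 0.2])
        labels = np.array([1, 1, 0, 0])
        tss, _ = tss_score(scores, labels)
        assert tss == pytest.approx(0.5)

    def test_rank_auc_equals_brute_force_and_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
            auc = auc_score(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_tss_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.uniform(0, 1, n), 1)
            tss, _ = tss_score(scores, labels)
            assert tss == pytest.approx(brute_force_tss(scores, labels), abs=1e-12)

    def test_single_class_test_set_error(self):
        class M:
            def predict(self, X):
                return np.zeros(X.shape[0])

        with pytest.raises(ValueError, match="both classes"):
            evaluate(M(), np.ones((3, 1)), np.ones(3, int))


class TestCrossValidate:
    def test_evaluation_count_and_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 2))
        y = (X[:, 0] > 0).astype(int)
        tables = [TrainingTable(X, y, ["a", "b"], replicate=r) for r in range(3)]
        evals = cross_validate(tables, ["GLM", "SRE"], repeats=5, seed=11)
        assert len(evals) == 5 * 3 * 2
        evals2 = cross_validate(tables, ["GLM", "SRE"], repeats=5, seed=11)
        assert [(e.auc, e.tss) for e in evals] == [(e.auc, e.tss) for e in evals2]

    def test_flexible_learner_beats_envelope_on_strong_signal(self, sdm_result):
        summary = summarize_evaluations(sdm_result["evaluations"]).set_index("algorithm")
        assert summary.loc["RF", "auc"] > summary.loc["SRE", "auc"]


class TestEnsemble:
    def _tables(self, seed=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        return [TrainingTable(X, y, ["a", "b"], replicate=0)]

    def test_single_qualifying_member_is_identity(self):
        tables = self._tables()
        evals = [ModelEvaluation("GLM", auc=0.95, tss=0.8, tss_threshold=0.5)]
        ens = build_ensemble(evals, tables, ["GLM"], seed=0)
        model = fit_algorithm("GLM", tables[0], seed=None)
        # one member: ensemble == that member up to the refit
        np.testing.assert_allclose(ens.weights, [1.0])
        assert ens.included_algorithms == ["GLM"]

    def test_tss_proportional_weights_arithmetic(self):
        class Fixed:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(X.shape[0], self.v)

        ens = vs.EnsembleModel(
            members=[("A", Fixed(0.9)), ("B", Fixed(0.3))],
            weights=np.array([2 / 3, 1 / 3]),
            evaluations=None,
            included_algorithms=["A", "B"],
        )
        out = ens.predict(np.zeros((1, 1)))
        assert out[0] == pytest.approx(0.7)

    def test_failing_member_excluded(self):
        tables = self._tables()
        evals = [
            ModelEvaluation("GLM", auc=0.95, tss=0.8, tss_threshold=0.5),
            ModelEvaluation("SRE", auc=0.79, tss=0.59, tss_threshold=0.5),
        ]
        ens = build_ensemble(evals, tables, ["GLM", "SRE"], seed=0)
        assert ens.included_algorithms == ["GLM"]
        assert ens.weights.sum() == pytest.approx(1.0)

    def test_no_qualifying_models_error(self):
        evals = [ModelEvaluation("GLM", auc=0.6, tss=0.2, tss_threshold=0.5)]
        with pytest.raises(ValueError, match="no qualifying"):
            build_ensemble(evals, self._tables(), ["GLM"])

    def test_ensemble_scores_bounded(self, sdm_result):
        suit = sdm_result["suitability"]
        assert np.all(suit >= 0) and np.all(suit <= 1)
        assert sdm_result["ensemble"].weights.sum() == pytest.approx(1.0)


class TestThreshold:
    def test_brute_force_example(self):
        scores = np.array([0.9, 0.8, 0.3, 0.4])
        labels = np.array([1, 1, 0, 0])
        assert max_sens_spec_threshold(scores, labels) == pytest.approx(0.8)

    def test_degenerate_all_equal(self, caplog):
        with caplog.at_level("WARNING"):
            t = max_sens_spec_threshold(np.full(4, 0.5), np.array([1, 1, 0, 0]))
        assert t == 0.5

    def test_low_scoring_absence_does_not_move_threshold(self):
        scores = np.array([0.9, 0.8, 0.3, 0.4])
        labels = np.array([1, 1, 0, 0])
        t0 = max_sens_spec_threshold(scores, labels)
        t1 = max_sens_spec_threshold(
            np.append(scores, 0.05), np.append(labels, 0)
        )
        assert t0 == t1


class TestNullModel:
    def _setup(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        table = TrainingTable(X, y, ["a", "b"])
        domain_X = rng.normal(size=(500, 2))
        return table, domain_X

    def test_unbeatable_real_auc_gives_minimal_p(self):
        table, domain_X = self._setup()
        p = null_model_test(1.01, [table], domain_X, n_null=19, seed=0)
        assert p == pytest.approx(1 / 20)

    def test_always_beaten_real_auc_gives_p_one(self):
        table, domain_X = self._setup()
        p = null_model_test(-0.01, [table], domain_X, n_null=19, seed=0)
        assert p == 1.0

    def test_rank_formula(self):
        # p = (1 + #null >= real) / (n_null + 1) spans [1/(n+1), 1]
        table, domain_X = self._setup()
        p = null_model_test(0.5, [table], domain_X, n_null=9, seed=1)
        assert 0.1 <= p <= 1.0

    def test_n_null_zero_error(self):
        table, domain_X = self._setup()
        with pytest.raises(ValueError, match="n_null"):
            null_model_test(0.9, [table], domain_X, n_null=0)
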
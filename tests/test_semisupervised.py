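"""Semi-supervised shared-embedding model: loss definitions, the
predictor-strength limits, the divided-task protocol, and the penalty sweep."""

import numpy as np
import pytest

import txbench as tb
from txbench.semisupervised import LAMBDA_GRID, SemiSupTrainSpec, heldout_error


def _identity_model(p, pi=0.0, lam_ae=0.0, lam_p=0.0, head=None):
    """Hand-built model with d = p so AE(x) = x exactly."""
    model = tb.SemiSupModel(
        W_enc=np.eye(p), b_enc=np.zeros(p),
        W_dec=np.eye(p), b_dec=np.zeros(p),
        head_w={}, head_b={},
        pi=pi, lambda_ae=lam_ae, lambda_p=lam_p,
    )
    if head is not None:
        w, b = head
        model.head_w["t"] = np.asarray(w, float)
        model.head_b["t"] = b
    return model


def _divided_fixture(n_per=240, p=20, seed=0):
    """Unlabeled pool plus one linearly separable divided task."""
    rng = np.random.default_rng(seed)
    X_pool = rng.normal(size=(300, p))
    y = rng.integers(2, size=n_per)
    y[:2] = [0, 1]
    X = rng.normal(size=(n_per, p))
    X[:, :3] += 2.5 * y[:, None]
    ids = np.array([f"L{i}" for i in range(n_per)])
    half = n_per // 2
    first = tb.LabeledBlock("t", X[:half], y[:half], ids[:half])
    second = tb.LabeledBlock("t", X[half:], y[half:], ids[half:])
    return X_pool, [first], [second]


class TestDividedTaskSplit:
    def _tasks_from_catalogue(self):
        tasks = []
        for _, row in tb.task_table().iterrows():
            n = int(row.n_samples)
            if row.task_type == "survival":
                t = tb.TaskSpec(
                    row.task_id, "survival", row.group,
                    np.arange(n).astype(str),
                    times=np.ones(n), events=np.ones(n, int),
                )
            else:
                labels = np.arange(n) % (3 if row.task_type == "multiclass" else 2)
                t = tb.TaskSpec(
                    row.task_id, row.task_type, row.group,
                    np.arange(n).astype(str), labels=labels,
                )
            tasks.append(t)
        return tasks

    def test_catalogue_yields_fourteen_divided_tasks(self):
        split = tb.split_divided_tasks(self._tasks_from_catalogue(), 200, seed=0)
        assert len(split.task_ids) == 14
        assert set(split.task_ids) == set(tb.divided_task_ids())

    def test_halves_are_disjoint_and_exhaustive(self):
        split = tb.split_divided_tasks(self._tasks_from_catalogue(), 200, seed=0)
        for tid in split.task_ids:
            a, b = split.first_half[tid], split.second_half[tid]
            assert len(np.intersect1d(a, b)) == 0
            n = int(tb.task_table().set_index("task_id").loc[tid, "n_samples"])
            assert len(a) + len(b) == n

    def test_exactly_at_threshold_is_selected(self):
        y = np.arange(200) % 2
        task = tb.TaskSpec("edge", "binary", "train",
                           np.arange(200).astype(str), labels=y)
        split = tb.split_divided_tasks([task], 200, seed=0)
        assert split.task_ids == ["edge"]

    def test_all_below_threshold_gives_empty_split(self):
        y = np.arange(100) % 2
        task = tb.TaskSpec("small", "binary", "train",
                           np.arange(100).astype(str), labels=y)
        split = tb.split_divided_tasks([task], 200, seed=0)
        assert split.task_ids == []


class TestLosses:
    def test_perfect_reconstruction_is_zero(self):
        model = _identity_model(4)
        x = np.array([1.0, -2.0, 0.5, 3.0])
        np.testing.assert_allclose(tb.reconstruction_loss(model, x), 0.0)

    def test_unit_offset_gives_unit_errors(self):
        model = _identity_model(4)
        model.b_dec = np.ones(4)  # AE(x) = x + 1 elementwise
        np.testing.assert_allclose(
            tb.reconstruction_loss(model, np.zeros(4)), 1.0
        )

    def test_reconstruction_errors_nonnegative(self):
        rng = np.random.default_rng(0)
        model = _identity_model(6)
        model.W_dec = rng.normal(size=(6, 6))
        assert (tb.reconstruction_loss(model, rng.normal(size=6)) >= 0).all()

    def test_uninformative_head_pays_log_two(self):
        model = _identity_model(3, pi=1.0, head=(np.zeros(3), 0.0))
        assert tb.classification_loss(model, np.ones(3), 1, "t") == pytest.approx(
            np.log(2)
        )

    def test_confident_head_examples(self):
        model = _identity_model(1, pi=1.0, head=(np.zeros(1), np.log(9.0)))
        # P = 0.9: confident wrong answer costs -log 0.1
        assert tb.classification_loss(model, np.zeros(1), 0, "t") == pytest.approx(
            2.3026, abs=1e-4
        )
        model.head_b["t"] = 50.0  # P -> 1 with true label 1: loss -> 0
        assert tb.classification_loss(model, np.zeros(1), 1, "t") < 1e-10

    def test_unknown_task_rejected(self):
        model = _identity_model(3)
        with pytest.raises(KeyError, match="no head"):
            tb.classification_loss(model, np.zeros(3), 1, "missing")


class TestCombinedLoss:
    def test_pi_zero_contains_only_reconstruction_and_penalties(self):
        rng = np.random.default_rng(1)
        model = _identity_model(4, pi=0.0, lam_ae=0.01, head=(rng.normal(size=4), 0.0))
        batch = rng.normal(size=(8, 4))
        expected = 0.01 * model.l2_ae()  # identity AE reconstructs exactly
        assert tb.combined_loss(model, batch, []) == pytest.approx(expected)

    def test_pi_one_contains_only_classification_and_penalties(self):
        model = _identity_model(2, pi=1.0, lam_p=0.1, head=(np.zeros(2), 0.0))
        labeled = [(np.zeros(2), 1, "t")]
        assert tb.combined_loss(model, np.empty((0, 2)), labeled) == pytest.approx(
            np.log(2)  # head weights are zero, so the l2 penalty vanishes
        )

    def test_zero_loss_when_everything_is_perfect(self):
        model = _identity_model(2, pi=0.5, head=(np.array([50.0, 0.0]), 0.0))
        labeled = [(np.array([1.0, 0.0]), 1, "t")]
        assert tb.combined_loss(model, np.zeros((4, 2)), labeled) == pytest.approx(
            0.5 * 0.0 + 0.5 * 0.0, abs=1e-10
        )

    def test_linear_in_pi(self):
        rng = np.random.default_rng(2)
        batch = rng.normal(size=(6, 3))
        labeled = [(rng.normal(size=3), 1, "t"), (rng.normal(size=3), 0, "t")]
        vals = []
        for pi in (0.0, 0.5, 1.0):
            model = _identity_model(3, pi=pi, head=(np.array([0.4, -0.2, 0.1]), 0.05))
            model.W_dec = np.eye(3) * 0.9
            vals.append(tb.combined_loss(model, batch, labeled))
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2)

    def test_positive_pi_without_labels_rejected(self):
        model = _identity_model(2, pi=0.5)
        with pytest.raises(ValueError, match="labeled"):
            tb.combined_loss(model, np.zeros((3, 2)), [])


class TestTraining:
    def test_pi_zero_is_a_plain_autoencoder_and_head_penalty_is_irrelevant(self):
        X_pool, labeled, _ = _divided_fixture()
        spec = SemiSupTrainSpec(steps=50, latent_dim=5, seed=3)
        a = tb.train_semisup(X_pool, labeled, 0.0, 0.01, 0.1, spec)
        b = tb.train_semisup(X_pool, labeled, 0.0, 0.01, 0.001, spec)
        trace_a = [e["reconstruction"] for e in a.training_log]
        trace_b = [e["reconstruction"] for e in b.training_log]
        np.testing.assert_array_equal(trace_a, trace_b)
        np.testing.assert_array_equal(a.W_enc, b.W_enc)
        assert a.labeled_ids_seen == set()  # heads untouched by data at pi=0

    def test_pure_supervision_learns_the_task(self):
        X_pool, labeled, heldout = _divided_fixture()
        spec = SemiSupTrainSpec(steps=600, latent_dim=8, learning_rate=5e-3, seed=0)
        model = tb.train_semisup(X_pool, labeled, 1.0, 0.0, 0.001, spec)
        err = heldout_error(model, heldout)
        assert 1.0 - err > 0.85  # held-out-half AUC

    def test_second_halves_never_sampled(self):
        X_pool, labeled, heldout = _divided_fixture()
        spec = SemiSupTrainSpec(steps=80, latent_dim=5, seed=1)
        model = tb.train_semisup(X_pool, labeled, 0.5, 0.01, 0.01, spec)
        first_ids = set(labeled[0].sample_ids.tolist())
        second_ids = set(heldout[0].sample_ids.tolist())
        assert model.labeled_ids_seen <= first_ids
        assert model.labeled_ids_seen.isdisjoint(second_ids)

    def test_invalid_pi_rejected(self):
        X_pool, labeled, _ = _divided_fixture()
        with pytest.raises(ValueError, match="pi"):
            tb.train_semisup(X_pool, labeled, 1.5, 0.0, 0.0)
        with pytest.raises(ValueError, match="labeled"):
            tb.train_semisup(X_pool, [], 0.5, 0.0, 0.0)


class TestEvaluateEmbedding:
    def test_no_embedding_arm_equals_plain_pipeline(self):
        """The identity arm of the representation comparison follows the
        same computation path as a direct nested-CV run on the features."""
        rng = np.random.default_rng(7)
        n, p = 120, 12
        y = rng.integers(2, size=n)
        y[:2] = [0, 1]
        X = rng.normal(size=(n, p))
        X[:, 0] += 2.0 * y
        task = tb.TaskSpec("t", "binary", "validate",
                           np.array([f"s{i}" for i in range(n)]), labels=y)
        learner = tb.LogisticLearner(grid=(0.01, 1.0), max_iter=100)
        arm = tb.semisupervised.evaluate_embedding(
            None, [(task, X)], [learner], K=5, seed=3
        )
        direct = tb.nested_cv_run(
            task, X, learner, tb.make_folds(task, 5, seed=3), seed=3
        )
        assert len(arm) == 1
        assert arm[0].mean_metric == direct.mean_metric
        assert arm[0].fold_hyperparameters == direct.fold_hyperparameters

    def test_latent_arm_runs_through_the_encoder(self):
        X_pool, labeled, _ = _divided_fixture(n_per=200, p=10)
        model = tb.train_semisup(
            X_pool, labeled, 0.0, 0.0, 0.0,
            SemiSupTrainSpec(steps=30, latent_dim=4, seed=0),
        )
        task = tb.TaskSpec("t", "binary", "validate",
                           labeled[0].sample_ids, labels=labeled[0].y)
        learner = tb.KNNLearner(grid=(3,))
        res = tb.semisupervised.evaluate_embedding(
            model, [(task, labeled[0].X)], [learner], K=5, seed=0
        )[0]
        assert res.fit_count == tb.count_models(5, 1)
        assert res.config["embedding"] == "semisup"


class TestLambdaSweep:
    def test_sixteen_pairs_and_minimum_selection(self):
        X_pool, labeled, heldout = _divided_fixture(n_per=200, p=10)
        spec = SemiSupTrainSpec(steps=20, latent_dim=4, seed=2)
        best, results = tb.sweep_lambdas(X_pool, labeled, heldout, 0.1, spec)
        assert len(results) == 16
        pairs = {(r["lambda_ae"], r["lambda_p"]) for r in results}
        assert pairs == {(a, b) for a in LAMBDA_GRID for b in LAMBDA_GRID}
        errors = [r["heldout_error"] for r in results]
        best_result = next(
            r for r in results if (r["lambda_ae"], r["lambda_p"]) == best
        )
        assert best_result["heldout_error"] == min(errors)

    def test_grid_values_match_design(self):
        assert LAMBDA_GRID == (0.0, 0.1, 0.01, 0.001)
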
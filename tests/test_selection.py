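"""SVM cross-validation fitness, grid search and the IBCGA sweep."""

import numpy as np
import pytest

from predcrp import (
    GAConfig,
    PredictorModel,
    cv_fitness,
    grid_search_svm,
    ibcga_select,
    planted_feature_table,
    train_model,
)


def separable_data(seed=0, n=60):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = np.where(X[:, 0] + X[:, 1] > 0, "activator", "repressor")
    X[:, 0] += np.where(y == "activator", 3.0, -3.0)  # widen the margin
    return X, y


class TestCVFitness:
    def test_separable_data_fitness_one(self):
        X, y = separable_data()
        fit = cv_fitness(X, y, np.ones(4, dtype=bool), folds=5, gamma=0.1, C=10)
        assert fit == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        accs = []
        for rep in range(20):
            X = rng.normal(size=(60, 4))
            y = np.array(["activator", "repressor"] * 30)
            accs.append(cv_fitness(X, y, np.ones(4, dtype=bool), folds=5, seed=rep))
        # chance level 0.5 within sampling error of 20 reps
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_empty_mask_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            cv_fitness(X, y, np.zeros(4, dtype=bool))

    def test_folds_reduced_with_warning(self):
        X, y = separable_data(n=20)  # smallest class < 24
        with pytest.warns(UserWarning, match="reducing folds"):
            cv_fitness(X, y, np.ones(4, dtype=bool), folds=24)

    def test_deterministic_under_seed(self):
        X, y = separable_data(seed=2)
        mask = np.array([True, True, False, True])
        a = cv_fitness(X, y, mask, folds=5, seed=9)
        b = cv_fitness(X, y, mask, folds=5, seed=9)
        assert a == b


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = separable_data()
        assert grid_search_svm(X, y, gamma_grid=[0.25], c_grid=[4.0], folds=5) == (0.25, 4.0)

    def test_returned_point_attains_grid_max(self):
        X, y = separable_data(seed=3)
        grid_g, grid_c = [0.01, 0.1, 1.0], [0.1, 1.0, 10.0]
        g, C = grid_search_svm(X, y, gamma_grid=grid_g, c_grid=grid_c, folds=5, seed=1)
        mask = np.ones(4, dtype=bool)
        best = max(
            cv_fitness(X, y, mask, folds=5, gamma=gg, C=cc, seed=1)
            for gg in grid_g for cc in grid_c
        )
        assert cv_fitness(X, y, mask, folds=5, gamma=g, C=C, seed=1) == best

    def test_empty_grid_rejected(self):
        X, y = separable_data()
        with pytest.raises(ValueError):
            grid_search_svm(X, y, gamma_grid=[], c_grid=[1.0])


class TestIBCGA:
    def test_masks_have_exactly_r_ones(self):
        X, y = planted_feature_table(0, n_samples=60, n_features=12, planted=(2, 7))
        cfg = GAConfig(r_start=2, r_end=4, population_size=8,
                       generations_per_r=3, cv_folds=3, seed=0)
        res = ibcga_select(X, y, cfg)
        for r, entry in res.per_r.items():
            assert int(np.sum(entry["mask"])) == r

    def test_finds_planted_pair(self):
        X, y = planted_feature_table(1)
        cfg = GAConfig(r_start=1, r_end=3, population_size=30,
                       generations_per_r=20, cv_folds=5, seed=1)
        res = ibcga_select(X, y, cfg)
        assert set(np.flatnonzero(res.per_r[2]["mask"])) == {3, 17}
        assert res.per_r[2]["fitness"] == 1.0

    def test_fixed_seed_bit_identical(self):
        X, y = planted_feature_table(2, n_samples=60, n_features=15, planted=(2, 7))
        cfg = GAConfig(r_start=1, r_end=3, population_size=10,
                       generations_per_r=4, cv_folds=3, seed=5)
        a = ibcga_select(X, y, cfg)
        b = ibcga_select(X, y, cfg)
        assert a.best_r == b.best_r
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.history == b.history

    def test_best_fitness_at_least_r_start(self):
        X, y = planted_feature_table(3, n_samples=60, n_features=15, planted=(2, 7))
        cfg = GAConfig(r_start=1, r_end=4, population_size=10,
                       generations_per_r=4, cv_folds=3, seed=2)
        res = ibcga_select(X, y, cfg)
        best = max(v["fitness"] for v in res.per_r.values())
        assert best >= res.per_r[cfg.r_start]["fitness"]

    def test_r_end_above_n_rejected(self):
        X, y = planted_feature_table(0, n_samples=30, n_features=5, planted=(1, 3))
        with pytest.raises(ValueError):
            ibcga_select(X, y, GAConfig(r_start=1, r_end=6, population_size=4,
                                        generations_per_r=1, cv_folds=3))


class TestModel:
    def test_train_predict_separable(self):
        X, y = separable_data()
        model = train_model(X, y, np.ones(4, dtype=bool), gamma=0.1, C=10)
        labels, scores = model.predict(X)
        assert np.mean(labels == y) == 1.0
        # scores oriented toward the repressor (positive) class
        assert scores[y == "repressor"].mean() > scores[y == "activator"].mean()

    def test_serialization_roundtrip(self, tmp_path):
        X, y = separable_data(seed=8)
        model = train_model(X, y, np.array([True, True, False, True]), gamma=0.2, C=4)
        path = tmp_path / "model.bin"
        model.save(path)
        back = PredictorModel.load(path)
        l1, s1 = model.predict(X)
        l2, s2 = back.predict(X)
        assert np.array_equal(l1, l2) and np.allclose(s1, s2)
        assert (path.with_name("model.bin.json")).exists()

    def test_holdout_accuracy_on_rule_generated_sites(self):
        """Labels are a deterministic function of Region + motif counts, so
        an SVM on the full descriptor should generalise almost perfectly on
        noise-free rule-covered sites."""
        from predcrp import SynthConfig, feature_matrix, generate_dataset, split_dataset

        cfg = SynthConfig(
            n_sites=300, seed=13,
            rule_weights={"A1": 88, "A2": 31, "R1": 14, "R2": 7},
        )
        dataset, truth = generate_dataset(cfg)
        features = feature_matrix(dataset)
        train, test = split_dataset(dataset, seed=13)
        Xtr = features.loc[[s.site_id for s in train]]
        Xte = features.loc[[s.site_id for s in test]]
        g, C = grid_search_svm(Xtr.to_numpy(), np.array(train.roles()), folds=5)
        model = train_model(Xtr, np.array(train.roles()),
                            np.ones(Xtr.shape[1], dtype=bool), gamma=g, C=C)
        labels, _ = model.predict(Xte)
        assert np.mean(labels == np.array(test.roles())) >= 0.95
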
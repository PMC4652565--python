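"""The four classifiers, with PAM pinned against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from xplatclass import (
    SUBTYPES,
    nb_fit_discrete,
    pam_fit,
    pam_predict,
    predict,
    predict_proba,
    train,
)
from xplatclass.exceptions import ContractError, LabelError

from conftest import random_matrix


def _labeled_noise(rng, n_features=10, n_per_class=10, classes=SUBTYPES):
    y = np.repeat(list(classes), n_per_class)
    X = random_matrix(rng, n_features, len(y))
    return X, y


def _separable_1d():
    X = pd.DataFrame([[0.0] * 6 + [5.0] * 6], index=["f0"])
    y = np.array(["PN"] * 6 + ["N"] * 6)
    return X, y


class TestTrainPredict:
    @pytest.mark.parametrize("method", ["svm", "rf", "nb", "pam"])
    def test_separable_classes_reach_perfect_training_accuracy(self, method):
        X, y = _separable_1d()
        model = train(X, y, method, seed=0)
        assert (predict(model, X) == y).all()

    def test_rf_same_seed_identical_predictions(self, rng):
        X, y = _labeled_noise(rng, 8, 8)
        m1 = train(X, y, "rf", params={"n_trees": 100}, seed=5)
        m2 = train(X, y, "rf", params={"n_trees": 100}, seed=5)
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))

    def test_svm_predict_on_training_matrix_is_consistent(self, rng):
        X, y = _labeled_noise(rng, 5, 8)
        model = train(X, y, "svm", seed=0)
        np.testing.assert_array_equal(
            predict(model, X), model.impl.predict(X.T.to_numpy())
        )

    def test_single_sample_prediction(self):
        X, y = _separable_1d()
        model = train(X, y, "svm")
        single = X.iloc[:, [0]]
        assert predict(model, single).shape == (1,)

    def test_sample_permutation_equivariance(self, rng):
        X, y = _labeled_noise(rng, 6, 10)
        model = train(X, y, "svm")
        perm = rng.permutation(X.shape[1])
        p_all = predict(model, X)
        p_perm = predict(model, X.iloc[:, perm])
        np.testing.assert_array_equal(p_perm, p_all[perm])

    def test_feature_permutation_invariance(self, rng):
        X, y = _labeled_noise(rng, 7, 10)
        model = train(X, y, "svm")
        shuffled = X.loc[list(rng.permutation(X.index))]
        np.testing.assert_array_equal(predict(model, shuffled), predict(model, X))

    def test_class_with_single_sample_rejected(self, rng):
        X = random_matrix(rng, 4, 3)
        with pytest.raises(LabelError):
            train(X, np.array(["PN", "PN", "N"]), "svm")

    def test_representation_mismatch_rejected(self, rng):
        X = pd.DataFrame(
            np.tile([1, 2, 3, 4, 1, 2, 3, 4], (3, 1)),
            index=["f0", "f1", "f2"],
        )
        y = np.array(["PN", "PN", "PN", "PN", "N", "N", "N", "N"])
        model = train(X, y, "nb", representation="equal_freq:k=4")
        continuous = X * 1.37
        with pytest.raises(ContractError):
            predict(model, continuous)
        with pytest.raises(ContractError):
            predict(model, X, representation="fc")

    def test_feature_list_mismatch_rejected(self, rng):
        X, y = _labeled_noise(rng, 5, 6)
        model = train(X, y, "svm")
        bad = X.copy()
        bad.index = [f"g{i}" for i in range(5)]
        with pytest.raises(ContractError):
            predict(model, bad)

    @pytest.mark.parametrize("method", ["svm", "rf", "nb", "pam"])
    def test_shuffled_labels_give_chance_level_heldout_accuracy(self, method):
        rng = np.random.default_rng(123)
        n_per_class = 25
        X, y = _labeled_noise(rng, 10, n_per_class)
        y = rng.permutation(y)
        train_idx = np.concatenate(
            [np.flatnonzero(y == c)[:20] for c in SUBTYPES]
        )
        test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
        model = train(
            X.iloc[:, train_idx], y[train_idx], method,
            params={"n_trees": 200} if method == "rf" else None, seed=0,
        )
        acc = (predict(model, X.iloc[:, test_idx]) == y[test_idx]).mean()
        se = np.sqrt(0.25 * 0.75 / test_idx.size)
        assert abs(acc - 0.25) <= 3 * se + 0.05

    def test_svm_ovo_trains_six_binary_classifiers_for_four_classes(self, rng):
        X, y = _labeled_noise(rng, 5, 5)
        model = train(X, y, "svm")
        assert model.impl.coef_.shape[0] == 6  # C(4,2)


class TestPAM:
    def _random_instance(self, rng, n_features=10, n_per_class=8, n_classes=3):
        classes = list(SUBTYPES[:n_classes])
        y = np.repeat(classes, n_per_class)
        X = random_matrix(rng, n_features, len(y))
        for j, c in enumerate(classes):
            X.iloc[j, y == c] += rng.uniform(0.5, 2.0)
        return X, y

    def test_delta_zero_equals_standardized_nearest_centroid_oracle(self, rng):
        """50 random instances: PAM at Delta=0 must agree everywhere with a
        brute-force standardized nearest-centroid rule."""
        for _ in range(50):
            X, y = self._random_instance(rng)
            model = pam_fit(X, y, delta=0.0)
            pred = pam_predict(model, X)
            Xv = X.to_numpy()
            denom = model.s + model.s0
            for j in range(Xv.shape[1]):
                scores = [
                    (((Xv[:, j] - model.centroids[:, i]) / denom) ** 2).sum()
                    - 2.0 * np.log(model.priors[i])
                    for i in range(len(model.classes))
                ]
                assert model.classes[int(np.argmin(scores))] == pred[j]

    def test_total_shrinkage_predicts_maximum_prior_class(self, rng):
        X = random_matrix(rng, 6, 30)
        y = np.array(["PN"] * 14 + ["N"] * 10 + ["CL"] * 6)
        model = pam_fit(X, y, delta=None, seed=0)
        dmax = float(np.abs(
            (model.centroids - model.overall[:, None])
            / ((model.s + model.s0)[:, None] * model.mk[None, :])
        ).max())
        total = pam_fit(X, y, delta=dmax + 1.0)
        pred = pam_predict(total, X)
        assert set(pred) == {"PN"}  # the maximum-prior class

    def test_feature_with_no_centroid_deviation_never_contributes(self, rng):
        X, y = self._random_instance(rng, n_features=5)
        classes = sorted(set(y))
        # force feature f4 to have identical class means
        for c in classes:
            cols = np.flatnonzero(np.asarray(y) == c)
            X.iloc[4, cols] = X.iloc[4, cols] - X.iloc[4, cols].mean()
        model = pam_fit(X, y, delta=0.0)
        assert np.allclose(model.dprime[4], 0.0, atol=1e-10)

    def test_number_of_active_features_non_increasing_in_delta(self, rng):
        X, y = self._random_instance(rng, n_features=20)
        deltas = np.linspace(0.0, 3.0, 12)
        active = [pam_fit(X, y, delta=d).n_active_features() for d in deltas]
        assert all(a >= b for a, b in zip(active, active[1:]))

    def test_exact_score_tie_goes_to_first_class_in_label_order(self):
        X = pd.DataFrame([[-1.0, -1.0, 1.0, 1.0]], index=["f0"])
        y = np.array(["PN", "PN", "N", "N"])
        model = pam_fit(X, y, delta=0.0)
        midpoint = pd.DataFrame([[0.0]], index=["f0"])
        assert pam_predict(model, midpoint)[0] == "PN"

    def test_agreement_with_exhaustive_score_oracle_on_new_samples(self, rng):
        X, y = self._random_instance(rng, n_features=8, n_per_class=10)
        model = pam_fit(X, y, seed=1)
        Xnew = random_matrix(rng, 8, 20)
        Xnew.index = X.index
        pred = pam_predict(model, Xnew)
        shrunk = model.shrunken_centroids
        denom = model.s + model.s0
        for j in range(20):
            scores = [
                (((Xnew.to_numpy()[:, j] - shrunk[:, i]) / denom) ** 2).sum()
                - 2.0 * np.log(model.priors[i])
                for i in range(len(model.classes))
            ]
            assert pred[j] == model.classes[int(np.argmin(scores))]


class TestNaiveBayes:
    def test_perfectly_informative_bin_gives_confident_posterior(self):
        # one feature, bin determines class exactly; alpha=0.01 smoothing
        X = pd.DataFrame([[1, 1, 1, 1, 2, 2, 2, 2]], index=["f0"])
        y = np.array(["PN"] * 4 + ["N"] * 4)
        model = nb_fit_discrete(X, y, alpha=0.01, representation="equal_freq:k=2")
        proba = predict_proba(model, X)
        # hand computation: P(bin=1|PN) = (4+.01)/(4+.03), P(bin=1|N) = .01/(4+.03)
        p_bin1_pn = 4.01 / 4.03
        p_bin1_n = 0.01 / 4.03
        expected = p_bin1_pn / (p_bin1_pn + p_bin1_n)
        assert proba.loc[proba.index[0], "PN"] == pytest.approx(expected, rel=1e-6)
        assert (proba.to_numpy().max(axis=1) >= 0.99).all()

    def test_infinite_smoothing_limit_approaches_class_priors(self):
        X = pd.DataFrame([[1, 1, 1, 2, 2, 2, 2, 2]], index=["f0"])
        y = np.array(["PN"] * 3 + ["N"] * 5)
        model = nb_fit_discrete(X, y, alpha=1e9, representation="equal_freq:k=2")
        proba = predict_proba(model, X)
        np.testing.assert_allclose(proba["PN"], 3 / 8, atol=1e-3)
        np.testing.assert_allclose(proba["N"], 5 / 8, atol=1e-3)

    def test_joint_likelihood_factorizes_over_independent_features(self):
        X = pd.DataFrame(
            [[1, 1, 2, 2, 1, 2, 1, 2], [1, 2, 1, 2, 2, 1, 2, 1]],
            index=["f0", "f1"],
        )
        y = np.array(["PN"] * 4 + ["N"] * 4)
        alpha = 0.5
        model = nb_fit_discrete(X, y, alpha=alpha, representation="equal_freq:k=2")
        proba = predict_proba(model, X)

        def table(row, cls, b):
            mask = y == cls
            count = int((X.iloc[row][mask] == b).sum())
            return (count + alpha) / (mask.sum() + 2 * alpha)

        for j, sid in enumerate(X.columns):
            post = {}
            for cls in ("PN", "N"):
                prior = 0.5
                post[cls] = prior * table(0, cls, X.iloc[0, j]) * table(
                    1, cls, X.iloc[1, j]
                )
            z = sum(post.values())
            assert proba.loc[sid, "PN"] == pytest.approx(post["PN"] / z, rel=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        X = pd.DataFrame(
            rng.integers(1, 5, size=(4, 24)), index=[f"f{i}" for i in range(4)]
        )
        y = np.repeat(list(SUBTYPES), 6)
        model = nb_fit_discrete(X, y, representation="equal_freq:k=4")
        proba = predict_proba(model, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_continuous_values_rejected_by_categorical_mode(self, rng):
        X = random_matrix(rng, 3, 12)
        y = np.repeat(list(SUBTYPES), 3)
        with pytest.raises(ContractError):
            nb_fit_discrete(X, y)

    def test_gaussian_variant_used_on_continuous_representation(self, rng):
        X, y = random_matrix(rng, 4, 20), np.repeat(list(SUBTYPES), 5)
        model = train(X, y, "nb", representation="fc")
        from sklearn.naive_bayes import GaussianNB

        assert isinstance(model.impl, GaussianNB)
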
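import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from streamdapc import DAPC, fit_dapc, loo_accuracy, predict_dapc


def _random_instance(rng, n_max=40, p_max=10, g_max=4, min_per_class=2):
    n = int(rng.integers(4 * min_per_class, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    g = int(rng.integers(2, g_max + 1))
    while True:
        y = rng.integers(0, g, n)
        counts = np.bincount(y, minlength=g)
        if counts.min() >= min_per_class:
            break
    X = rng.normal(0, 1, (n, p)) + y[:, None] * rng.normal(0.5, 0.5, p)
    return X, y


@pytest.fixture()
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(0, 0.3, (10, 2)), rng.normal(10, 0.3, (10, 2))]
    )
    y = np.repeat([0, 1], 10)
    return X, y


def test_separable_clusters_resubstitution(separable):
    X, y = separable
    model = DAPC(variance_fraction=0.95).fit(X, y)
    assert (model.predict(X) == y).all()


def test_full_rank_matches_direct_lda(separable):
    """With every component kept, DAPC is LDA in a rotated basis."""
    rng = np.random.default_rng(11)
    for _ in range(15):
        X, y = _random_instance(rng)
        dapc = DAPC(variance_fraction=1.0).fit(X, y)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        assert (dapc.predict(X) == lda.predict(X)).all()


def test_rotation_invariance():
    rng = np.random.default_rng(2)
    X, y = _random_instance(rng)
    Q = ortho_group.rvs(X.shape[1], random_state=5)
    acc = lambda M, Z: (M.predict(Z) == y).mean()  # noqa: E731
    a = acc(DAPC(variance_fraction=1.0).fit(X, y), X)
    b = acc(DAPC(variance_fraction=1.0).fit(X @ Q, y), X @ Q)
    assert a == b


def test_posteriors_sum_to_one():
    rng = np.random.default_rng(3)
    X, y = _random_instance(rng)
    model = fit_dapc(X, y)
    labels, post = predict_dapc(model, rng.normal(0, 2, (25, X.shape[1])))
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
    assert set(labels) <= set(model.classes_)


def test_equidistant_point_splits_posterior_and_takes_lower_label():
    # two 1-D groups symmetric about zero, equal priors, one axis
    X = np.array([[-2.0], [-1.0], [-1.5], [1.0], [2.0], [1.5]])
    y = np.array([1, 1, 1, 2, 2, 2])
    model = DAPC(variance_fraction=1.0).fit(X, y)
    labels, post = predict_dapc(model, np.array([[0.0]]))
    assert np.allclose(post[0], [0.5, 0.5], atol=1e-9)
    assert labels[0] == 1


def test_contributions_normalised_and_zero_for_silent_variable():
    rng = np.random.default_rng(4)
    n = 30
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack(
        [
            y + rng.normal(0, 0.1, n),  # carries the group signal
            rng.normal(0, 1, n),
            np.zeros(n),  # constant: zero loading everywhere
        ]
    )
    model = DAPC(variance_fraction=1.0).fit(X, y)
    contrib = model.variable_contributions()
    assert np.allclose(contrib.sum(axis=0), 1.0, atol=1e-9)
    assert np.all(contrib[2] < 1e-12)
    assert contrib[:, 0].argmax() == 0


def test_contribution_dataframe_with_names():
    rng = np.random.default_rng(6)
    X, y = _random_instance(rng)
    frame = pd.DataFrame(X, columns=[f"t{j}" for j in range(X.shape[1])])
    contrib = DAPC().fit(frame, y).variable_contributions()
    assert isinstance(contrib, pd.DataFrame)
    assert list(contrib.index) == list(frame.columns)


def test_loo_perfect_separation(separable):
    X, y = separable
    assert loo_accuracy(X, y, variance_fraction=0.95) == 1.0


def test_loo_equals_brute_force_oracle():
    """Full-refit folds agree with an independent per-fold LDA oracle."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        X, y = _random_instance(rng, n_max=25, p_max=6, g_max=3, min_per_class=3)
        ours = loo_accuracy(X, y, variance_fraction=1.0)
        correct = 0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            lda = LinearDiscriminantAnalysis().fit(X[mask], y[mask])
            correct += int(lda.predict(X[i: i + 1])[0] == y[i])
        assert ours == pytest.approx(correct / len(y))


def test_loo_skips_singleton_class_with_warning():
    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (9, 3))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2])  # class 2 has one member
    with pytest.warns(UserWarning, match="single-member"):
        acc = loo_accuracy(X, y)
    assert 0.0 <= acc <= 1.0


def test_loo_chance_level_for_random_labels():
    rng = np.random.default_rng(9)
    accs = []
    for _ in range(8):
        X = rng.normal(0, 1, (40, 5))
        y = np.repeat([0, 1], 20)
        accs.append(loo_accuracy(X, y, variance_fraction=0.95))
    # binomial noise around 0.5: se of the mean of 8x40 fold outcomes
    se = 0.5 / np.sqrt(8 * 40)
    assert abs(np.mean(accs) - 0.5) < 5 * se


def test_fit_is_bit_deterministic():
    rng = np.random.default_rng(10)
    X, y = _random_instance(rng)
    a = DAPC().fit(X, y)
    b = DAPC().fit(X, y)
    for attr in ("center_", "pca_basis_", "da_coefficients_",
                 "group_centroids_", "priors_"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))


def test_n_pc_monotone_in_variance_fraction():
    rng = np.random.default_rng(12)
    X, y = _random_instance(rng, n_max=30, p_max=10)
    kept = [
        DAPC(variance_fraction=f).fit(X, y).n_pc_
        for f in (0.2, 0.5, 0.8, 0.95, 1.0)
    ]
    assert kept == sorted(kept)
    assert DAPC().variance_fraction == 0.95  # protocol default


def test_pca_basis_orthonormal_and_retention_minimal():
    rng = np.random.default_rng(13)
    X, y = _random_instance(rng)
    model = DAPC(variance_fraction=0.9).fit(X, y)
    V = model.pca_basis_
    assert np.allclose(V.T @ V, np.eye(model.n_pc_), atol=1e-9)
    cum = np.cumsum(model.explained_variance_ratio_)
    assert cum[model.n_pc_ - 1] >= 0.9 - 1e-12
    if model.n_pc_ > 1:
        assert cum[model.n_pc_ - 2] < 0.9


def test_fit_error_cases():
    rng = np.random.default_rng(14)
    X = rng.normal(0, 1, (10, 3))
    with pytest.raises(ValueError, match="2 distinct"):
        DAPC().fit(X, np.zeros(10))
    with pytest.raises(ValueError, match="constant"):
        DAPC().fit(np.ones((10, 3)), np.repeat([0, 1], 5))
    with pytest.raises(ValueError, match="3 samples"):
        DAPC().fit(X[:2], [0, 1])


def test_feature_mismatch_names_difference():
    rng = np.random.default_rng(15)
    X = pd.DataFrame(rng.normal(0, 1, (12, 3)), columns=["a", "b", "c"])
    y = np.repeat([0, 1], 6)
    model = DAPC().fit(X, y)
    bad = X.rename(columns={"c": "d"})
    with pytest.raises(ValueError, match="missing \\['c'\\].*extra \\['d'\\]"):
        model.predict(bad)
    # same set, permuted order: realigned, identical predictions
    assert (model.predict(X[["c", "a", "b"]]) == model.predict(X)).all()


def test_json_round_trip(tmp_path):
    rng = np.random.default_rng(16)
    X, y = _random_instance(rng)
    model = DAPC().fit(X, y)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = DAPC.from_json(path)
    Xnew = rng.normal(0, 1, (20, X.shape[1]))
    assert (back.predict(Xnew) == model.predict(Xnew)).all()
    assert np.allclose(back.predict_proba(Xnew), model.predict_proba(Xnew))
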
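import numpy as np
import pandas as pd
import pytest

from streamdapc import (
    AssessmentConfig,
    accuracy,
    cohens_kappa,
    confusion_table,
    discretize_bibi,
    fit_dapc,
    fuzzy_match,
    kappa_permutation_pvalue,
    resample_evaluate,
    restricted_reassessment,
    select_important_taxa,
)

from conftest import make_metadata


# ---------------------------------------------------------------------------
# Discretisation


@pytest.mark.parametrize(
    "score, category",
    [(1.0, 1), (1.5, 1), (1.51, 2), (3.9, 6), (4.0, 6), (4.1, 7), (5.0, 8)],
)
def test_discretize_category_boundaries(score, category):
    assert discretize_bibi(score) == category


def test_small_score_difference_can_cross_categories():
    # 3.9 and 4.1 differ by 0.2 yet land in different categories
    assert discretize_bibi(3.9) != discretize_bibi(4.1)


@pytest.mark.parametrize("score", [0.99, 5.01, -1.0])
def test_discretize_out_of_range(score):
    with pytest.raises(ValueError):
        discretize_bibi(score)


def test_discretize_grid_is_monotone_with_eight_steps():
    grid = np.round(np.arange(100, 501) / 100.0, 2)  # 1.00, 1.01, ..., 5.00
    cats = discretize_bibi(grid)
    assert (np.diff(cats) >= 0).all()
    assert sorted(set(cats.tolist())) == list(range(1, 9))


# ---------------------------------------------------------------------------
# Fuzzy matching


def test_window_zero_is_exact_equality():
    assert fuzzy_match(4, 4, window=0)
    assert not fuzzy_match(4, 5, window=0)


def test_fuzzy_pair_count_over_grid():
    matches = sum(
        fuzzy_match(p, o, window=1)
        for p in range(1, 9)
        for o in range(1, 9)
    )
    assert matches == 22


def test_fuzzy_worked_example_category_six():
    """A prediction into the 3.51-4.0 bin is correct for any observed score
    whose category is 5, 6 or 7, i.e. up to a BIBI of 4.5."""
    predicted = discretize_bibi(3.8)
    assert predicted == 6
    for observed_score in (3.2, 3.5, 3.9, 4.2, 4.5):
        assert fuzzy_match(predicted, discretize_bibi(observed_score))
    for observed_score in (3.0, 4.6):
        assert not fuzzy_match(predicted, discretize_bibi(observed_score))


def test_fuzzy_match_range_checks():
    with pytest.raises(ValueError):
        fuzzy_match(0, 4)


# ---------------------------------------------------------------------------
# Accuracy and kappa


def test_accuracy_extreme_tables():
    diag = np.diag([3, 1, 2, 0, 0, 0, 0, 1])
    assert accuracy(diag) == 1.0
    assert accuracy(diag, fuzzy=True) == 1.0
    corner = np.zeros((8, 8), dtype=int)
    corner[0, 7] = 5
    assert accuracy(corner) == 0.0
    assert accuracy(corner, fuzzy=True) == 0.0


def test_accuracy_hand_counted_table():
    table = np.zeros((8, 8), dtype=int)
    table[2, 2] = 3  # on diagonal
    table[3, 4] = 2  # one off
    table[5, 7] = 1  # two off
    assert accuracy(table) == 0.5
    assert accuracy(table, fuzzy=True) == pytest.approx(5 / 6)


def test_accuracy_empty_table_error():
    with pytest.raises(ValueError):
        accuracy(np.zeros((8, 8)))


def test_kappa_perfect_agreement():
    assert cohens_kappa(np.diag([2, 3, 1, 0, 0, 0, 0, 4])) == pytest.approx(1.0)


def test_kappa_zero_for_independent_margins():
    row = np.array([4, 2, 1, 1, 0, 0, 0, 2], dtype=float)
    col = np.array([1, 3, 3, 0, 1, 0, 2, 0], dtype=float)
    rank_one = np.outer(row, col)
    assert cohens_kappa(rank_one) == pytest.approx(0.0, abs=1e-12)


def test_kappa_embedded_two_by_two_matches_brute_force():
    table = np.zeros((8, 8), dtype=float)
    table[0, 0], table[0, 1] = 20, 5
    table[1, 0], table[1, 1] = 10, 15
    total = table.sum()
    p_o = (20 + 15) / total
    p_e = (25 * 30 + 25 * 20) / total**2
    assert cohens_kappa(table) == pytest.approx((p_o - p_e) / (1 - p_e))


def test_kappa_degenerate_margin_defined_as_zero():
    table = np.zeros((8, 8))
    table[3, 3] = 10  # single category on both margins: p_e = 1
    assert cohens_kappa(table) == 0.0


def test_fuzzy_kappa_uses_banded_agreement():
    table = np.zeros((8, 8), dtype=float)
    table[0, 1] = 6
    table[4, 6] = 4
    mask = np.abs(np.subtract.outer(np.arange(8), np.arange(8))) <= 1
    p_o = table[mask].sum() / 10
    row, col = table.sum(1) / 10, table.sum(0) / 10
    p_e = (np.outer(row, col))[mask].sum()
    assert cohens_kappa(table, fuzzy=True) == pytest.approx(
        (p_o - p_e) / (1 - p_e)
    )


def test_kappa_permutation_detects_real_agreement():
    rng = np.random.default_rng(0)
    obs = rng.integers(1, 9, 60)
    assert kappa_permutation_pvalue(obs, obs, n_permutations=200, seed=1) < 0.05
    pred = rng.integers(1, 9, 60)  # independent of obs
    assert kappa_permutation_pvalue(obs, pred, n_permutations=200, seed=2) > 0.01


# ---------------------------------------------------------------------------
# Resampling evaluation


def _encoded_dataset(n_per_cat=6, categories=(1, 3, 5, 7), noise=0.05, seed=0):
    """Category perfectly encoded in the first variable."""
    rng = np.random.default_rng(seed)
    cats = np.repeat(categories, n_per_cat)
    X = pd.DataFrame(
        {
            "signal": cats * 10.0 + rng.normal(0, noise, len(cats)),
            "noise": rng.normal(0, 1, len(cats)),
        },
        index=[f"S{i}" for i in range(len(cats))],
    )
    bibi = 1.0 + (cats - 1) * 0.5 + 0.2  # mid-bin scores
    meta = make_metadata(bibi, sample_ids=list(X.index))
    return X, meta, cats


def test_separable_data_reaches_perfect_accuracy():
    X, meta, _ = _encoded_dataset()
    cfg = AssessmentConfig(n_replicates=20, n_permutations=50, seed=5)
    report = resample_evaluate(X, meta, cfg)
    assert report.summary["train_overall"]["mean"] == 1.0
    assert report.summary["val_overall"]["mean"] == 1.0
    assert report.kappa["overall"] == pytest.approx(1.0)


def test_resampling_reproducible_and_ordered():
    X, meta, _ = _encoded_dataset(noise=15.0, seed=1)
    cfg = AssessmentConfig(n_replicates=25, n_permutations=50, seed=9)
    a = resample_evaluate(X, meta, cfg)
    b = resample_evaluate(X, meta, cfg)
    assert a.replicates.equals(b.replicates)
    assert a.kappa == b.kappa
    # fuzzy >= overall for every replicate and in summary
    assert (a.replicates["val_fuzzy"] >= a.replicates["val_overall"]).all()
    assert (a.replicates["train_fuzzy"] >= a.replicates["train_overall"]).all()
    for metric, stats in a.summary.items():
        lo, hi = stats["ci_low"], stats["ci_high"]
        assert lo <= stats["mean"] <= hi
        assert a.replicates[metric].min() <= stats["mean"] <= a.replicates[metric].max()


def test_resampling_different_seeds_differ():
    X, meta, _ = _encoded_dataset(noise=15.0, seed=1)
    a = resample_evaluate(X, meta, AssessmentConfig(n_replicates=25, seed=1, n_permutations=20))
    b = resample_evaluate(X, meta, AssessmentConfig(n_replicates=25, seed=2, n_permutations=20))
    assert not a.replicates.equals(b.replicates)
    # but estimates agree within Monte-Carlo noise
    se = a.replicates["val_overall"].std() / np.sqrt(25)
    diff = abs(
        a.summary["val_overall"]["mean"] - b.summary["val_overall"]["mean"]
    )
    assert diff < 3 * max(se, 1e-6) + 0.05


def test_resampling_preconditions():
    X, meta, _ = _encoded_dataset(n_per_cat=3)
    with pytest.raises(ValueError, match="10 samples"):
        resample_evaluate(X.iloc[:8], meta, AssessmentConfig(n_replicates=2))
    flat = make_metadata([3.2] * len(X), sample_ids=list(X.index))
    with pytest.raises(ValueError, match="2 observed categories"):
        resample_evaluate(X, flat, AssessmentConfig(n_replicates=2))


# ---------------------------------------------------------------------------
# Indicator selection and restricted re-evaluation


def _fitted_model():
    X, meta, cats = _encoded_dataset(noise=0.5, seed=3)
    return fit_dapc(X, cats), X, meta


def test_select_threshold_zero_returns_all_contributing():
    model, X, _ = _fitted_model()
    selected = select_important_taxa(model, threshold=0.0)
    assert set(selected.index) == set(X.columns)
    assert (selected["max_contribution"].diff().dropna() <= 0).all()


def test_select_above_maximum_returns_empty():
    model, _, _ = _fitted_model()
    assert len(select_important_taxa(model, threshold=1.1)) == 0


def test_select_uses_only_first_axes():
    model, _, _ = _fitted_model()
    contrib = model.variable_contributions()
    one_axis = select_important_taxa(model, threshold=0.0, n_axes=1)
    assert np.allclose(
        one_axis["max_contribution"].sort_index(),
        contrib.iloc[:, 0].sort_index(),
    )


def test_restricted_equals_plain_when_all_selected():
    X, meta, _ = _encoded_dataset(noise=0.5, seed=3)
    cfg = AssessmentConfig(
        n_replicates=15, n_permutations=20, loading_threshold=1e-9, seed=4
    )
    restricted = restricted_reassessment(X, meta, cfg)
    # selection keeps both variables; only the column order may change
    assert set(restricted.provenance["restricted_to"]) == set(X.columns)
    plain = resample_evaluate(X[restricted.selected_taxa.index], meta, cfg)
    assert restricted.replicates.equals(plain.replicates)


def test_restricted_model_confined_to_selected_taxa(strong_dataset):
    from streamdapc import aggregate, rarefy

    table, tax, meta, truth = strong_dataset
    otu = aggregate(rarefy(table, seed=0), tax, "otu")
    cfg = AssessmentConfig(n_replicates=8, n_permutations=20, seed=6)
    report = restricted_reassessment(otu, meta, cfg)
    assert report.n_variables == len(report.selected_taxa)
    assert set(report.provenance["restricted_to"]) == set(report.selected_taxa.index)
    assert report.provenance["stage1_n_variables"] == otu.counts.shape[1]


def test_restricted_too_few_taxa_error():
    X, meta, _ = _encoded_dataset(noise=0.5, seed=3)
    cfg = AssessmentConfig(n_replicates=5, loading_threshold=0.9999, seed=4)
    with pytest.raises(ValueError, match="lower the threshold"):
        restricted_reassessment(X, meta, cfg)
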
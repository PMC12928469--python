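"""Splitting, AUC scoring, the classifier panel, and Welch comparisons."""

import numpy as np
import pytest
from scipy import stats

from pathsim import (
    ClassifierSpec,
    ConfigError,
    CoreProfile,
    Experiment,
    ExperimentConfig,
    LabeledPopulation,
    SplitError,
    auc_score,
    compare_models,
    named_model,
    split,
    train_and_score,
)


def _pop(rng, n_case=300, n_control=300, n_features=10):
    X = rng.integers(0, 3, size=(n_case + n_control, n_features))
    y = np.array([1] * n_case + [0] * n_control)
    return LabeledPopulation(X, y)


# --- split ----------------------------------------------------------------


def test_split_stratification_arithmetic(rng):
    train, test = split(_pop(rng), train_fraction=2 / 3, seed=0)
    assert (train.n_cases, train.n_controls) == (200, 200)
    assert (test.n_cases, test.n_controls) == (100, 100)
    assert train.meta["partition"] == "train"
    assert test.meta["partition"] == "test"


def test_split_determinism(rng):
    pop = _pop(rng)
    a = split(pop, seed=7)
    b = split(pop, seed=7)
    assert np.array_equal(a[0].X, b[0].X) and np.array_equal(a[1].X, b[1].X)


def test_split_errors(rng):
    pop = _pop(rng)
    with pytest.raises(SplitError):
        split(pop, train_fraction=1.0, seed=0)  # empty holdout
    single = LabeledPopulation(pop.X, np.ones(pop.n, dtype=int))
    with pytest.raises(SplitError):
        split(single, seed=0)


# --- AUC ------------------------------------------------------------------


def test_auc_matches_brute_force_pair_counting():
    y = np.array([1, 1, 1, 0, 0, 0])
    s = np.array([0.9, 0.4, 0.7, 0.2, 0.8, 0.3])
    wins = ties = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            wins += s[i] > s[j]
            ties += s[i] == s[j]
    expected = (wins + 0.5 * ties) / 9
    assert auc_score(y, s) == pytest.approx(expected) == pytest.approx(7 / 9)


def test_auc_boundary_values():
    y = np.array([0, 0, 1, 1])
    assert auc_score(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auc_score(y, [0.5, 0.5, 0.5, 0.5]) == 0.5  # all ties


def test_auc_complement_symmetry(rng):
    y = rng.integers(0, 2, size=50)
    y[0], y[1] = 0, 1
    s = rng.random(50)
    assert auc_score(y, s) + auc_score(y, 1 - s) == pytest.approx(1.0)


# --- classifier panel -----------------------------------------------------


def test_classifier_spec_kinds_and_validation():
    for kind in ("NB", "LR", "DT", "RF", "NN"):
        est = ClassifierSpec(kind).build(seed=0)
        assert hasattr(est, "fit")
    with pytest.raises(ConfigError):
        ClassifierSpec("SVM")


def test_nn_solves_linearly_separable_panel(rng):
    """Capacity smoke test: 25 sigmoid units on a separable 48-feature task."""
    X = rng.integers(0, 3, size=(900, 48))
    w = rng.normal(size=48)
    score = X @ w
    y = (score > np.median(score)).astype(int)
    pop = LabeledPopulation(X, y)
    train, test = split(pop, seed=1)
    fit = train_and_score(train, test, ClassifierSpec("NN"), seed=2)
    assert fit.auc > 0.95


def test_label_permutation_drives_auc_to_chance(rng):
    X = rng.integers(0, 3, size=(800, 20))
    y = rng.permutation(np.array([1] * 400 + [0] * 400))
    pop = LabeledPopulation(X, y)
    train, test = split(pop, seed=3)
    fit = train_and_score(train, test, ClassifierSpec("LR"), seed=4)
    assert abs(fit.auc - 0.5) < 0.1


def test_train_and_score_requires_both_classes(rng):
    pop = _pop(rng, 50, 50)
    train, test = split(pop, seed=0)
    train.y[:] = 1
    with pytest.raises(SplitError):
        train_and_score(train, test, ClassifierSpec("NB"), seed=0)


# --- Welch comparison -----------------------------------------------------


def test_identical_samples_give_half():
    a = [0.8, 0.85, 0.9]
    assert compare_models(a, a) == pytest.approx(0.5)


def test_large_shift_drives_p_to_zero(rng):
    a = rng.normal(10.0, 0.01, size=20)
    b = rng.normal(0.0, 0.01, size=20)
    assert compare_models(a, b) < 1e-12


def test_zero_variance_special_cases():
    assert compare_models([1.0, 1.0], [1.0, 1.0]) == 0.5
    assert compare_models([2.0, 2.0], [1.0, 1.0]) == 0.0
    assert compare_models([1.0, 1.0], [2.0, 2.0]) == 1.0


def test_three_value_toy_matches_t_distribution():
    """Closed form: equal variances 0.0025, n=3 each, mean gap 0.1 ->
    t = 0.1/sqrt(2*0.0025/3), Welch df = 4."""
    a, b = [0.8, 0.85, 0.9], [0.7, 0.75, 0.8]
    t = 0.1 / np.sqrt(2 * 0.0025 / 3)
    expected = stats.t.sf(t, df=4)
    assert compare_models(a, b) == pytest.approx(expected)
    assert compare_models(a, b) == pytest.approx(0.0352, abs=2e-3)


def test_compare_needs_replicates():
    with pytest.raises(ConfigError):
        compare_models([1.0], [1.0, 2.0])


# --- experiment runner ----------------------------------------------------


def test_experiment_end_to_end_reproducible():
    config = ExperimentConfig(
        model=named_model("simple-default"),
        profile=CoreProfile(n_case=150, n_control=100),
        sizes=(1.0,),
        classifiers=(ClassifierSpec("NB"), ClassifierSpec("DT")),
        n_replicates=2,
        seed=5,
    )
    r1 = Experiment(config).run()
    r2 = Experiment(config).run()
    assert r1.records.equals(r2.records)
    assert len(r1.records) == 4  # 2 replicates x 2 classifiers
    assert ((r1.records["auc"] >= 0) & (r1.records["auc"] <= 1)).all()
    summ = r1.summary()
    assert set(summ.columns) == {"size", "classifier", "mean_auc", "se", "n_replicates"}


def test_experiment_config_from_dict_round_trip():
    config = ExperimentConfig.from_dict(
        {
            "model": "simple-low-prevalence",
            "profile": {"n_case": 120, "n_control": 90},
            "sizes": [1.0, 2.0],
            "classifiers": ["NB", {"kind": "NN", "params": {"max_iter": 50}}],
            "perturbations": [{"kind": "mislabel_cases", "fraction": 0.1}],
            "n_replicates": 3,
            "seed": 9,
        }
    )
    assert config.model.mp == 5
    assert config.sizes == (1.0, 2.0)
    assert config.classifiers[1].kind == "NN"
    d = config.to_dict()
    assert d["n_replicates"] == 3 and d["seed"] == 9
    with pytest.raises(ConfigError):
        ExperimentConfig.from_dict({"model": "simple-default", "bogus": 1})
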
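"""Cross-validation schemes and the sparse logistic regression decoder."""

import numpy as np
import pytest

import lfpdecode as L
from lfpdecode.decoder import SLRModel, fit_slr, periodic_folds, rolling_folds
from lfpdecode.features import FeatureTable


def test_periodic_folds_are_balanced():
    g = periodic_folds(70, 7)
    assert np.all(np.bincount(g) == 10)
    assert np.array_equal(g[:14], np.tile(np.arange(7), 2))
    assert np.all(np.bincount(periodic_folds(7, 7)) == 1)
    with pytest.raises(ValueError):
        periodic_folds(5, 7)


def test_rolling_folds_are_chronological():
    splits = rolling_folds(70, 3)
    assert len(splits) == 3
    for train, test in splits:
        assert train.max() < test.min()
        assert len(test) == 17
    assert [len(tr) for tr, _ in splits] == [17, 34, 51]
    train, test = rolling_folds(2, 1)[0]
    assert train.tolist() == [0] and test.tolist() == [1]
    with pytest.raises(ValueError):
        rolling_folds(5, 3)


def test_two_choice_ratio_classes():
    tasks = L.two_choice_tasks((8000, 10000, 13000, 16000, 32000))
    assert len(tasks) == 10
    assert len({t.ratio_class for t in tasks}) == 6
    by_class = {}
    for t in tasks:
        by_class.setdefault(t.ratio_class, []).append(t.labels)
    sizes = sorted(len(v) for v in by_class.values())
    assert sizes == [1, 1, 1, 2, 2, 3]
    # one-octave pairs group together, the two-octave pair stands alone
    octave = [t for t in tasks if t.ratio_octaves == 1.0]
    assert len(octave) == 2
    assert len({t.ratio_class for t in octave}) == 1

    small = L.two_choice_tasks((8000, 16000, 32000))
    assert len(small) == 3 and len({t.ratio_class for t in small}) == 2
    assert len(L.two_choice_tasks((8000, 10000))) == 1
    with pytest.raises(ValueError, match="distinct"):
        L.two_choice_tasks((8000, 8000, 16000))


def _separable_toy(seed=4242, n=160, n_noise=98):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 2 + n_noise))
    X[:, 0] += 5.0 * y
    X[:, 1] -= 5.0 * y
    perm = rng.permutation(n)
    return X[perm], y[perm]


def test_ard_recovers_separable_toy_and_prunes_noise():
    X, y = _separable_toy()
    model = fit_slr(X[:100], y[:100])
    acc = np.mean(model.predict(X[100:]) == y[100:])
    assert acc >= 0.95
    noise_active = model.active_[2:].sum()
    assert noise_active <= 0.1 * 98
    assert model.active_[0] or model.active_[1]
    # pruned features carry exactly zero weight
    assert np.all(model.coef_[~model.active_] == 0)


def test_l1_route_agrees_on_separable_toy():
    X, y = _separable_toy()
    model = fit_slr(X[:100], y[:100], method="l1")
    assert np.mean(model.predict(X[100:]) == y[100:]) >= 0.95


def test_fit_is_deterministic():
    X, y = _separable_toy(seed=1, n=60, n_noise=20)
    a = fit_slr(X, y)
    b = fit_slr(X, y)
    assert np.array_equal(a.coef_, b.coef_)
    assert np.array_equal(a.intercept_, b.intercept_)


def test_active_set_never_grows():
    X, y = _separable_toy(seed=2, n=80, n_noise=40)
    model = fit_slr(X, y)
    trace = model.active_trace_
    assert all(b <= a for a, b in zip(trace, trace[1:]))


def test_constant_features_are_pruned_and_majority_predicted(rng):
    X = np.ones((30, 4))
    y = np.array([0] * 18 + [1] * 12)
    model = fit_slr(X, y)
    assert model.n_active == 0
    assert np.all(model.predict(rng.standard_normal((5, 4))) == 0)


def test_fit_input_validation(rng):
    with pytest.raises(ValueError, match="2 classes"):
        fit_slr(rng.standard_normal((10, 3)), np.zeros(10))
    with pytest.raises(ValueError, match="2 rows per class"):
        fit_slr(rng.standard_normal((3, 2)), np.array([0, 0, 1]))


def test_zero_weight_model_gives_uniform_probabilities():
    model = SLRModel(classes_=np.arange(5), coef_=np.zeros((3, 5)),
                     intercept_=np.zeros(5), mean_=np.zeros(3), scale_=np.ones(3),
                     active_=np.zeros(3, bool), alpha_=np.full(3, np.inf),
                     n_iter_=0, converged_=True)
    proba = model.predict_proba(np.random.default_rng(0).normal(size=(4, 3)))
    assert np.allclose(proba, 0.2)
    single = model.predict_proba(np.zeros((1, 3)))
    assert abs(single.sum() - 1.0) < 1e-12
    assert model.predict(np.zeros((1, 3)))[0] == 0  # tie -> lowest class
    with pytest.raises(ValueError, match="features"):
        model.predict_proba(np.zeros((2, 7)))


def _noise_table(rng, n_per_label=35, n_feat=40, labels=(8000, 10000, 13000, 16000, 32000)):
    n = n_per_label * len(labels)
    y = np.array(list(labels) * n_per_label)
    return FeatureTable(X=rng.standard_normal((n, n_feat)), labels_hz=y,
                        band="high-gamma", kind="power", session_id="null",
                        starts_ms=np.arange(n, dtype=float))


def test_label_free_features_decode_at_chance():
    """Five-choice on pure noise ~20%, two-choice ~50%.

    Fold-level accuracies are correlated through the shared training
    rows, so the tolerance is the pooled 99% binomial half-width
    inflated by 2 to cover that correlation."""
    pair = L.DecodingTask((8000, 32000), "two_choice", 0)
    acc5, acc2, n5 = [], [], 0
    for seed in range(5):
        table = _noise_table(np.random.default_rng(seed))
        r5 = L.run_task(table, L.five_choice_task(np.unique(table.labels_hz)))
        acc5.append(r5.mean_accuracy)
        n5 += r5.n_test_total
        acc2.append(L.run_task(table, pair).mean_accuracy)
    assert abs(np.mean(acc5) - 20.0) <= 2 * 2.576 * 100 * np.sqrt(0.2 * 0.8 / n5)
    assert abs(np.mean(acc2) - 50.0) <= 2 * 2.576 * 100 * np.sqrt(0.25 / (n5 * 0.4))


def test_run_task_validates_labels(rng):
    table = _noise_table(rng, labels=(8000, 16000))
    with pytest.raises(ValueError, match="missing"):
        L.run_task(table, L.five_choice_task((8000, 16000, 32000)))


def test_rolling_scheme_runs_end_to_end(rng):
    table = _noise_table(rng, n_per_label=20, n_feat=10, labels=(8000, 16000))
    r = L.run_task(table, L.DecodingTask((8000, 16000), "two_choice", 0),
                   scheme="rolling", n_rolling=3)
    assert len(r.fold_accuracies) == 3
    assert 0 <= r.mean_accuracy <= 100
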
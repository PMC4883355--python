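import numpy as np
import pytest

from conftest import make_rulebase
from gaitnfc.fcm import FCMConfig, FCMResult, fcm_fit
from gaitnfc.tsk import (
    RuleBase,
    TrainConfig,
    TSKRule,
    bp_premise_step,
    firing_strengths,
    fit,
    infer,
    infer_batch,
    init_from_fcm,
    lse_consequents,
    predict_class,
    premise_gradients,
    training_sse,
)


# ---------------------------------------------------------------------------
# rule construction

def test_single_cluster_widths_match_weighted_std(rng):
    X = rng.normal(0.0, [[1.0], [3.0]], size=(2, 400))  # anisotropic cloud
    res = fcm_fit(X, FCMConfig(c=1, seed=0))
    model = init_from_fcm(res, X)
    # with one cluster every membership is 1: width = population std
    expected = X.std(axis=1)
    np.testing.assert_allclose(model.rules[0].width, expected, rtol=1e-10)
    np.testing.assert_allclose(
        model.rules[0].center, X.mean(axis=1), atol=1e-12
    )


def test_coincident_groups_get_floor_widths():
    X = np.column_stack([np.zeros((2, 10)), np.full((2, 10), 4.0)])
    res = fcm_fit(X, FCMConfig(c=2, seed=1))
    model = init_from_fcm(res, X)
    # every point sits on its center: widths collapse onto the floor,
    # 1e-3 of the per-dimension range (range = 4)
    floor = 1e-3 * 4.0
    widths = model.widths
    assert np.all(widths <= floor * 1.5)
    assert np.all(widths > 0)


def test_rule_count_equals_cluster_count(rng):
    X = rng.normal(size=(3, 40))
    res = fcm_fit(X, FCMConfig(c=5, seed=2))
    model = init_from_fcm(res, X)
    assert model.n_rules == 5
    assert all(r.consequent.size == 4 for r in model.rules)
    assert np.all(model.consequents == 0.0)


def test_rule_validation():
    with pytest.raises(ValueError):
        TSKRule(center=np.zeros(2), width=np.array([1.0, 0.0]),
                consequent=np.zeros(3))
    with pytest.raises(ValueError):
        TSKRule(center=np.zeros(2), width=np.ones(2), consequent=np.zeros(2))


# ---------------------------------------------------------------------------
# inference

def test_firing_is_one_at_rule_center(random_rulebase):
    x = random_rulebase.rules[1].center
    w, w_norm = firing_strengths(random_rulebase, x)
    assert w[1] == pytest.approx(1.0, abs=1e-12)
    assert np.argmax(w_norm) == 1
    assert w_norm.sum() == pytest.approx(1.0, abs=1e-12)


def test_symmetric_rules_fire_equally():
    model = make_rulebase(
        centers=[[-1.0], [1.0]], widths=[[1.0], [1.0]],
        consequents=[[0.0, 0.0], [0.0, 0.0]],
    )
    _, w_norm = firing_strengths(model, np.array([0.0]))
    np.testing.assert_allclose(w_norm, [0.5, 0.5], atol=1e-12)


def test_firing_matches_per_dimension_loop_oracle(random_rulebase, rng):
    x = rng.normal(size=4)
    w, w_norm = firing_strengths(random_rulebase, x)
    w_oracle = []
    for rule in random_rulebase.rules:
        prod = 1.0
        for j in range(4):
            prod *= np.exp(
                -(((x[j] - rule.center[j]) / rule.width[j]) ** 2)
            )
        w_oracle.append(prod)
    np.testing.assert_allclose(w, w_oracle, atol=1e-12)
    np.testing.assert_allclose(
        w_norm, np.array(w_oracle) / np.sum(w_oracle), atol=1e-12
    )
    assert w_norm.sum() == pytest.approx(1.0, abs=1e-12)


def test_far_input_falls_back_to_uniform_weights():
    model = make_rulebase(
        centers=[[0.0], [1.0]], widths=[[1e-3], [1e-3]],
        consequents=[[0.0, 1.0], [0.0, 3.0]],
    )
    _, w_norm = firing_strengths(model, np.array([1e6]))
    np.testing.assert_allclose(w_norm, [0.5, 0.5])


def test_single_constant_rule_infers_the_constant(rng):
    model = make_rulebase(
        centers=[[0.0, 0.0]], widths=[[1.0, 1.0]],
        consequents=[[0.0, 0.0, 7.0]],
    )
    for x in rng.normal(size=(5, 2)):
        assert infer(model, x) == pytest.approx(7.0, abs=1e-12)


def test_equal_firing_constants_average():
    model = make_rulebase(
        centers=[[-1.0], [1.0]], widths=[[1.0], [1.0]],
        consequents=[[0.0, 1.0], [0.0, 3.0]],
    )
    assert infer(model, np.array([0.0])) == pytest.approx(2.0, abs=1e-12)


def test_inference_matches_direct_evaluation(random_rulebase, rng):
    x = rng.normal(size=4)
    _, w_norm = firing_strengths(random_rulebase, x)
    expected = sum(
        w_norm[i] * (rule.consequent[:-1] @ x + rule.consequent[-1])
        for i, rule in enumerate(random_rulebase.rules)
    )
    assert infer(random_rulebase, x) == pytest.approx(expected, abs=1e-12)


def test_inference_is_a_convex_combination(random_rulebase, rng):
    X = rng.normal(size=(4, 20))
    f = infer_batch(random_rulebase, X)
    P = random_rulebase.consequents
    fi = X.T @ P[:, :-1].T + P[:, -1]
    assert np.all(f >= fi.min(axis=1) - 1e-9)
    assert np.all(f <= fi.max(axis=1) + 1e-9)


# ---------------------------------------------------------------------------
# least-squares consequents

def test_single_rule_recovers_exact_affine_function(rng):
    X = rng.normal(size=(3, 20))
    coef = np.array([2.0, -1.0, 0.5])
    y = coef @ X + 4.0
    model = make_rulebase(
        centers=[X.mean(axis=1)], widths=[X.std(axis=1)],
        consequents=[np.zeros(4)],
    )
    lse_consequents(model, X, y, ridge=0.0)
    np.testing.assert_allclose(model.rules[0].consequent[:-1], coef,
                               atol=1e-8)
    assert model.rules[0].consequent[-1] == pytest.approx(4.0, abs=1e-8)
    assert training_sse(model, X, y) == pytest.approx(0.0, abs=1e-12)


def test_constant_target_fits_exactly(random_rulebase, rng):
    X = rng.normal(size=(4, 30))
    y = np.full(30, 4.0)
    lse_consequents(random_rulebase, X, y, ridge=1e-10)
    np.testing.assert_allclose(
        infer_batch(random_rulebase, X), 4.0, atol=1e-6
    )


def test_lse_matches_normal_equations_oracle(rng):
    d, n, r = 3, 20, 2
    X = rng.normal(size=(d, n))
    y = rng.normal(size=n)
    ridge = 1e-6
    model = make_rulebase(
        centers=rng.normal(size=(r, d)),
        widths=rng.uniform(0.8, 1.5, size=(r, d)),
        consequents=np.zeros((r, d + 1)),
    )
    from gaitnfc.tsk import _firing_batch

    _, wbar = _firing_batch(model, X.T)
    # explicit-loop design assembly and regularised normal equations
    p = r * (d + 1)
    Phi = np.zeros((n, p))
    for s in range(n):
        for i in range(r):
            for j in range(d):
                Phi[s, i * (d + 1) + j] = wbar[s, i] * X[j, s]
            Phi[s, i * (d + 1) + d] = wbar[s, i]
    theta = np.linalg.solve(Phi.T @ Phi + ridge * np.eye(p), Phi.T @ y)
    lse_consequents(model, X, y, ridge=ridge)
    np.testing.assert_allclose(
        model.consequents.ravel(), theta, atol=1e-8
    )


def test_lse_never_increases_sse(random_rulebase, rng):
    X = rng.normal(size=(4, 25))
    y = rng.normal(size=25)
    # start from arbitrary non-zero consequents
    sse_before = training_sse(random_rulebase, X, y)
    lse_consequents(random_rulebase, X, y, ridge=1e-8)
    assert training_sse(random_rulebase, X, y) <= sse_before + 1e-9


def test_lse_is_optimal_against_perturbations(rng):
    d, n, r = 2, 30, 2
    X = rng.normal(size=(d, n))
    y = rng.normal(size=n)
    model = make_rulebase(
        centers=rng.normal(size=(r, d)),
        widths=rng.uniform(0.8, 1.5, size=(r, d)),
        consequents=np.zeros((r, d + 1)),
    )
    lse_consequents(model, X, y, ridge=0.0)
    base = training_sse(model, X, y)
    for i in range(r):
        for j in range(d + 1):
            for delta in (1e-3, -1e-3):
                pert = model.consequents
                pert[i, j] += delta
                model._set_params(consequents=pert)
                assert training_sse(model, X, y) >= base - 1e-9
                pert[i, j] -= delta
                model._set_params(consequents=pert)


def test_zero_order_consequents_are_constants(rng):
    X = rng.normal(size=(2, 20))
    y = rng.normal(size=20)
    model = make_rulebase(
        centers=rng.normal(size=(2, 2)),
        widths=np.ones((2, 2)),
        consequents=np.zeros((2, 3)),
    )
    lse_consequents(model, X, y, ridge=1e-8, first_order=False)
    assert np.all(model.consequents[:, :-1] == 0.0)


def test_single_rule_lse_equals_ordinary_least_squares(rng):
    """With one always-active rule the model is plain affine regression."""
    X = rng.normal(size=(3, 40))
    y = rng.normal(size=40)
    model = make_rulebase(
        centers=[X.mean(axis=1)], widths=[10.0 * X.std(axis=1)],
        consequents=[np.zeros(4)],
    )
    lse_consequents(model, X, y, ridge=0.0)
    A = np.column_stack([X.T, np.ones(40)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    np.testing.assert_allclose(model.rules[0].consequent, beta, atol=1e-8)


# ---------------------------------------------------------------------------
# backprop premise step

def _small_instance(rng, r=2, d=2, n=8):
    X = rng.normal(size=(d, n))
    y = rng.normal(size=n)
    model = make_rulebase(
        centers=rng.normal(size=(r, d)),
        widths=rng.uniform(0.7, 1.5, size=(r, d)),
        consequents=rng.normal(size=(r, d + 1)),
    )
    return model, X, y


def test_zero_learning_rate_leaves_parameters(rng):
    model, X, y = _small_instance(rng)
    C0, S0 = model.centers.copy(), model.widths.copy()
    bp_premise_step(model, X, y, learning_rate=0.0)
    np.testing.assert_array_equal(model.centers, C0)
    np.testing.assert_array_equal(model.widths, S0)


def test_analytic_gradient_matches_finite_differences(rng):
    model, X, y = _small_instance(rng)
    grad_C, grad_S = premise_gradients(model, X, y)
    h = 1e-6
    for i in range(model.n_rules):
        for j in range(model.input_dim):
            for grad, attr in ((grad_C, "center"), (grad_S, "width")):
                plus = make_rulebase(
                    model.centers, model.widths, model.consequents
                )
                minus = make_rulebase(
                    model.centers, model.widths, model.consequents
                )
                getattr(plus.rules[i], attr)[j] += h
                getattr(minus.rules[i], attr)[j] -= h
                fd = (
                    training_sse(plus, X, y) - training_sse(minus, X, y)
                ) / (2 * h)
                assert grad[i, j] == pytest.approx(
                    fd, rel=1e-4, abs=1e-6
                )


def test_small_step_descends(rng):
    model, X, y = _small_instance(rng)
    sse0 = training_sse(model, X, y)
    lr = 1e-3
    for _ in range(20):
        trial = make_rulebase(model.centers, model.widths,
                              model.consequents)
        bp_premise_step(trial, X, y, learning_rate=lr)
        if training_sse(trial, X, y) <= sse0:
            break
        lr *= 0.5
    else:
        pytest.fail("no descending step found by rate halving")


def test_widths_stay_above_floor_after_step(rng):
    model, X, y = _small_instance(rng)
    bp_premise_step(model, X, y, learning_rate=100.0)
    assert np.all(model.widths >= np.asarray(model.width_floor) - 1e-15)


# ---------------------------------------------------------------------------
# full pipeline

def _xor_data(rng, reps=10, jitter=0.05):
    base = np.array(
        [[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float
    ).T  # (2, 4)
    labels = ["a", "a", "b", "b"] * reps
    X = np.tile(base, reps) + rng.normal(0, jitter, size=(2, 4 * reps))
    y = np.array([{"a": 1, "b": 2}[l] for l in labels], dtype=float)
    return X, y, {"a": 1, "b": 2}


def test_epochs_zero_is_pure_fcm_plus_lse(rng):
    X = rng.normal(size=(2, 20))
    y = rng.integers(1, 5, size=20).astype(float)
    model = fit(X, y, FCMConfig(c=3, seed=0), TrainConfig(epochs=0, seed=0))
    epochs = [e["epoch"] for e in model.training_log]
    assert epochs == [0, "final"]


def test_xor_data_reaches_perfect_training_accuracy(rng):
    X, y, codes = _xor_data(rng)
    model = fit(
        X, y, FCMConfig(c=4, seed=1),
        TrainConfig(epochs=10, seed=1),
        class_codes=codes,
    )
    pred = [predict_class(model, X[:, i]) for i in range(X.shape[1])]
    truth = ["a" if v == 1 else "b" for v in y]
    assert pred == truth


def test_training_log_sse_non_increasing(rng):
    X, y, codes = _xor_data(rng)
    model = fit(
        X, y, FCMConfig(c=4, seed=1), TrainConfig(epochs=10, seed=1),
        class_codes=codes,
    )
    sses = [e["sse"] for e in model.training_log]
    assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))


def test_fit_is_deterministic(rng):
    X, y, codes = _xor_data(rng)
    kwargs = dict(class_codes=codes)
    m1 = fit(X, y, FCMConfig(c=3, seed=5), TrainConfig(epochs=5, seed=5),
             **kwargs)
    m2 = fit(X, y, FCMConfig(c=3, seed=5), TrainConfig(epochs=5, seed=5),
             **kwargs)
    assert m1.training_log == m2.training_log
    np.testing.assert_array_equal(m1.centers, m2.centers)
    np.testing.assert_array_equal(m1.widths, m2.widths)
    np.testing.assert_array_equal(m1.consequents, m2.consequents)


def test_single_class_targets_warn(rng):
    X = rng.normal(size=(2, 10))
    y = np.ones(10)
    with pytest.warns(UserWarning, match="single class"):
        fit(X, y, FCMConfig(c=2, seed=0), TrainConfig(epochs=0, seed=0))


# ---------------------------------------------------------------------------
# class decoding

@pytest.mark.parametrize(
    "value,expected",
    [(2.4, "sitting_trot"), (2.5, "sitting_trot"), (9.7, "canter"),
     (-3.0, "walk"), (1.0, "walk")],
)
def test_predict_class_decoding(value, expected):
    model = make_rulebase(
        centers=[[0.0]], widths=[[1.0]], consequents=[[0.0, value]]
    )
    assert predict_class(model, np.array([0.0])) == expected


# ---------------------------------------------------------------------------
# serialisation

def test_rulebase_json_round_trip(tmp_path, random_rulebase, rng):
    p = tmp_path / "model.json"
    random_rulebase.training_log.append({"epoch": 0, "sse": 1.0, "lr": 0.01})
    random_rulebase.save(p)
    back = RuleBase.load(p)
    X = rng.normal(size=(4, 10))
    np.testing.assert_array_equal(
        infer_batch(back, X), infer_batch(random_rulebase, X)
    )
    assert back.training_log == random_rulebase.training_log
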
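import numpy as np
import pandas as pd
import pytest

from bbbkit import qsar
from bbbkit import synthetic_data as synth
from conftest import TABLE3_ROWS, EXPECTED_LOGBB


def test_delta_logp_reproduces_printed_rows():
    for name, (logkw, logpcw, expected, _e) in TABLE3_ROWS.items():
        assert qsar.delta_logp(logkw, logpcw) == pytest.approx(expected,
                                                               abs=1e-12)
    assert qsar.delta_logp(1.23, 1.23) == 0.0


def test_delta_logp_requires_finite_inputs():
    with pytest.raises(ValueError):
        qsar.delta_logp(float("nan"), 1.0)


@pytest.mark.parametrize("system", sorted(TABLE3_ROWS))
def test_builtin_model_predictions(system):
    logkw, logpcw, _dlp, e = TABLE3_ROWS[system]
    d = qsar.CompoundDescriptors(logkw=logkw, logPcw=logpcw, E=e)
    assert qsar.predict_logbb(qsar.EQ2, d) == pytest.approx(
        EXPECTED_LOGBB[system], abs=1e-4)


def test_intercept_only_prediction():
    assert qsar.EQ2.predict({"delta_logp": 0, "logkw": 0, "E": 0}) == \
        pytest.approx(-0.114)


def test_missing_descriptor_named():
    with pytest.raises(ValueError, match="logkw"):
        qsar.EQ2.predict({"delta_logp": 1.0, "E": 1.0})


def test_prediction_is_linear():
    """Prediction of the descriptor average equals the average prediction."""
    rng = np.random.default_rng(0)
    records = [{"delta_logp": a, "logkw": b, "E": c}
               for a, b, c in rng.uniform(0, 5, size=(10, 3))]
    mean_record = {k: np.mean([r[k] for r in records]) for k in records[0]}
    preds = [qsar.EQ2.predict(r) for r in records]
    assert qsar.EQ2.predict(mean_record) == pytest.approx(np.mean(preds),
                                                          abs=1e-12)


def test_noiseless_backward_fit_recovers_coefficients():
    df = synth.gen_qsar_dataset(n=40, sigma=0.0, seed=5)
    model = qsar.fit_mlr_backward(df[["delta_logp", "logkw", "E"]],
                                  df["logBB"])
    assert model.intercept == pytest.approx(-0.114, abs=1e-9)
    for name, coef in qsar.EQ2.coefficients.items():
        assert model.coefficients[name] == pytest.approx(coef, abs=1e-9)
    assert model.r2 == pytest.approx(1.0)


def test_backward_elimination_drops_null_descriptor():
    df = synth.gen_qsar_dataset(n=40, sigma=0.2, seed=11)
    X = df[["delta_logp", "logkw", "E"]].copy()
    X["null"] = np.random.default_rng(99).uniform(0, 1, size=40)
    model = qsar.fit_mlr_backward(X, df["logBB"], alpha_remove=0.05)
    assert "null" not in model.coefficients


def test_pure_noise_gives_intercept_only_with_warning():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    y = rng.normal(size=30)
    with pytest.warns(UserWarning, match="intercept-only"):
        model = qsar.fit_mlr_backward(X, y, alpha_remove=1e-6)
    assert model.coefficients == {}
    assert model.intercept == pytest.approx(y.mean())


def test_design_validation():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": rng.normal(size=20)})
    X["b"] = 2 * X["a"]   # collinear
    with pytest.raises(ValueError, match="rank-deficient"):
        qsar.fit_mlr_backward(X, rng.normal(size=20))
    X2 = pd.DataFrame({"a": rng.normal(size=20), "c": np.ones(20)})
    with pytest.raises(ValueError, match="constant"):
        qsar.fit_mlr_backward(X2, rng.normal(size=20))


def test_lto_press_matches_per_fold_refit_oracle():
    """PRESS equals an explicit fold-by-fold normal-equations refit."""
    df = synth.gen_qsar_dataset(n=40, sigma=0.436, seed=17)
    X = df[["delta_logp", "logkw", "E"]]
    y = df["logBB"].to_numpy()
    seed = 123
    cv = qsar.cross_validate_lto(X, y, fold_size=10, seed=seed)

    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    order = np.random.default_rng(seed).permutation(len(y))
    press = 0.0
    for start in range(0, len(y), 10):
        test = order[start:start + 10]
        train = np.setdiff1d(order, test)
        A = design[train]
        beta = np.linalg.solve(A.T @ A, A.T @ y[train])
        press += float(np.sum((y[test] - design[test] @ beta) ** 2))
    assert cv.press == pytest.approx(press, abs=1e-10)
    tss = float(np.sum((y - y.mean()) ** 2))
    assert cv.r2_cv == pytest.approx(1 - press / tss, abs=1e-12)
    assert cv.rmsecv == pytest.approx(np.sqrt(press / len(y)), abs=1e-12)


def test_lto_noiseless_press_is_zero():
    df = synth.gen_qsar_dataset(n=40, sigma=0.0, seed=2)
    cv = qsar.cross_validate_lto(df[["delta_logp", "logkw", "E"]],
                                 df["logBB"], seed=0)
    assert cv.press == pytest.approx(0.0, abs=1e-16)
    assert cv.r2_cv == pytest.approx(1.0)


def test_lto_requires_enough_samples():
    df = synth.gen_qsar_dataset(n=10, sigma=0.1, seed=0,
                                coefficients={"logkw": 0.3},
                                descriptor_ranges={"logkw": (0, 3)})
    with pytest.raises(ValueError):
        qsar.cross_validate_lto(df[["logkw"]], df["logBB"], fold_size=10)


def test_cv_is_pessimistic_on_noisy_data():
    """R2CV < R2 on every seeded noisy replicate (CV optimism property)."""
    for seed in range(25):
        df = synth.gen_qsar_dataset(n=40, sigma=0.436, seed=200 + seed)
        X = df[["delta_logp", "logkw", "E"]]
        model = qsar.fit_mlr_backward(X, df["logBB"], alpha_remove=1.0)
        cv = qsar.cross_validate_lto(X, df["logBB"], seed=seed)
        assert cv.r2_cv < model.r2


def test_leverage_centroid_and_trace():
    df = synth.gen_qsar_dataset(n=40, sigma=0.436, seed=8)
    X = df[["delta_logp", "logkw", "E"]]
    model = qsar.fit_mlr_backward(X, df["logBB"], alpha_remove=1.0)
    centroid = {c: float(X[c].mean()) for c in X.columns}
    h, in_domain = qsar.applicability_domain(model, centroid)
    assert h == pytest.approx(1.0 / 40, abs=1e-12)
    assert in_domain
    # hat-matrix trace identity: sum of training leverages = p + 1
    assert qsar.training_leverages(model).sum() == pytest.approx(4.0,
                                                                 abs=1e-9)


def test_far_query_is_out_of_domain():
    df = synth.gen_qsar_dataset(n=40, sigma=0.436, seed=8)
    X = df[["delta_logp", "logkw", "E"]]
    model = qsar.fit_mlr_backward(X, df["logBB"], alpha_remove=1.0)
    far = {c: float(X[c].mean() + 10 * X[c].std()) for c in X.columns}
    h, in_domain = qsar.applicability_domain(model, far)
    assert h > model.ad_leverage_threshold
    assert not in_domain


def test_builtin_model_has_no_domain_information():
    with pytest.raises(ValueError, match="training design"):
        qsar.applicability_domain(qsar.EQ2, {"delta_logp": 1, "logkw": 1,
                                             "E": 1})


def test_model_json_round_trip(tmp_path):
    df = synth.gen_qsar_dataset(n=40, sigma=0.3, seed=4)
    model = qsar.fit_mlr_backward(df[["delta_logp", "logkw", "E"]],
                                  df["logBB"])
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = qsar.QSARModel.from_json(path)
    assert loaded.intercept == model.intercept
    assert loaded.coefficients == model.coefficients
    record = {"delta_logp": 5.0, "logkw": 1.0, "E": 1.5}
    assert loaded.predict(record) == pytest.approx(model.predict(record))


def test_descriptor_table_recomputes_delta_logp(tmp_path):
    df = pd.DataFrame({"logkw": [0.637], "logPcw": [8.995], "E": [1.46],
                       "delta_logp": [999.0]})   # bogus stored value
    path = tmp_path / "d.csv"
    df.to_csv(path, index=False)
    table = qsar.read_descriptor_csv(path)
    assert table.loc[0, "delta_logp"] == pytest.approx(8.358)
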
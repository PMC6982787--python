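import numpy as np
import pandas as pd
import pytest

from admetnet.evaluation import (fold_report, gse_consistency, gse_logS,
                                 metrics_frame, pearson_r, r2, rmse,
                                 spearman_rho)


def brute_r2(pred, obs):
    return 1 - sum((o - p) ** 2 for p, o in zip(pred, obs)) / \
        sum((o - np.mean(obs)) ** 2 for o in obs)


def brute_pearson(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return num / np.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))


def brute_spearman(x, y):
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ranks for ties
        for val in np.unique(v):
            sel = v == val
            r[sel] = r[sel].mean()
        return r
    return brute_pearson(ranks(np.asarray(x)), ranks(np.asarray(y)))


def test_r2_definition_examples():
    obs = np.array([0.0, 1.0, 2.0])
    assert r2(obs, obs) == pytest.approx(1.0)
    assert r2(np.full(3, obs.mean()), obs) == pytest.approx(0.0)
    # worse than the mean predictor: the coefficient goes negative
    assert r2(np.zeros(3), obs) == pytest.approx(-1.5)
    with pytest.raises(ValueError):
        r2(obs, np.ones(3))


def test_correlation_examples():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert spearman_rho(np.exp(obs), obs) == pytest.approx(1.0)   # monotone map
    assert spearman_rho(-obs, obs) == pytest.approx(-1.0)
    assert pearson_r(-obs, obs) == pytest.approx(-1.0)
    assert pearson_r([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(
        brute_pearson([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        pearson_r(np.ones(4), obs)
    with pytest.raises(ValueError):
        spearman_rho(np.ones(4), obs)


def test_metrics_match_brute_force_on_random_vectors():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = rng.integers(3, 30)
        pred, obs = rng.normal(size=n), rng.normal(size=n)
        assert r2(pred, obs) == pytest.approx(brute_r2(pred, obs), abs=1e-10)
        assert pearson_r(pred, obs) == pytest.approx(brute_pearson(pred, obs), abs=1e-10)
        assert spearman_rho(pred, obs) == pytest.approx(brute_spearman(pred, obs), abs=1e-10)
        assert rmse(pred, obs) == pytest.approx(
            np.sqrt(np.mean((pred - obs) ** 2)), abs=1e-10)


def test_spearman_handles_ties_with_average_ranks():
    pred = np.array([1.0, 1.0, 2.0, 3.0])
    obs = np.array([0.0, 1.0, 2.0, 3.0])
    assert spearman_rho(pred, obs) == pytest.approx(brute_spearman(pred, obs), abs=1e-12)


@pytest.mark.parametrize("lmp,logkow,expected", [
    (25.0, 0.0, 0.5),
    (125.0, 0.0, -0.5),
    (25.0, 2.0, -1.5),
])
def test_general_solubility_equation(lmp, logkow, expected):
    assert gse_logS(lmp, logkow) == pytest.approx(expected)


def test_gse_consistency_exact_surface():
    """Endpoints generated exactly on the GSE surface correlate perfectly."""
    rng = np.random.default_rng(2)
    lmp = rng.uniform(50, 250, size=200)
    logd = rng.uniform(-1, 5, size=200)
    logs = gse_logS(lmp, logd)
    audit = gse_consistency(lmp, logd, logs)
    assert audit.predicted == pytest.approx(1.0, abs=1e-12)


def test_gse_consistency_null_band():
    """Independent solubility: correlation within the Monte-Carlo null band."""
    rng = np.random.default_rng(3)
    n = 1000
    lmp, logd = rng.uniform(50, 250, n), rng.uniform(-1, 5, n)
    logs = rng.normal(-3, 1.5, n)
    audit = gse_consistency(lmp, logd, logs)
    assert abs(audit.predicted) < 4 / np.sqrt(n)


def test_gse_consistency_with_measurements_and_errors():
    rng = np.random.default_rng(4)
    lmp, logd = rng.uniform(50, 250, 50), rng.uniform(-1, 5, 50)
    logs = gse_logS(lmp, logd) + rng.normal(0, 0.1, 50)
    audit = gse_consistency(lmp, logd, logs, measured_lmp=lmp, measured_logd=logd,
                            measured_logs=logs)
    assert audit.measured == pytest.approx(audit.predicted)
    assert audit.anticorrelation <= audit.predicted
    with pytest.raises(ValueError):
        gse_consistency([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])


def test_fold_report_is_mean_of_per_fold_values():
    per_fold = pd.DataFrame({
        "endpoint": ["A", "A", "B", "B"], "fold": [0, 1, 0, 1],
        "r2": [0.5, 0.7, 0.2, 0.4], "spearman_rho": [0.6, 0.8, 0.3, 0.5],
        "pearson_r": [0.6, 0.8, 0.3, 0.5], "rmse": [1.0, 2.0, 3.0, 4.0]})
    report = fold_report(per_fold).set_index("endpoint")
    assert report.loc["A", "r2_mean"] == pytest.approx(0.6)
    assert report.loc["B", "rmse_mean"] == pytest.approx(3.5)
    assert report.loc["A", "r2_sd"] == pytest.approx(np.std([0.5, 0.7]))
    assert (report["n_folds"] == 2).all()


def test_metrics_frame_skips_underlabeled_tasks():
    pred = np.random.default_rng(0).normal(size=(10, 2))
    obs = pred + 0.1
    mask = np.ones((10, 2), bool)
    mask[2:, 1] = False  # only 2 labels in task 1
    frame = metrics_frame(pred, obs, mask, ["A", "B"])
    assert list(frame["endpoint"]) == ["A"]
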
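"""Prediction pipeline units: series construction, classifier, Firing Power, metrics."""

import numpy as np
import pytest

from evoseizure.features import FEATURE_NAMES, FeatureTensor
from evoseizure.genotype import (
    GeneDomains,
    HyperFeature,
    Individual,
    decode,
)
from evoseizure.predictor import (
    EXCLUDED,
    INTER_ICTAL,
    PRE_ICTAL,
    HyperFeatureSeries,
    LogisticModel,
    SeriesBuilder,
    add_lags,
    build_series,
    correlation_filter,
    evaluate_seizure,
    firing_power,
    fit_classifier,
    fitness,
    performance_score,
    trigger_alarms,
)


def make_tensor(n_minutes: int, fill, onset_s: float | None = None,
                electrodes=("T3", "C3")) -> FeatureTensor:
    """Tiny synthetic tensor: 12 five-second windows per minute."""
    n_win = n_minutes * 12
    values = np.zeros((n_win, len(electrodes), 12))
    values[:] = np.asarray(fill) if np.ndim(fill) else fill
    return FeatureTensor(
        values=values,
        feature_names=FEATURE_NAMES,
        electrode_labels=tuple(electrodes),
        window_start_times=5.0 * np.arange(n_win),
        degenerate=np.zeros((n_win, len(electrodes)), dtype=bool),
        seizure_onsets=np.asarray([onset_s] if onset_s else []),
    )


def make_individual(operator="mean", window=1, instants=(0, 0, 0, 0, 0),
                    electrode="T3", band="theta") -> Individual:
    return Individual(tuple(
        HyperFeature("band_wave", band, "average_power", operator, electrode, window, t)
        for t in instants
    ))


# ---------------------------------------------------------------------------
# build_series / add_lags


def test_constant_feature_gives_constant_mean_and_zero_variance():
    tensor = make_tensor(90, 3.25, onset_s=90 * 60.0)
    builder = SeriesBuilder(tensor)
    ph_mean = decode(make_individual("mean", window=5), 40)
    ph_var = decode(make_individual("variance", window=5), 40)
    s_mean = build_series(builder, ph_mean)
    s_var = build_series(builder, ph_var)
    assert np.allclose(s_mean.matrix, 3.25)
    assert np.allclose(s_var.matrix, 0.0)


def test_hand_aggregation_window_one_offset_zero():
    # hyper-feature at reference r = mean of the 12 five-second windows ending at r
    tensor = make_tensor(10, 0.0)
    x = np.arange(120, dtype=float)
    tensor.values[:, 0, tensor.feature_index("rp_theta")] = x
    builder = SeriesBuilder(tensor)
    series = build_series(builder, decode(make_individual("mean", window=1), 40))
    for i, r_minute in enumerate(series.times / 60.0):
        j = int(r_minute) * 12
        assert series.matrix[i, 0] == pytest.approx(x[j - 12 : j].mean())


def test_underfilled_windows_are_excluded():
    tensor = make_tensor(60, 1.0)
    builder = SeriesBuilder(tensor)
    ph = decode(make_individual("mean", window=10, instants=(5, 0, 0, 0, 0)), 40)
    series = build_series(builder, ph)
    # first usable reference = max(t+w) = 15 min
    assert series.times[0] == 15 * 60.0


def test_add_lags_column_count_and_alignment():
    tensor = make_tensor(30, 0.0)
    tensor.values[:, 0, 1] = np.repeat(np.arange(30, dtype=float), 12)
    builder = SeriesBuilder(tensor)
    series = build_series(builder, decode(make_individual("mean", window=1), 40))
    lagged = add_lags(series)
    assert lagged.matrix.shape[1] == 20
    assert lagged.n_rows == series.n_rows - 3
    base = series.matrix[:, 0]
    for lag in (1, 2, 3):
        col = 5 * lag  # first hyper-feature's lag-l column
        assert np.allclose(lagged.matrix[:, col], base[3 - lag : len(base) - lag])
    with pytest.raises(ValueError):
        add_lags(HyperFeatureSeries(series.times[:3], series.matrix[:3],
                                    series.labels[:3], series.column_meta))


# ---------------------------------------------------------------------------
# correlation filter


def test_correlation_filter_duplicates_negations_and_noise(rng):
    x = rng.standard_normal(500)
    y = rng.standard_normal(500)
    matrix = np.column_stack([x, x.copy(), -x, y])
    retained = correlation_filter(matrix)
    assert retained == [0, 3]
    noise = rng.standard_normal((2000, 8))
    assert correlation_filter(noise) == list(range(8))


def test_correlation_filter_drops_zero_variance_with_warning(rng):
    matrix = np.column_stack([np.ones(100), rng.standard_normal(100)])
    with pytest.warns(UserWarning):
        assert correlation_filter(matrix) == [1]


# ---------------------------------------------------------------------------
# logistic model


def test_zero_coefficients_give_probability_half(rng):
    model = LogisticModel(0.0, np.zeros(3), np.zeros(3), np.ones(3), [0, 1, 2])
    assert np.allclose(model.probabilities(rng.standard_normal((10, 3))), 0.5)


def test_logistic_probability_matches_hand_rolled_sigmoid(rng):
    beta0 = float(rng.normal())
    beta = rng.normal(size=4)
    mean, sd = rng.normal(size=4), np.abs(rng.normal(size=4)) + 0.1
    model = LogisticModel(beta0, beta, mean, sd, [0, 1, 2, 3])
    X = rng.normal(size=(50, 4))
    z = (X - mean) / sd
    expected = 1.0 / (1.0 + np.exp(-(beta0 + z @ beta)))
    assert np.allclose(model.probabilities(X), expected, atol=1e-12)


def test_fit_on_separable_toy_set_is_perfect():
    X = np.array([[0.0], [1.0], [10.0], [11.0], [10.5], [0.5]])
    y = np.array([0, 0, 1, 1, 1, 0], dtype=np.int8)
    model = fit_classifier(X, y)
    assert np.array_equal(model.predict(X), y)


def test_single_class_training_raises():
    with pytest.raises(ValueError):
        fit_classifier(np.ones((10, 2)), np.zeros(10, dtype=np.int8))


def test_class_weighting_matches_duplication(rng):
    # balanced class weights ~ duplicating the minority class
    x_major = rng.normal(0.0, 1.0, size=120)
    x_minor = rng.normal(3.0, 1.0, size=30)
    X = np.concatenate([x_major, x_minor])[:, None]
    y = np.concatenate([np.zeros(120), np.ones(30)]).astype(np.int8)
    model = fit_classifier(X, y)
    X_dup = np.concatenate([x_major, np.tile(x_minor, 4)])[:, None]
    y_dup = np.concatenate([np.zeros(120), np.ones(120)]).astype(np.int8)
    from sklearn.linear_model import LogisticRegression

    ref = LogisticRegression(C=1.0).fit(
        (X_dup - model.mean) / model.sd, y_dup
    )
    boundary = -model.intercept / model.coefficients[0]
    boundary_ref = -ref.intercept_[0] / ref.coef_[0][0]
    assert boundary == pytest.approx(boundary_ref, abs=0.15)


def test_z_score_parameters_come_from_training_rows_only():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(100, 2))
    y = (X[:, 0] > 0).astype(np.int8)
    y[:10] = EXCLUDED  # excluded rows must not influence the scaler
    model = fit_classifier(X, y)
    train = y != EXCLUDED
    expected_mean = X[train][:, model.retained_columns].mean(axis=0)
    assert np.allclose(model.mean, expected_mean)


# ---------------------------------------------------------------------------
# firing power + alarms


def test_firing_power_basics():
    assert np.allclose(firing_power(np.ones(30), 10), 1.0)
    fp = firing_power(np.tile([0, 1], 20), 10)
    assert np.allclose(fp[9:], 0.5)
    fp0 = firing_power(np.zeros(40), 10)
    assert np.allclose(fp0, 0.0)
    assert trigger_alarms(fp0, 60.0 * np.arange(1, 41)).alarm_times.size == 0


def test_firing_power_matches_brute_force_moving_mean(rng):
    outputs = rng.integers(0, 2, size=200)
    w = 37
    fp = firing_power(outputs, w)
    brute = np.array([outputs[max(0, i - w + 1) : i + 1].mean() for i in range(200)])
    assert np.allclose(fp, brute, atol=1e-12)


def test_alarms_fire_at_upward_crossings_only():
    fp = np.array([0.69] * 10)
    times = 60.0 * np.arange(1, 11)
    assert trigger_alarms(fp, times).alarm_times.size == 0
    fp = np.array([0.5, 0.6, 0.75, 0.8, 0.6, 0.9])
    train = trigger_alarms(fp, 60.0 * np.arange(1, 7))
    assert list(train.alarm_times) == [3 * 60.0, 6 * 60.0]


def test_refractory_suppresses_second_crossing():
    # two crossings 10 min apart, 55-min refractory -> a single alarm
    fp = np.zeros(80)
    fp[10:12] = 0.8
    fp[20:22] = 0.8
    times = 60.0 * np.arange(1, 81)
    train = trigger_alarms(fp, times, refractory_minutes=55)
    assert len(train.alarm_times) == 1
    assert train.refractory_intervals[0][1] - train.refractory_intervals[0][0] == 55 * 60


# ---------------------------------------------------------------------------
# metrics and fitness


def test_performance_composite_examples():
    assert performance_score(1, 1, 0, 0) == 1.0
    assert performance_score(0, 0, 0, 0) == 0.0
    assert performance_score(0.8, 1, 0.1, 0.2) == pytest.approx(0.68)


def test_performance_bounded_above_by_one(rng):
    for _ in range(200):
        s_s, s_p, t_f = rng.uniform(0, 1, 3)
        fpr = rng.uniform(0, 5)
        assert performance_score(s_s, s_p, t_f, fpr) <= 1.0


def _planted_builder(onset_minutes=240, electrodes=("T3", "C3")):
    """Tensor whose theta power on T3 jumps during the pre-ictal period."""
    rng = np.random.default_rng(3)
    tensor = make_tensor(onset_minutes, 0.0, onset_s=onset_minutes * 60.0,
                         electrodes=electrodes)
    n_win = tensor.values.shape[0]
    tensor.values[:, :, :] = rng.normal(0.2, 0.02, size=tensor.values.shape)
    onset = onset_minutes * 60.0
    windows_pre = (tensor.window_start_times >= onset - 50 * 60.0)
    tensor.values[windows_pre, 0, tensor.feature_index("rp_theta")] += 0.3
    return SeriesBuilder(tensor)


def test_fitness_two_segments_equals_single_split_and_is_cached():
    builders = [_planted_builder(), _planted_builder()]
    ind = make_individual("mean", window=5)
    value = fitness(ind, builders, 40)
    # k = 2 -> exactly the performance of evaluating segment 2
    ph = decode(ind, 40)
    from evoseizure.predictor import fit_on_segments

    model = fit_on_segments(builders[:1], ph)
    series = add_lags(build_series(builders[1], ph))
    metrics = evaluate_seizure(series, model, ph, 240 * 60.0)
    assert value == pytest.approx(metrics.performance)
    assert fitness(ind, builders, 40) == value  # deterministic re-evaluation
    assert value > 0.5  # planted signal is learnable


def test_fitness_requires_two_segments():
    with pytest.raises(ValueError):
        fitness(make_individual(), [_planted_builder()], 40)


def test_degenerate_individual_gets_sentinel_fitness():
    # constant features -> zero-variance columns -> no usable design
    builders = [SeriesBuilder(make_tensor(240, 1.0, onset_s=240 * 60.0)),
                SeriesBuilder(make_tensor(240, 1.0, onset_s=240 * 60.0))]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert fitness(make_individual(), builders, 40) == -10.0


def test_evaluate_seizure_label_spans():
    builder = _planted_builder()
    ph = decode(make_individual("mean", window=5), 40)
    series = add_lags(build_series(builder, ph))
    onset = 240 * 60.0
    pre = series.labels == PRE_ICTAL
    inter = series.labels == INTER_ICTAL
    assert series.times[pre].min() >= onset - 40 * 60.0
    assert series.times[pre].max() < onset - 10 * 60.0
    assert series.times[inter].max() < onset - 40 * 60.0
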
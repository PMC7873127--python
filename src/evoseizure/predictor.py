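"""Prediction pipeline: hyper-feature series, logistic classifier, Firing Power.

Given a decoded phenotype and a first-level :class:`~evoseizure.features.FeatureTensor`,
this module

1. builds each hyper-feature's 1-min time series by sliding the configured
   aggregation window over the 5-s first-level feature stream (offset by the
   hyper-feature's time instant),
2. appends lagged copies (lags 1-3 min) so the static classifier sees short
   temporal context,
3. drops redundant columns (|Pearson rho| > 0.95, greedy left-to-right),
4. z-scores with training statistics and fits a class-weighted logistic
   regression (weights inversely proportional to class frequency),
5. regularises the binary output stream with the Firing Power — a trailing
   moving average with window equal to the pre-ictal duration — and raises
   alarms at upward crossings of a 0.70 threshold,
6. scores each evaluated seizure with the composite

   ``performance = (S_s + S_p) * 0.5 - FPR/h * (1 + T_f)``

   which equals 1 exactly for a perfect prediction (every pre-ictal sample
   classified pre-ictal, the seizure predicted, no inter-ictal sample
   misclassified and no false alarm).

Sample metrics (``S_s``, ``T_f``) are computed on the raw classifier outputs
(p > 0.5); alarm metrics (``S_p``, FPR/h) on the Firing-Power alarm train.
During prospective testing a refractory period of SOP+SPH follows each alarm
and is excluded from the FPR/h denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .features import FeatureTensor
from .genotype import Individual, Phenotype, decode

#: Label codes on the 1-min grid.
INTER_ICTAL, PRE_ICTAL, EXCLUDED = 0, 1, -1

#: Firing-Power alarm threshold.
FP_THRESHOLD = 0.70

#: Guard after a seizure onset excluded from both classes, minutes.
POST_ICTAL_GUARD_MINUTES = 30

#: Fitness assigned to individuals whose model cannot be fitted.
FITNESS_SENTINEL = -10.0

#: Default lags (minutes) appended to each hyper-feature column.
LAGS = (1, 2, 3)

_WINDOWS_PER_MINUTE = 12  # 5-s windows per 1-min grid step

_OPERATORS = {
    "mean": np.mean,
    "median": np.median,
    "variance": np.var,
    "max": np.max,
    "min": np.min,
}


@dataclass
class HyperFeatureSeries:
    """Hyper-feature design matrix on the 1-min reference grid.

    ``times[i]`` is the reference time (seconds from segment start) of row
    ``i``; rows whose aggregation windows (or lags) would reach before the
    start of the data are excluded, so the retained grid is a contiguous
    suffix.  ``labels`` uses ``PRE_ICTAL`` / ``INTER_ICTAL`` / ``EXCLUDED``;
    the SPH and a 30-min post-onset guard are excluded from both classes.
    ``column_meta[j] = (hyper_feature_index, lag_minutes)``.
    """

    times: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    column_meta: tuple[tuple[int, int], ...]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


class SeriesBuilder:
    """Caches hyper-feature columns for one segment's feature tensor.

    The same (feature, electrode, operator, window, instant) tuple recurs
    thousands of times across a GA run; each decoded column is computed once
    per segment and memoised.
    """

    def __init__(self, tensor: FeatureTensor):
        self.tensor = tensor
        self.n_minutes = (tensor.n_windows * 5) // 60
        self._cache: dict[tuple, np.ndarray] = {}

    def column(self, feature: str, electrode: str, operator: str,
               window_minutes: int, offset_minutes: int) -> np.ndarray:
        """The hyper-feature value at each grid minute ``m`` (1-based; NaN where
        the aggregation window would reach before the record start).

        At reference time ``r = 60 m`` the value is the operator applied to the
        5-s feature stream over ``[r - (t + w) * 60, r - t * 60)``.
        """
        key = (feature, electrode, operator, window_minutes, offset_minutes)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        x = self.tensor.values[
            :, self.tensor.electrode_index(electrode), self.tensor.feature_index(feature)
        ]
        length = window_minutes * _WINDOWS_PER_MINUTE
        op = _OPERATORS[operator]
        col = np.full(self.n_minutes, np.nan)
        if len(x) >= length:
            agg = op(sliding_window_view(x, length)[::_WINDOWS_PER_MINUTE], axis=-1)
            first_m = offset_minutes + window_minutes  # earliest fully-covered minute
            usable = min(len(agg), self.n_minutes - first_m + 1)
            if usable > 0:
                col[first_m - 1 : first_m - 1 + usable] = agg[:usable]
        self._cache[key] = col
        return col


def _grid_labels(n_minutes: int, onsets: np.ndarray, pre_ictal_minutes: int,
                 sph_minutes: int) -> np.ndarray:
    times = 60.0 * np.arange(1, n_minutes + 1)
    labels = np.full(n_minutes, INTER_ICTAL, dtype=np.int8)
    for onset in np.atleast_1d(onsets):
        pre = (times >= onset - 60 * pre_ictal_minutes) & (times < onset - 60 * sph_minutes)
        guard = (times >= onset - 60 * sph_minutes) & (
            times <= onset + 60 * POST_ICTAL_GUARD_MINUTES
        )
        labels[pre] = PRE_ICTAL
        labels[guard] = EXCLUDED
    return labels


def build_series(builder: SeriesBuilder, phenotype: Phenotype) -> HyperFeatureSeries:
    """Base design: one column per hyper-feature on the 1-min grid (no lags)."""
    cols = [
        builder.column(r.feature, r.electrode, r.operator, r.window_minutes, r.offset_minutes)
        for r in phenotype.recipes
    ]
    matrix = np.column_stack(cols)
    labels = _grid_labels(
        builder.n_minutes, builder.tensor.seizure_onsets,
        phenotype.pre_ictal_minutes, phenotype.sph_minutes,
    )
    valid = ~np.isnan(matrix).any(axis=1)
    times = 60.0 * np.arange(1, builder.n_minutes + 1)
    meta = tuple((i, 0) for i in range(len(cols)))
    return HyperFeatureSeries(times[valid], matrix[valid], labels[valid], meta)


def add_lags(series: HyperFeatureSeries, lags: tuple[int, ...] = LAGS) -> HyperFeatureSeries:
    """Append lagged copies of every column; the first ``max(lags)`` rows drop out.

    With the default lags (1, 2, 3 min) the 5 base columns become 20.
    """
    max_lag = max(lags)
    if series.n_rows <= max_lag:
        raise ValueError(f"series of {series.n_rows} rows is too short for lag {max_lag}")
    blocks = [series.matrix[max_lag:]]
    meta = list(series.column_meta)
    for lag in lags:
        blocks.append(series.matrix[max_lag - lag : series.n_rows - lag])
        meta.extend((hf, lag) for hf, _ in series.column_meta)
    return HyperFeatureSeries(
        series.times[max_lag:], np.hstack(blocks), series.labels[max_lag:], tuple(meta)
    )


def correlation_filter(matrix: np.ndarray, threshold: float = 0.95) -> list[int]:
    """Greedy left-to-right redundancy filter.

    A column is dropped iff its |Pearson rho| with any already-retained column
    exceeds ``threshold``; zero-variance columns are dropped with a warning
    (their correlation is undefined).
    """
    n = matrix.shape[1]
    sd = matrix.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("dropping zero-variance column(s) from the design", stacklevel=2)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    retained: list[int] = []
    for j in range(n):
        if degenerate[j]:
            continue
        if all(abs(corr[j, k]) <= threshold for k in retained):
            retained.append(j)
    return retained


@dataclass
class LogisticModel:
    """Fitted classifier plus the preprocessing state needed to apply it."""

    intercept: float
    coefficients: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    retained_columns: list[int]
    column_meta: tuple[tuple[int, int], ...] = ()

    def probabilities(self, matrix: np.ndarray) -> np.ndarray:
        """Pre-ictal probability per row (logistic of the linear predictor)."""
        from scipy.special import expit

        z = (matrix[:, self.retained_columns] - self.mean) / self.sd
        return expit(self.intercept + z @ self.coefficients)

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Raw binary outputs (p > 0.5)."""
        return (self.probabilities(matrix) > 0.5).astype(np.int8)


def fit_classifier(matrix: np.ndarray, labels: np.ndarray,
                   column_meta: tuple[tuple[int, int], ...] = ()) -> LogisticModel:
    """Class-weighted logistic regression on z-scored, redundancy-filtered columns.

    Class weights are inversely proportional to class frequency,
    ``w_c = N / (2 N_c)``; z-score statistics come from the training rows
    only, so applying the model to test data leaks nothing.
    """
    train = labels != EXCLUDED
    X, y = matrix[train], labels[train]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    retained = correlation_filter(X)
    if not retained:
        raise ValueError("no columns survive the redundancy filter")
    Xr = X[:, retained]
    mean, sd = Xr.mean(axis=0), Xr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(
            C=1.0, class_weight="balanced", solver="lbfgs", max_iter=200
        ).fit((Xr - mean) / sd, y)
    return LogisticModel(
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].copy(),
        mean=mean,
        sd=sd,
        retained_columns=retained,
        column_meta=column_meta,
    )


# ---------------------------------------------------------------------------
# Firing Power and alarms


def firing_power(outputs: np.ndarray, pre_ictal_minutes: int) -> np.ndarray:
    """Trailing moving average of the binary outputs over ``pre_ictal_minutes``
    samples (1-min grid); during warm-up the mean over the available samples
    is emitted so the stream is defined from the first sample.
    """
    x = np.asarray(outputs, dtype=float)
    w = int(pre_ictal_minutes)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - w, 0)
    return (csum[idx] - csum[lo]) / (idx - lo)


@dataclass
class AlarmTrain:
    """Alarm times (seconds) plus the Firing-Power stream that produced them."""

    firing_power: np.ndarray
    times: np.ndarray
    alarm_times: np.ndarray
    refractory_intervals: tuple[tuple[float, float], ...] = ()


def trigger_alarms(fp: np.ndarray, times: np.ndarray, threshold: float = FP_THRESHOLD,
                   refractory_minutes: float | None = None) -> AlarmTrain:
    """Alarms at upward crossings of ``threshold``.

    Without a refractory period (fitness mode) the detector re-arms once the
    stream falls back to or below the threshold.  With one (testing mode),
    alarms are suppressed for ``refractory_minutes`` after each alarm and the
    detector re-arms at expiry; suppressed intervals are recorded.
    """
    fp = np.asarray(fp, dtype=float)
    times = np.asarray(times, dtype=float)
    alarms: list[float] = []
    intervals: list[tuple[float, float]] = []
    armed = True
    refractory_until = -np.inf
    for t, value in zip(times, fp):
        if refractory_minutes is not None and t < refractory_until:
            continue
        if value > threshold:
            if armed:
                alarms.append(t)
                if refractory_minutes is not None:
                    refractory_until = t + 60.0 * refractory_minutes
                    intervals.append((t, refractory_until))
                else:
                    armed = False
        else:
            armed = True
    return AlarmTrain(fp, times, np.asarray(alarms), tuple(intervals))


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class PerformanceMetrics:
    """Per-seizure evaluation summary; ``performance`` is the composite score."""

    s_s: float
    s_p: float
    t_f: float
    fpr_h: float
    performance: float = field(init=False)

    def __post_init__(self) -> None:
        self.performance = performance_score(self.s_s, self.s_p, self.t_f, self.fpr_h)


def performance_score(s_s: float, s_p: float, t_f: float, fpr_h: float) -> float:
    """Composite seizure-prediction score; 1 iff prediction is perfect."""
    return (s_s + s_p) * 0.5 - fpr_h * (1.0 + t_f)


def _in_pre_ictal(t: np.ndarray, onset: float, pre_ictal_minutes: int, sph_minutes: int):
    return (t >= onset - 60 * pre_ictal_minutes) & (t < onset - 60 * sph_minutes)


def evaluate_seizure(series: HyperFeatureSeries, model: LogisticModel,
                     phenotype: Phenotype, onset: float,
                     refractory: bool = False) -> PerformanceMetrics:
    """Evaluate one seizure's segment (single onset) with the fitted model."""
    outputs = model.predict(series.matrix)
    metrics, _ = _score(series, outputs, phenotype, np.array([onset]), refractory)
    return metrics[0]


def _score(series: HyperFeatureSeries, outputs: np.ndarray, phenotype: Phenotype,
           onsets: np.ndarray, refractory: bool):
    """Shared scoring: sample metrics from raw outputs, alarm metrics from FP."""
    labels, times = series.labels, series.times
    pre_rows = labels == PRE_ICTAL
    inter_rows = labels == INTER_ICTAL
    if not inter_rows.any():
        raise ValueError("no inter-ictal rows to evaluate")
    s_s = float(outputs[pre_rows].mean()) if pre_rows.any() else 0.0
    t_f = float(outputs[inter_rows].mean())

    fp = firing_power(outputs, phenotype.pre_ictal_minutes)
    refractory_minutes = (
        phenotype.sop_minutes + phenotype.sph_minutes if refractory else None
    )
    train = trigger_alarms(fp, times, refractory_minutes=refractory_minutes)

    onsets = np.atleast_1d(onsets)
    predicted = np.zeros(len(onsets))
    in_any_pre = np.zeros(len(train.alarm_times), dtype=bool)
    for i, onset in enumerate(onsets):
        hits = _in_pre_ictal(train.alarm_times, onset, phenotype.pre_ictal_minutes,
                             phenotype.sph_minutes)
        predicted[i] = 1.0 if hits.any() else 0.0
        in_any_pre |= hits
    n_false = int((~in_any_pre).sum())

    inter_times = times[inter_rows]
    if refractory and train.refractory_intervals:
        blocked = np.zeros(len(inter_times), dtype=bool)
        for lo, hi in train.refractory_intervals:
            blocked |= (inter_times > lo) & (inter_times <= hi)
        inter_hours = float((~blocked).sum()) / 60.0
    else:
        inter_hours = float(len(inter_times)) / 60.0
    fpr_h = n_false / inter_hours if inter_hours > 0 else 0.0

    per_seizure = [
        PerformanceMetrics(s_s=s_s, s_p=float(p), t_f=t_f, fpr_h=fpr_h) for p in predicted
    ]
    return per_seizure, train


# ---------------------------------------------------------------------------
# Fitness and prospective testing


def _training_design(builders: list[SeriesBuilder], phenotype: Phenotype):
    parts = [add_lags(build_series(b, phenotype)) for b in builders]
    matrix = np.vstack([p.matrix for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    return matrix, labels, parts[0].column_meta


def fit_on_segments(builders: list[SeriesBuilder], phenotype: Phenotype) -> LogisticModel:
    matrix, labels, meta = _training_design(builders, phenotype)
    return fit_classifier(matrix, labels, column_meta=meta)


def fitness(ind: Individual, builders: list[SeriesBuilder], min_preictal: int) -> float:
    """Iterative-retraining fitness: for each seizure j >= 2, train on seizures
    1..j-1 and evaluate seizure j (no refractory); fitness is the mean
    composite performance.  Individuals whose model cannot be fitted receive
    the sentinel minimum so the GA discards them.
    """
    if len(builders) < 2:
        raise ValueError("fitness needs at least 2 training seizures")
    phenotype = decode(ind, min_preictal)
    scores = []
    try:
        for j in range(1, len(builders)):
            model = fit_on_segments(builders[:j], phenotype)
            series = add_lags(build_series(builders[j], phenotype))
            onset = float(builders[j].tensor.seizure_onsets[-1])
            metrics = evaluate_seizure(series, model, phenotype, onset)
            scores.append(metrics.performance)
    except ValueError:
        return FITNESS_SENTINEL
    return float(np.mean(scores))


@dataclass
class TestResult:
    """Prospective evaluation of one individual on the continuous test record."""

    per_seizure: list[PerformanceMetrics]
    alarm_train: AlarmTrain
    phenotype: Phenotype
    model: LogisticModel
    record_extent: float
    onsets: np.ndarray

    @property
    def sensitivities(self) -> np.ndarray:
        return np.asarray([m.s_p for m in self.per_seizure])

    @property
    def s_p(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def fpr_h(self) -> float:
        return self.per_seizure[0].fpr_h


def evaluate_test(ind: Individual, train_builders: list[SeriesBuilder],
                  test_builder: SeriesBuilder, min_preictal: int) -> TestResult:
    """Train on all training seizures, then evaluate the continuous test record
    prospectively with SOP+SPH refractory alarms.
    """
    phenotype = decode(ind, min_preictal)
    model = fit_on_segments(train_builders, phenotype)
    series = add_lags(build_series(test_builder, phenotype))
    outputs = model.predict(series.matrix)
    onsets = np.atleast_1d(test_builder.tensor.seizure_onsets)
    per_seizure, alarm_train = _score(series, outputs, phenotype, onsets, refractory=True)
    return TestResult(
        per_seizure=per_seizure,
        alarm_train=alarm_train,
        phenotype=phenotype,
        model=model,
        record_extent=test_builder.n_minutes * 60.0,
        onsets=onsets,
    )
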
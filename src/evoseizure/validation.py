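"""Statistical validation: surrogate predictor, above-chance test, binomial count.

The surrogate predictor estimates the chance level of a fixed alarm train by
Monte-Carlo shifting of the seizure onset times: the alarms stay exactly
where the real evaluation produced them, only the onsets move (uniformly over
the placements that keep the shifted pre-ictal window fully inside the
record), and the seizure sensitivity is re-scored against the shifted
windows.  An execution performs above chance when its real sensitivities beat
the surrogate repetitions in a one-tailed Welch t-test at alpha = 0.01.

Across a set of executions, the count that individually beat the surrogate is
itself tested against a binomial null:

    P(i, I, alpha) = sum_{j=i}^{I} C(I, j) alpha^j (1 - alpha)^(I - j)

evaluated at alpha = 0.05; the set is significant when P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .predictor import TestResult


@dataclass
class SurrogateResult:
    """Per-repetition surrogate seizure sensitivities for one alarm train."""

    sensitivities: np.ndarray
    n_repetitions: int

    @property
    def mean(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def sd(self) -> float:
        return float(self.sensitivities.std(ddof=1)) if self.n_repetitions > 1 else 0.0


@dataclass
class ValidationReport:
    per_execution_flags: list[bool]
    per_execution_p: list[float]
    overall_flag: bool
    overall_p: float
    ratio_above_chance: float
    binomial_p: float
    binomial_significant: bool


def surrogate_sensitivity(alarm_times: np.ndarray, onsets: np.ndarray,
                          record_extent: float, pre_ictal_minutes: int,
                          sph_minutes: int, rng: np.random.Generator,
                          n_reps: int = 30) -> SurrogateResult:
    """Chance-level sensitivity of a fixed alarm train under shifted onsets.

    Each repetition draws, per seizure, a surrogate onset uniformly over
    ``[pre_ictal, record_extent]`` seconds so the shifted pre-ictal window
    ``[onset - pre_ictal, onset - SPH)`` lies fully inside the record, and
    scores the fraction of surrogate seizures with at least one alarm inside
    their window.
    """
    alarm_times = np.asarray(alarm_times, dtype=float)
    onsets = np.atleast_1d(onsets)
    pre = 60.0 * pre_ictal_minutes
    sph = 60.0 * sph_minutes
    if record_extent <= pre:
        raise ValueError(
            f"record of {record_extent:.0f} s cannot hold a {pre:.0f}-s pre-ictal window"
        )
    shifted = rng.uniform(pre, record_extent, size=(n_reps, len(onsets)))
    if alarm_times.size:
        hit = (
            (alarm_times[None, None, :] >= shifted[..., None] - pre)
            & (alarm_times[None, None, :] < shifted[..., None] - sph)
        ).any(axis=-1)
    else:
        hit = np.zeros(shifted.shape, dtype=bool)
    return SurrogateResult(hit.mean(axis=1), n_reps)


def surrogate_for_result(result: TestResult, rng: np.random.Generator,
                         n_reps: int = 30) -> SurrogateResult:
    """Surrogate repetitions for a prospective :class:`TestResult`."""
    return surrogate_sensitivity(
        result.alarm_train.alarm_times,
        result.onsets,
        result.record_extent,
        result.phenotype.pre_ictal_minutes,
        result.phenotype.sph_minutes,
        rng,
        n_reps=n_reps,
    )


def above_chance_test(real_sensitivities: np.ndarray, surrogate: SurrogateResult,
                      alpha: float = 0.01) -> tuple[bool, float]:
    """One-tailed Welch t-test of real vs surrogate sensitivities.

    Returns ``(flag, p)`` with ``flag`` true iff p < alpha *and* the real mean
    exceeds the surrogate mean.  Degenerate cases: when both groups have zero
    variance the comparison falls back to an exact comparison of means
    (p = 0 or 1); when only the *real* group is constant (e.g. every test
    seizure predicted), the t statistic would treat its mean as certain, so
    the p-value is instead the exact Monte-Carlo exceedance
    ``(1 + #{surrogate >= real mean}) / (n_reps + 1)`` — the standard
    surrogate-data rank test, conservative for small seizure counts.
    """
    real = np.atleast_1d(np.asarray(real_sensitivities, dtype=float))
    surr = surrogate.sensitivities
    if real.size < 2 or surr.size < 2:
        raise ValueError("above-chance test needs >= 2 observations per group")
    if real.std() == 0 and surr.std() == 0:
        p = 0.0 if real.mean() > surr.mean() else 1.0
    elif real.std() == 0:
        p = float(1 + (surr >= real.mean()).sum()) / (surr.size + 1)
    else:
        p = float(stats.ttest_ind(real, surr, equal_var=False, alternative="greater").pvalue)
    flag = bool(p < alpha and real.mean() > surr.mean())
    return flag, p


def binomial_prob(i: int, n_total: int, alpha: float) -> float:
    """Probability of observing at least ``i`` successes out of ``n_total``
    under a per-trial success probability ``alpha``.
    """
    if not (0 <= i <= n_total):
        raise ValueError(f"need 0 <= i <= {n_total}, got {i}")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    return float(stats.binom.sf(i - 1, n_total, alpha))


def validate_patient(real_sensitivities: list[np.ndarray],
                     surrogates: list[SurrogateResult],
                     exec_alpha: float = 0.01,
                     binom_alpha: float = 0.05) -> ValidationReport:
    """Both statistical validations over a set of executions.

    ``real_sensitivities[k]`` holds execution k's per-seizure test
    sensitivities and ``surrogates[k]`` its matched surrogate repetitions.
    The overall flag compares per-execution mean sensitivities against
    per-execution surrogate means with the same one-tailed test; the count of
    individually-flagged executions is checked against the binomial null.
    """
    if len(real_sensitivities) != len(surrogates):
        raise ValueError("one surrogate result is required per execution")
    flags, ps = [], []
    for real, surr in zip(real_sensitivities, surrogates):
        flag, p = above_chance_test(real, surr, alpha=exec_alpha)
        flags.append(flag)
        ps.append(p)

    real_means = np.asarray([np.mean(r) for r in real_sensitivities])
    surr_means = np.asarray([s.mean for s in surrogates])
    pooled = SurrogateResult(surr_means, len(surr_means))
    overall_flag, overall_p = above_chance_test(real_means, pooled, alpha=exec_alpha)

    n_above = int(sum(flags))
    binom_p = binomial_prob(n_above, len(flags), binom_alpha) if n_above > 0 else 1.0
    return ValidationReport(
        per_execution_flags=flags,
        per_execution_p=ps,
        overall_flag=overall_flag,
        overall_p=overall_p,
        ratio_above_chance=n_above / len(flags),
        binomial_p=binom_p,
        binomial_significant=bool(binom_p < binom_alpha),
    )
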
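"""End-to-end orchestration: data -> features -> evolution -> testing -> reports.

This module wires the stages together for programmatic use; the command-line
interface in :mod:`evoseizure.cli` is a thin wrapper around it.  A *run*
on one synthetic (or loaded) patient comprises:

1. filter + segment every record and extract the first-level feature tensors;
2. run the configured number of GA executions on the training seizures;
3. evaluate each execution's best individual prospectively on the continuous
   test record (refractory alarms);
4. score each alarm train against its surrogate predictor and produce the
   two-level validation report;
5. aggregate the phenotype report over the best individuals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

from . import __version__
from .features import FeatureTensor, extract_all
from .ga import ExecutionResult, GAConfig, run_patient
from .genotype import GeneDomains, Individual, random_individual
from .predictor import SeriesBuilder, TestResult, evaluate_test, fitness
from .recording import EEGRecording, filter_recording, segment
from .synthetic import PatientDataset
from .validation import SurrogateResult, ValidationReport, surrogate_for_result, validate_patient

#: Seed offset separating the surrogate stream from the GA stream.
_SURROGATE_STREAM = 101


def tensor_for(record: EEGRecording) -> FeatureTensor:
    """Filter, segment and extract first-level features for one record."""
    return extract_all(segment(filter_recording(record)))


def builders_for(dataset: PatientDataset) -> tuple[list[SeriesBuilder], SeriesBuilder]:
    """Series builders for the training segments and the test record."""
    train = [SeriesBuilder(tensor_for(rec)) for rec in dataset.train_records]
    test = SeriesBuilder(tensor_for(dataset.test_record))
    return train, test


@dataclass
class FullRunResult:
    executions: list[ExecutionResult]
    test_results: list[TestResult]
    surrogates: list[SurrogateResult]
    validation: ValidationReport
    phenotype_report: object
    min_preictal: int


def make_fitness(train_builders: list[SeriesBuilder], min_preictal: int):
    def fitness_fn(ind: Individual) -> float:
        return fitness(ind, train_builders, min_preictal)

    return fitness_fn


def evaluate_executions(
    executions: list[ExecutionResult],
    train_builders: list[SeriesBuilder],
    test_builder: SeriesBuilder,
    min_preictal: int,
    seed: int,
    surrogate_reps: int = 30,
) -> tuple[list[TestResult], list[SurrogateResult]]:
    """Prospective test + surrogate scoring for each execution's best individual."""
    test_results, surrogates = [], []
    for i, execution in enumerate(executions):
        result = evaluate_test(
            execution.best_individual, train_builders, test_builder, min_preictal
        )
        rng = np.random.default_rng(
            np.random.SeedSequence((seed, _SURROGATE_STREAM, i))
        )
        surrogates.append(surrogate_for_result(result, rng, n_reps=surrogate_reps))
        test_results.append(result)
    return test_results, surrogates


def phenotype_from_executions(
    executions: list[ExecutionResult],
    train_builders: list[SeriesBuilder],
    min_preictal: int,
    elite_k: int = 10,
):
    """Phenotype report over the executions' elite individuals.

    Each execution contributes its top ``elite_k`` distinct genotypes (the
    paper-style study aggregates 30 best-of-execution individuals; at reduced
    execution counts the final-population elite plays that role).  Every
    individual is paired with its deployed model — the classifier refitted on
    all training seizures.
    """
    from .genotype import decode
    from .phenotype import aggregate_report
    from .predictor import fit_on_segments

    individuals, models = [], []
    for execution in executions:
        for ind in execution.elite(elite_k):
            try:
                model = fit_on_segments(train_builders, decode(ind, min_preictal))
            except ValueError:
                continue
            individuals.append(ind)
            models.append(model)
    return aggregate_report(individuals, models, min_preictal=min_preictal)


def run_full(
    dataset: PatientDataset,
    ga_config: GAConfig,
    min_preictal: int = 40,
    domains: GeneDomains | None = None,
    surrogate_reps: int = 30,
) -> FullRunResult:
    """The whole pipeline on one patient (see module docstring)."""
    domains = domains or GeneDomains(electrodes=dataset.test_record.channel_labels)
    train_builders, test_builder = builders_for(dataset)
    executions = run_patient(
        ga_config, make_fitness(train_builders, min_preictal), domains
    )
    test_results, surrogates = evaluate_executions(
        executions, train_builders, test_builder, min_preictal,
        seed=ga_config.seed, surrogate_reps=surrogate_reps,
    )
    validation = validate_patient(
        [r.sensitivities for r in test_results], surrogates
    )
    report = phenotype_from_executions(executions, train_builders, min_preictal)
    return FullRunResult(executions, test_results, surrogates, validation, report, min_preictal)


def null_execution(
    train_builders: list[SeriesBuilder],
    test_builder: SeriesBuilder,
    min_preictal: int,
    seed: int,
    domains: GeneDomains | None = None,
    surrogate_reps: int = 30,
) -> tuple[TestResult, SurrogateResult, bool]:
    """One calibration execution: a random individual (no evolution) trained,
    tested prospectively and scored against its surrogate.  Used to measure
    the false-flag rate of the above-chance test on signal-free data.
    """
    from .validation import above_chance_test

    rng = np.random.default_rng(seed)
    domains = domains or GeneDomains(electrodes=test_builder.tensor.electrode_labels)
    result = None
    for _ in range(20):  # rare degenerate genotypes (unfittable design) are redrawn
        ind = random_individual(domains, rng)
        try:
            result = evaluate_test(ind, train_builders, test_builder, min_preictal)
            break
        except ValueError:
            continue
    if result is None:
        raise RuntimeError("could not draw a fittable individual in 20 attempts")
    surrogate = surrogate_for_result(result, rng, n_reps=surrogate_reps)
    flag, _ = above_chance_test(result.sensitivities, surrogate)
    return result, surrogate, flag


# ---------------------------------------------------------------------------
# Result persistence (used by the CLI)


def manifest(config_blob: dict, seed: int) -> dict:
    canonical = yaml.safe_dump(config_blob, sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }


def results_table(test_results: list[TestResult]) -> "object":
    import pandas as pd

    rows = []
    for i, result in enumerate(test_results):
        for j, metrics in enumerate(result.per_seizure):
            rows.append(
                {
                    "execution": i,
                    "seizure_id": j,
                    "S_s": metrics.s_s,
                    "S_p": metrics.s_p,
                    "T_f": metrics.t_f,
                    "FPR_h": metrics.fpr_h,
                    "performance": metrics.performance,
                }
            )
    return pd.DataFrame(rows)


def alarms_table(test_results: list[TestResult]) -> "object":
    import pandas as pd

    rows = []
    for i, result in enumerate(test_results):
        predicted_windows = [
            (
                onset - 60.0 * result.phenotype.pre_ictal_minutes,
                onset - 60.0 * result.phenotype.sph_minutes,
            )
            for onset in result.onsets
        ]
        for t in result.alarm_train.alarm_times:
            hit = any(lo <= t < hi for lo, hi in predicted_windows)
            rows.append({"execution": i, "time_s": float(t), "seizure_predicted_flag": int(hit)})
    return pd.DataFrame(rows)


def validation_json(validation: ValidationReport) -> str:
    return json.dumps(
        {
            "per_execution_flags": [bool(f) for f in validation.per_execution_flags],
            "per_execution_p": validation.per_execution_p,
            "overall_flag": validation.overall_flag,
            "overall_p": validation.overall_p,
            "ratio_above_chance": validation.ratio_above_chance,
            "binomial_p": validation.binomial_p,
            "binomial_significant": validation.binomial_significant,
        },
        indent=1,
    )
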
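"""Phenotype study: presence and predictive power of gene values.

Because the GA is stochastic, repeated executions yield different solutions
of similar quality; the phenotype study summarises what those solutions have
in common.  For each *expressed* gene dimension — decoded feature, operator,
electrode, lobe, hemisphere, window length and time instant — it reports

* **presence**: each hyper-feature contributes an indicator for the value it
  carries; per-individual vectors are normalized to sum to 1;
* **predictive power**: each hyper-feature is weighted by the mean absolute
  logistic-regression coefficient over its retained (lagged) design columns;
  a gene value's score is the summed weight of the hyper-features carrying
  it, normalized per dimension.

Non-expressed feature genes (masked by the dominant flag) contribute nothing.
Co-occurrence statistics count, per individual, the number of distinct
window lengths, time instants and lobes, mirroring the question of how many
temporal scales and scalp regions one solution combines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import Individual, decode
from .montage import LOBE_OF, hemisphere_of
from .predictor import LogisticModel

DIMENSIONS = (
    "feature", "band_wave", "operator", "electrode", "lobe", "hemisphere",
    "window_length", "time_instant",
)


def _recipe_values(recipe) -> dict[str, object]:
    """Expressed gene values of one decoded hyper-feature, per dimension.

    ``feature`` is the decoded (dominant) feature; ``band_wave`` is the band
    gene restricted to hyper-features that actually express a band — masked
    feature genes contribute to no dimension.  A ``None`` marks "does not
    carry a value in this dimension".
    """
    electrode = recipe.electrode
    return {
        "feature": recipe.feature,
        "band_wave": recipe.feature[3:] if recipe.feature.startswith("rp_") else None,
        "operator": recipe.operator,
        "electrode": electrode,
        "lobe": LOBE_OF.get(electrode, "unknown"),
        "hemisphere": hemisphere_of(electrode) if electrode in LOBE_OF else "unknown",
        "window_length": recipe.window_minutes,
        "time_instant": recipe.offset_minutes,
    }


def _normalize(series: pd.Series) -> pd.Series:
    total = series.sum()
    return series / total if total > 0 else series


def _accumulate(weights: np.ndarray, recipes) -> dict[str, pd.Series]:
    out: dict[str, pd.Series] = {}
    rows = [_recipe_values(r) for r in recipes]
    for dim in DIMENSIONS:
        scores: dict = {}
        for w, row in zip(weights, rows):
            value = row[dim]
            if value is None:
                continue
            scores[value] = scores.get(value, 0.0) + w
        out[dim] = _normalize(pd.Series(scores, dtype=float))
    return out


def gene_presence(ind: Individual, min_preictal: int = 40) -> dict[str, pd.Series]:
    """Normalized presence of each expressed gene value (one dict per dimension)."""
    phenotype = decode(ind, min_preictal)
    return _accumulate(np.ones(len(phenotype.recipes)), phenotype.recipes)


def hyper_feature_weights(model: LogisticModel, n_hyper_features: int = 5,
                          collapse: str = "mean") -> np.ndarray:
    """Scalar weight per hyper-feature: mean (or sum) |beta| over its retained
    design columns; 0 when every column of a hyper-feature was filtered out.
    """
    weights = np.zeros(n_hyper_features)
    counts = np.zeros(n_hyper_features)
    for coef, col in zip(model.coefficients, model.retained_columns):
        hf_idx, _lag = model.column_meta[col]
        weights[hf_idx] += abs(coef)
        counts[hf_idx] += 1
    if collapse == "mean":
        with np.errstate(invalid="ignore"):
            weights = np.where(counts > 0, weights / np.maximum(counts, 1), 0.0)
    elif collapse != "sum":
        raise ValueError(f"unknown collapse rule '{collapse}'")
    return weights


def gene_predictive_power(ind: Individual, model: LogisticModel,
                          min_preictal: int = 40,
                          collapse: str = "mean") -> dict[str, pd.Series]:
    """Normalized predictive power of each expressed gene value."""
    phenotype = decode(ind, min_preictal)
    weights = hyper_feature_weights(model, len(phenotype.recipes), collapse=collapse)
    return _accumulate(weights, phenotype.recipes)


@dataclass
class PhenotypeReport:
    """Averaged normalized presence/power vectors plus co-occurrence histograms."""

    presence: dict[str, pd.Series]
    power: dict[str, pd.Series]
    cooccurrence: dict[str, pd.Series]
    n_individuals: int

    def top_values(self, dimension: str, k: int = 2, by: str = "power") -> list:
        table = (self.power if by == "power" else self.presence)[dimension]
        return list(table.sort_values(ascending=False).index[:k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dim in DIMENSIONS:
            presence = self.presence[dim]
            power = self.power[dim]
            for value in presence.index.union(power.index):
                rows.append(
                    {
                        "dimension": dim,
                        "value": value,
                        "presence": float(presence.get(value, 0.0)),
                        "predictive_power": float(power.get(value, 0.0)),
                    }
                )
        return pd.DataFrame(rows)


def _mean_vectors(per_individual: list[dict[str, pd.Series]]) -> dict[str, pd.Series]:
    out = {}
    for dim in DIMENSIONS:
        frame = pd.DataFrame([d[dim] for d in per_individual]).fillna(0.0)
        out[dim] = frame.mean(axis=0).sort_values(ascending=False)
    return out


def aggregate_report(individuals: list[Individual], models: list[LogisticModel],
                     min_preictal: int = 40, collapse: str = "mean") -> PhenotypeReport:
    """Average the per-individual normalized vectors over a set of solutions
    (typically the 30 best-of-execution individuals with their final models).
    """
    if len(individuals) != len(models):
        raise ValueError("one fitted model is required per individual")
    presence = [gene_presence(ind, min_preictal) for ind in individuals]
    power = [
        gene_predictive_power(ind, model, min_preictal, collapse=collapse)
        for ind, model in zip(individuals, models)
    ]
    distinct = {"window_length": [], "time_instant": [], "lobe": []}
    for vectors in presence:
        for dim in distinct:
            distinct[dim].append(int((vectors[dim] > 0).sum()))
    cooccurrence = {
        f"distinct_{dim}s_per_individual": pd.Series(vals).value_counts().sort_index()
        for dim, vals in distinct.items()
    }
    return PhenotypeReport(
        presence=_mean_vectors(presence),
        power=_mean_vectors(power),
        cooccurrence=cooccurrence,
        n_individuals=len(individuals),
    )


def plot_report(report: PhenotypeReport, path) -> None:
    """Bar-chart rendering of the presence/power panels (one row per dimension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(DIMENSIONS), 1, figsize=(8, 3 * len(DIMENSIONS)))
    for ax, dim in zip(np.atleast_1d(axes), DIMENSIONS):
        presence = report.presence[dim]
        power = report.power[dim].reindex(presence.index).fillna(0.0)
        x = np.arange(len(presence))
        ax.bar(x - 0.2, presence.to_numpy(), width=0.4, label="presence")
        ax.bar(x + 0.2, power.to_numpy(), width=0.4, label="predictive power")
        ax.set_xticks(x, [str(v) for v in presence.index], rotation=45, ha="right")
        ax.set_title(dim)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
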
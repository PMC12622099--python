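"""The two headline pipelines over nested feature sets.

``run_feature_influence`` traces the accuracy/discrimination trade-off: for
each ranking criterion (mutual information with age, and with the clinical
pair's label), features are added one at a time in descending MI order; at
each set size k a brain-age model is fitted on controls, deltas are computed
for the two clinical groups (out-of-fold where a group *is* the control
group), and the 1-D deltas are scored as a classifier.  The result is a pair
of (MAE, AUC)-vs-k progression curves.

``run_model_vs_logistic`` compares, at every k, three delta-based classifiers
(deltas from linear / ridge / support-vector age models) against a logistic
model trained directly on the raw feature set, all four sharing identical
stratified fold assignments.

All stage seeds fan out deterministically from one master seed via
``derive_seed(master, stage, k)``.  The criterion is deliberately *not* part
of the seed path: at equal k the two orderings share fold assignments, so at
k = p (identical feature sets) their metrics coincide exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .classify import augmentation_comparison, classify_groups, stratified_splits
from .cohort import CohortTable, GroupPair, subset_by_labels
from .config import RunConfig
from .model import AgeModelSpec, BrainAgeResults, fit_age_model
from .ranking import (
    FeatureRanking,
    mi_with_age,
    mi_with_labels,
    nested_feature_sets,
    rank_features,
)

__all__ = [
    "ProgressionCurve",
    "ModelComparisonCurve",
    "FeatureInfluenceResult",
    "ModelVsLogisticResult",
    "run_feature_influence",
    "run_model_vs_logistic",
]

logger = logging.getLogger("brainage_influence")

AGE_MODEL_KINDS = ("linear", "ridge", "svr")


@dataclass
class ProgressionCurve:
    """(k, feature added, MAE ± CI, AUC ± CI) series for one ranking criterion."""

    criterion: str
    points: pd.DataFrame  # columns: k, feature_added, mae, mae_ci95, auc, auc_sd, auc_ci95

    def __post_init__(self) -> None:
        ks = self.points["k"].to_numpy()
        if not np.all(np.diff(ks) > 0):
            raise ValueError("k must be strictly increasing")


@dataclass
class ModelComparisonCurve:
    """AUC-vs-k series for one (ordering, model kind) combination."""

    ordering: str
    model_kind: str  # delta-linear | delta-ridge | delta-svr | direct-logistic
    points: pd.DataFrame  # columns: k, auc_mean, auc_sd


@dataclass
class FeatureInfluenceResult:
    pair: GroupPair
    rankings: dict[str, FeatureRanking]
    curves: dict[str, ProgressionCurve]  # keys: "age", "discrimination"

    def table(self) -> pd.DataFrame:
        frames = []
        for crit, curve in self.curves.items():
            f = curve.points.copy()
            f.insert(0, "ordering", crit)
            f.insert(0, "comparison", str(self.pair))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


@dataclass
class ModelVsLogisticResult:
    pair: GroupPair
    rankings: dict[str, FeatureRanking]
    curves: list[ModelComparisonCurve] = field(default_factory=list)
    #: four-input paired comparison at the full feature set:
    #: features / features+age / delta / features+delta
    augmentation: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        frames = []
        for c in self.curves:
            f = c.points.copy()
            f.insert(0, "model_kind", c.model_kind)
            f.insert(0, "ordering", c.ordering)
            f.insert(0, "comparison", str(self.pair))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _build_rankings(
    cohort: CohortTable, pair: GroupPair, config: RunConfig
) -> dict[str, FeatureRanking]:
    master = config.seeds.master
    k_nn = config.mi.k_neighbors
    if config.experiment.age_ranking_population == "controls":
        age_pop = subset_by_labels(cohort, {pair.control_label})
    else:
        age_pop = cohort
    age_scores = mi_with_age(age_pop, k_neighbors=k_nn, seed=derive_seed(master, "mi", "age"))
    disc_scores = mi_with_labels(
        cohort, pair, k_neighbors=k_nn, seed=derive_seed(master, "mi", "labels")
    )
    return {
        "age": rank_features(age_scores, criterion="age"),
        "discrimination": rank_features(disc_scores, criterion=pair),
    }


def _fit_and_deltas(
    cohort: CohortTable,
    pair: GroupPair,
    feature_set: list[str],
    regressor: str,
    config: RunConfig,
    seed: int,
) -> tuple[BrainAgeResults, pd.DataFrame]:
    """Fit a control-only age model and return deltas for the pair's subjects.

    Out-of-fold predictions are used for any group that coincides with the
    control group; other groups are scored with the refit-on-all pipeline.
    """
    controls = subset_by_labels(cohort, {pair.control_label})
    spec = AgeModelSpec(
        feature_set=tuple(feature_set),
        regressor=regressor,
        regressor_hyperparams=config.model.hyperparams if regressor == config.model.regressor else {},
        n_folds=config.model.n_folds,
        seed=seed,
        bias_correction=config.model.bias_correction,
    )
    results = fit_age_model(controls, spec, control_label=pair.control_label)
    parts = []
    for lab in pair.labels:
        group = subset_by_labels(cohort, {lab})
        parts.append(results.compute_deltas(group, use_oof=(lab == pair.control_label)))
    return results, pd.concat(parts)


def run_feature_influence(
    cohort: CohortTable, pair: GroupPair, config: RunConfig | None = None
) -> FeatureInfluenceResult:
    """MAE/AUC progression over nested feature sets for both orderings."""
    config = config or RunConfig()
    master = config.seeds.master
    rankings = _build_rankings(cohort, pair, config)
    curves: dict[str, ProgressionCurve] = {}
    for crit, ranking in rankings.items():
        rows = []
        for k, fset in enumerate(nested_feature_sets(ranking), start=1):
            model_seed = derive_seed(master, "agemodel", k)
            clf_seed = derive_seed(master, "classify", k)
            results, deltas = _fit_and_deltas(
                cohort, pair, fset, config.model.regressor, config, model_seed
            )
            pair_sub = subset_by_labels(cohort, pair.labels)
            d = deltas.loc[pair_sub.subject_ids]
            clf = classify_groups(
                d["delta"].to_numpy(),
                d["label"].to_numpy(),
                n_folds=config.classification.n_folds,
                seed=clf_seed,
                penalty_c=config.classification.penalty_c,
            )
            logger.info(
                "feature_influence criterion=%s k=%d mae=%.3f auc=%.3f seed=%d",
                crit, k, results.mae_uncorrected, clf.auc_mean, model_seed,
            )
            rows.append(
                {
                    "k": k,
                    "feature_added": fset[-1],
                    "mae": results.mae_uncorrected,
                    "mae_ci95": results.mae_ci95,
                    "auc": clf.auc_mean,
                    "auc_sd": clf.auc_sd,
                    "auc_ci95": clf.auc_ci95,
                }
            )
        curves[crit] = ProgressionCurve(
            criterion=ranking.criterion_name, points=pd.DataFrame(rows)
        )
    return FeatureInfluenceResult(pair=pair, rankings=rankings, curves=curves)


def run_model_vs_logistic(
    cohort: CohortTable, pair: GroupPair, config: RunConfig | None = None
) -> ModelVsLogisticResult:
    """Delta-based (linear/ridge/svr) vs direct-logistic AUC over nested sets.

    At each k the four classifiers share identical stratified fold
    assignments, so curve differences are attributable to the input
    representation, not split noise.
    """
    config = config or RunConfig()
    master = config.seeds.master
    rankings = _build_rankings(cohort, pair, config)
    if config.experiment.ordering == "both":
        orderings = ["age", "discrimination"]
    else:
        orderings = [config.experiment.ordering]

    result = ModelVsLogisticResult(pair=pair, rankings=rankings)
    pair_sub = subset_by_labels(cohort, pair.labels)
    y = pair_sub.labels.to_numpy()
    for ordering in orderings:
        ranking = rankings[ordering]
        rows: dict[str, list[dict]] = {
            **{f"delta-{m}": [] for m in AGE_MODEL_KINDS},
            "direct-logistic": [],
        }
        for k, fset in enumerate(nested_feature_sets(ranking), start=1):
            clf_seed = derive_seed(master, "classify", k)
            splits = stratified_splits(y, config.classification.n_folds, clf_seed)
            for m in AGE_MODEL_KINDS:
                model_seed = derive_seed(master, "agemodel", m, k)
                _, deltas = _fit_and_deltas(cohort, pair, fset, m, config, model_seed)
                d = deltas.loc[pair_sub.subject_ids, "delta"].to_numpy()
                res = classify_groups(
                    d, y,
                    n_folds=config.classification.n_folds,
                    seed=clf_seed,
                    penalty_c=config.classification.penalty_c,
                    splits=splits,
                )
                rows[f"delta-{m}"].append(
                    {"k": k, "auc_mean": res.auc_mean, "auc_sd": res.auc_sd}
                )
            X = pair_sub.features(fset).to_numpy()
            res = classify_groups(
                X, y,
                n_folds=config.classification.n_folds,
                seed=clf_seed,
                penalty_c=config.classification.penalty_c,
                splits=splits,
            )
            rows["direct-logistic"].append(
                {"k": k, "auc_mean": res.auc_mean, "auc_sd": res.auc_sd}
            )
            logger.info("model_vs_logistic ordering=%s k=%d seed=%d", ordering, k, clf_seed)
        for kind, pts in rows.items():
            result.curves.append(
                ModelComparisonCurve(
                    ordering=ordering, model_kind=kind, points=pd.DataFrame(pts)
                )
            )

    # value-added check at the full feature set: does the delta carry
    # information beyond the features (and age) themselves?
    _, deltas = _fit_and_deltas(
        cohort, pair, cohort.feature_names, config.model.regressor, config,
        derive_seed(master, "augmentation", "agemodel"),
    )
    result.augmentation = augmentation_comparison(
        cohort, pair, deltas,
        feature_set=cohort.feature_names,
        n_folds=config.classification.n_folds,
        seed=derive_seed(master, "augmentation", "classify"),
        penalty_c=config.classification.penalty_c,
    )
    return result
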
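"""Mutual-information feature ranking and nested feature sets.

Features are scored by their mutual information (MI, in nats) either with
chronological age (continuous target) or with a binary clinical label, using
the Kraskov-Stögbauer-Grassberger family of k-nearest-neighbour estimators:
the continuous-continuous variant for age and the continuous-discrete variant
for labels.  KSG estimators are invariant to per-variable monotone rescaling,
so features are used raw (unscaled).  A tiny seeded jitter breaks exact ties
among sample values; negative raw estimates are clamped to zero.

The ranking drives the nested-feature-set construction: set ``k`` holds the
``k`` highest-MI features, so a sweep over ``k = 1..p`` traces how model
behaviour changes as progressively less-informative features are added.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif, mutual_info_regression

from .cohort import CohortTable, GroupPair, subset_by_labels

__all__ = [
    "FeatureRanking",
    "mi_with_age",
    "mi_with_labels",
    "rank_features",
    "nested_feature_sets",
    "write_ranking_csv",
]

DEFAULT_K_NEIGHBORS = 3


@dataclass(frozen=True)
class FeatureRanking:
    """Ordered features with their MI scores under one criterion.

    ``criterion`` is ``"age"`` or a :class:`GroupPair`; ``order`` lists
    features by descending MI, exact ties broken by ascending feature name so
    the ranking is independent of CSV column order.
    """

    criterion: Union[str, GroupPair]
    scores: dict[str, float]
    order: tuple[str, ...]

    @property
    def criterion_name(self) -> str:
        return self.criterion if isinstance(self.criterion, str) else str(self.criterion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": list(self.order),
                "criterion": self.criterion_name,
                "mi_nats": [self.scores[f] for f in self.order],
            }
        )


def _check_n(n: int, k_neighbors: int) -> None:
    if n < k_neighbors + 2:
        raise ValueError(
            f"need at least k_neighbors+2 = {k_neighbors + 2} subjects, got {n}"
        )


def mi_with_age(
    cohort: CohortTable,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> dict[str, float]:
    """MI of each feature with age (nats), KSG continuous-continuous estimator."""
    _check_n(cohort.n_subjects, k_neighbors)
    X = cohort.features().to_numpy()
    y = cohort.ages.to_numpy()
    mi = mutual_info_regression(
        X, y, n_neighbors=k_neighbors, random_state=seed, discrete_features=False
    )
    # a constant feature carries no information; the jittered estimate can
    # otherwise come out slightly positive
    constant = np.ptp(X, axis=0) == 0
    return {
        f: 0.0 if const else float(max(v, 0.0))
        for f, v, const in zip(cohort.feature_names, mi, constant)
    }


def mi_with_labels(
    cohort: CohortTable,
    pair: GroupPair,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> dict[str, float]:
    """MI of each feature with the binary label of ``pair`` (nats).

    Computed only on subjects belonging to the two groups, via the KSG
    continuous-discrete estimator.
    """
    sub = subset_by_labels(cohort, pair.labels)
    counts = sub.labels.value_counts()
    for lab in pair.labels:
        if counts.get(lab, 0) < k_neighbors + 2:
            raise ValueError(
                f"group {lab!r} has {counts.get(lab, 0)} subjects; "
                f"need at least {k_neighbors + 2}"
            )
    X = sub.features().to_numpy()
    y = (sub.labels == pair.group_b).to_numpy().astype(int)
    mi = mutual_info_classif(
        X, y, n_neighbors=k_neighbors, random_state=seed, discrete_features=False
    )
    constant = np.ptp(X, axis=0) == 0
    return {
        f: 0.0 if const else float(max(v, 0.0))
        for f, v, const in zip(sub.feature_names, mi, constant)
    }


def rank_features(
    scores: Mapping[str, float],
    criterion: Union[str, GroupPair] = "age",
) -> FeatureRanking:
    """Descending-MI ranking; exact ties broken by ascending feature name."""
    if not scores:
        raise ValueError("cannot rank an empty score mapping")
    if any(not np.isfinite(v) for v in scores.values()):
        raise ValueError("MI scores must be finite")
    order = tuple(sorted(scores, key=lambda f: (-scores[f], f)))
    return FeatureRanking(criterion=criterion, scores=dict(scores), order=order)


def nested_feature_sets(ranking: FeatureRanking) -> list[list[str]]:
    """Top-k feature sets for k = 1..p; set k is a subset of set k+1."""
    return [list(ranking.order[:k]) for k in range(1, len(ranking.order) + 1)]


def write_ranking_csv(rankings: Sequence[FeatureRanking], path: str | Path) -> Path:
    """Machine-readable ranking table (rank, feature, criterion, mi_nats)."""
    path = Path(path)
    pd.concat([r.to_frame() for r in rankings], ignore_index=True).to_csv(
        path, index=False
    )
    return path
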
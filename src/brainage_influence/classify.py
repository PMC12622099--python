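"""Two-group classification with stratified CV, in-fold undersampling and AUC.

Any representation of a subject — a 1-D brain-age delta, the raw feature
vector, or an augmented set — is evaluated the same way: stratified k-fold
splits preserve the class ratio in every fold; within each *training* fold
the majority class is randomly undersampled to the minority count (the test
fold is left untouched, so it remains representative); inputs are
standardized on the undersampled training fold; an (effectively unpenalized)
logistic model is fitted; and the held-out fold is scored by the area under
the ROC curve computed from predicted class probabilities.

Because rebalancing happens strictly inside training folds, the reported AUC
carries no optimistic leakage from the test subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from ._seeds import derive_seed
from .cohort import CohortTable, GroupPair, subset_by_labels

__all__ = [
    "ClassificationResult",
    "DeltaClassifier",
    "classify_groups",
    "stratified_splits",
    "augmentation_comparison",
    "repeat_classify",
]

DEFAULT_PENALTY_C = 1e6  # negligible penalty: inputs are low-dimensional


@dataclass
class ClassificationResult:
    """Per-fold and summary AUC of one two-group classifier."""

    fold_aucs: list[float]
    auc_mean: float
    auc_sd: float
    n_per_class_used: list[dict[str, int]]
    n_folds: int
    seed: int

    @property
    def auc_ci95(self) -> float:
        return 1.96 * self.auc_sd / np.sqrt(self.n_folds)

    def summary(self) -> str:
        return (
            f"AUC {self.auc_mean:.3f} ± {self.auc_sd:.3f} "
            f"(sd across {self.n_folds} folds, seed {self.seed})"
        )


def stratified_splits(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified fold indices, shared across paired comparisons."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _undersample(train_idx: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class within ``train_idx`` to the minority count."""
    classes, counts = np.unique(y[train_idx], return_counts=True)
    n_min = counts.min()
    kept = []
    for cls in classes:
        members = train_idx[y[train_idx] == cls]
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        kept.append(np.sort(members))
    return np.concatenate(kept)


class DeltaClassifier:
    """Logistic two-group classifier over any per-subject input vectors.

    Parameters
    ----------
    inputs
        (n, d) array or DataFrame, d >= 1 — deltas, features, or both.
    labels
        Binary group label per subject (any two distinct values).
    n_folds, seed
        Stratified CV configuration; the seed drives fold shuffling and the
        per-fold undersampling draws.
    penalty_c
        Inverse L2 strength of the logistic model; large = unpenalized.
    """

    def __init__(
        self,
        inputs: np.ndarray | pd.DataFrame | pd.Series,
        labels: Sequence,
        n_folds: int = 5,
        seed: int = 0,
        penalty_c: float = DEFAULT_PENALTY_C,
    ):
        X = np.asarray(inputs, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels)
        if X.shape[0] != len(y):
            raise ValueError("inputs and labels length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("inputs must be finite")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < n_folds:
            raise ValueError(
                f"each class needs >= n_folds={n_folds} subjects "
                f"(counts: {dict(zip(classes, counts))})"
            )
        self.X, self.y = X, y
        self.classes = classes
        self.n_folds = n_folds
        self.seed = seed
        self.penalty_c = penalty_c

    def fit(
        self, splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None
    ) -> ClassificationResult:
        X, y = self.X, self.y
        if splits is None:
            splits = stratified_splits(y, self.n_folds, self.seed)

        if len(np.unique(X)) == 1:
            warnings.warn(
                "classifier input is constant; AUC is chance level", stacklevel=2
            )
            return ClassificationResult(
                fold_aucs=[0.5] * self.n_folds,
                auc_mean=0.5,
                auc_sd=0.0,
                n_per_class_used=[
                    {str(c): 0 for c in self.classes} for _ in range(self.n_folds)
                ],
                n_folds=self.n_folds,
                seed=self.seed,
            )

        pos = self.classes[1]  # sorted by np.unique: deterministic positive class
        fold_aucs: list[float] = []
        n_used: list[dict[str, int]] = []
        for fold, (tr, te) in enumerate(splits):
            rng = np.random.default_rng(derive_seed(self.seed, "undersample", fold))
            tr_bal = _undersample(tr, y, rng)
            scaler = StandardScaler().fit(X[tr_bal])
            clf = LogisticRegression(C=self.penalty_c, max_iter=2000)
            clf.fit(scaler.transform(X[tr_bal]), y[tr_bal])
            proba = clf.predict_proba(scaler.transform(X[te]))[:, list(clf.classes_).index(pos)]
            fold_aucs.append(float(roc_auc_score((y[te] == pos).astype(int), proba)))
            cls, cnt = np.unique(y[tr_bal], return_counts=True)
            n_used.append({str(c): int(n) for c, n in zip(cls, cnt)})
        return ClassificationResult(
            fold_aucs=fold_aucs,
            auc_mean=float(np.mean(fold_aucs)),
            auc_sd=float(np.std(fold_aucs, ddof=1)),
            n_per_class_used=n_used,
            n_folds=self.n_folds,
            seed=self.seed,
        )


def classify_groups(
    inputs: np.ndarray | pd.DataFrame | pd.Series,
    labels: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    penalty_c: float = DEFAULT_PENALTY_C,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ClassificationResult:
    """Evaluate ``inputs`` as a two-group classifier; see :class:`DeltaClassifier`."""
    return DeltaClassifier(
        inputs, labels, n_folds=n_folds, seed=seed, penalty_c=penalty_c
    ).fit(splits=splits)


def repeat_classify(
    inputs: np.ndarray | pd.DataFrame | pd.Series,
    labels: Sequence,
    n_folds: int = 5,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    penalty_c: float = DEFAULT_PENALTY_C,
) -> pd.DataFrame:
    """Repeat-seed mode: one row per seed plus across-seed mean/sd of the AUC."""
    rows = []
    for s in seeds:
        res = classify_groups(
            inputs, labels, n_folds=n_folds, seed=s, penalty_c=penalty_c
        )
        rows.append({"seed": s, "auc_mean": res.auc_mean, "auc_sd_folds": res.auc_sd})
    out = pd.DataFrame(rows)
    out.attrs["auc_mean_over_seeds"] = float(out["auc_mean"].mean())
    out.attrs["auc_sd_over_seeds"] = float(out["auc_mean"].std(ddof=1))
    return out


def augmentation_comparison(
    cohort: CohortTable,
    pair: GroupPair,
    deltas: pd.DataFrame,
    feature_set: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    penalty_c: float = DEFAULT_PENALTY_C,
) -> pd.DataFrame:
    """Four paired classifiers: features, features+age, delta, features+delta.

    All four use identical stratified fold assignments and undersampling
    seeds, so AUC differences reflect the input representation rather than
    split noise.  ``deltas`` must cover every subject of the pair (output of
    :meth:`BrainAgeResults.compute_deltas`, possibly concatenated over
    groups).
    """
    sub = subset_by_labels(cohort, pair.labels)
    missing = [s for s in sub.subject_ids if s not in deltas.index]
    if missing:
        raise ValueError(f"no delta available for subjects: {missing[:5]}")
    d = deltas.loc[sub.subject_ids, "delta"].to_numpy()[:, None]
    F = sub.features(feature_set).to_numpy()
    age = sub.ages.to_numpy()[:, None]
    y = sub.labels.to_numpy()

    input_sets = {
        "features": F,
        "features+age": np.hstack([F, age]),
        "delta": d,
        "features+delta": np.hstack([F, d]),
    }
    splits = stratified_splits(y, n_folds, seed)
    rows = []
    for name, X in input_sets.items():
        res = classify_groups(
            X, y, n_folds=n_folds, seed=seed, penalty_c=penalty_c, splits=splits
        )
        rows.append(
            {
                "comparison": str(pair),
                "input_set": name,
                "auc_mean": res.auc_mean,
                "auc_sd": res.auc_sd,
                "n_folds": n_folds,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
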
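"""Brain-age regression on healthy controls, age-bias correction, and deltas.

The model is fitted in the statsmodels mould: construct a
:class:`BrainAgeModel` from a control cohort and an :class:`AgeModelSpec`,
call :meth:`~BrainAgeModel.fit`, and work with the returned
:class:`BrainAgeResults`.

Fitting minimises squared age-prediction error on cognitively normal
controls with a scaler + regressor pipeline under seeded k-fold
cross-validation.  Every control receives exactly one out-of-fold (oof)
predicted age; the uncorrected mean absolute error (MAE) is computed from
those oof predictions *before* any bias correction.  A final pipeline is
refit on all controls for scoring external (clinical) groups.

Age-bias correction addresses the regression-to-the-mean artifact: predicted
ages are systematically compressed toward the training mean, making young
subjects look "old" and vice versa.  The default correction regresses the
oof predicted age on chronological age in controls, ``ŷ ≈ a·y + b``, and
inverts: ``ŷ_c = (ŷ − b)/a``.  The delta is then ``ŷ_c − y``; positive means
an older-appearing brain.  The alternative "delta on age" correction
(regress ``ŷ − y`` on ``y`` and subtract the fit) is available via the spec;
both zero the delta-age slope on the fitting sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cohort import CohortTable

__all__ = [
    "AgeModelSpec",
    "BrainAgeModel",
    "BrainAgeResults",
    "fit_age_model",
    "fit_bias_correction",
    "compute_deltas",
]

_REGRESSOR_DEFAULTS: dict[str, dict] = {
    "linear": {},
    "ridge": {"alpha": 1.0},
    "svr": {"kernel": "rbf", "C": 1.0, "epsilon": 0.1},
}


@dataclass(frozen=True)
class AgeModelSpec:
    """Configuration of one brain-age pipeline.

    ``feature_set`` is interpreted as a set: the design matrix always uses
    the cohort's declared column order, so rankings that converge on the same
    features yield identical fits.
    """

    feature_set: tuple[str, ...]
    regressor: str = "linear"
    regressor_hyperparams: dict = field(default_factory=dict)
    n_folds: int = 5
    seed: int = 0
    bias_correction: str = "predicted_on_age"  # or "delta_on_age"

    def __post_init__(self) -> None:
        if not self.feature_set:
            raise ValueError("feature_set must be non-empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.regressor not in _REGRESSOR_DEFAULTS:
            raise ValueError(
                f"unknown regressor {self.regressor!r}; "
                f"choose from {sorted(_REGRESSOR_DEFAULTS)}"
            )
        if self.bias_correction not in ("predicted_on_age", "delta_on_age"):
            raise ValueError(f"unknown bias_correction {self.bias_correction!r}")

    def make_pipeline(self) -> Pipeline:
        params = {**_REGRESSOR_DEFAULTS[self.regressor], **self.regressor_hyperparams}
        reg = {"linear": LinearRegression, "ridge": Ridge, "svr": SVR}[self.regressor](
            **params
        )
        return Pipeline([("scaler", StandardScaler()), ("regressor", reg)])


class BrainAgeModel:
    """Brain-age regression model over a control-only cohort.

    Parameters
    ----------
    controls
        Cohort containing only the control group (enforced).
    spec
        Pipeline configuration.
    control_label
        Clinical label designating healthy controls; any other label in
        ``controls`` raises.
    """

    def __init__(
        self,
        controls: CohortTable,
        spec: AgeModelSpec,
        control_label: str = "CN",
    ):
        extra = controls.label_set - {control_label}
        if extra:
            raise ValueError(
                f"training cohort must contain only {control_label!r}; "
                f"found {sorted(extra)}"
            )
        if controls.n_subjects < spec.n_folds:
            raise ValueError(
                f"{controls.n_subjects} controls < n_folds={spec.n_folds}"
            )
        missing = set(spec.feature_set) - set(controls.feature_names)
        if missing:
            raise ValueError(f"features not in cohort: {sorted(missing)}")
        self.controls = controls
        self.spec = spec
        self.control_label = control_label

    def fit(self) -> "BrainAgeResults":
        spec = self.spec
        X = self.controls.features(spec.feature_set).to_numpy()
        y = self.controls.ages.to_numpy()
        ids = np.array(self.controls.subject_ids)

        kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        oof = np.full(len(y), np.nan)
        fold_of = np.full(len(y), -1, dtype=int)
        fold_models: list[Pipeline] = []
        for fold, (tr, te) in enumerate(kf.split(X)):
            pipe = spec.make_pipeline()
            pipe.fit(X[tr], y[tr])  # scaler statistics from training folds only
            oof[te] = pipe.predict(X[te])
            fold_of[te] = fold
            fold_models.append(pipe)

        mae_uncorrected = float(np.mean(np.abs(oof - y)))
        fold_maes = [
            float(np.mean(np.abs(oof[fold_of == f] - y[fold_of == f])))
            for f in range(spec.n_folds)
        ]
        full_model = spec.make_pipeline().fit(X, y)
        oof_series = pd.Series(oof, index=pd.Index(ids, name="subject_id"))
        bias = fit_bias_correction(oof, y, method=spec.bias_correction)
        return BrainAgeResults(
            model=self,
            fold_models=fold_models,
            fold_assignments=pd.Series(fold_of, index=oof_series.index),
            full_model=full_model,
            oof_predictions=oof_series,
            mae_uncorrected=mae_uncorrected,
            fold_maes=fold_maes,
            bias_coefficients=bias,
        )


def fit_bias_correction(
    predictions: Sequence[float] | pd.Series,
    ages: Sequence[float] | pd.Series,
    method: str = "predicted_on_age",
) -> tuple[float, float]:
    """OLS coefficients of the age-bias correction on control predictions.

    ``predicted_on_age`` returns ``(a, b)`` with ``ŷ ≈ a·y + b``;
    ``delta_on_age`` returns ``(α, β)`` with ``ŷ − y ≈ α·y + β``.
    """
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(ages, dtype=float)
    if pred.shape != age.shape or pred.ndim != 1:
        raise ValueError("predictions and ages must be 1-D and equal length")
    if len(age) < 3:
        raise ValueError("need at least 3 subjects to fit the correction")
    if np.var(age) == 0:
        raise ValueError("age variance is zero; correction is undefined")
    target = pred if method == "predicted_on_age" else pred - age
    slope, intercept = np.polyfit(age, target, 1)
    return float(slope), float(intercept)


@dataclass
class BrainAgeResults:
    """Fitted brain-age model: per-fold pipelines, oof predictions, MAE,
    bias-correction coefficients, and delta computation for any group."""

    model: BrainAgeModel
    fold_models: list[Pipeline]
    fold_assignments: pd.Series
    full_model: Pipeline
    oof_predictions: pd.Series
    mae_uncorrected: float
    fold_maes: list[float]
    bias_coefficients: tuple[float, float]

    @property
    def spec(self) -> AgeModelSpec:
        return self.model.spec

    @property
    def mae_ci95(self) -> float:
        """95% normal-approximation half-width of the MAE across folds."""
        sd = float(np.std(self.fold_maes, ddof=1))
        return 1.96 * sd / np.sqrt(len(self.fold_maes))

    def predict_raw(self, group: CohortTable, use_oof: bool = False) -> pd.Series:
        """Uncorrected predicted ages: oof for training controls, otherwise
        from the refit-on-all-controls pipeline."""
        if use_oof:
            missing = [s for s in group.subject_ids if s not in self.oof_predictions.index]
            if missing:
                raise ValueError(
                    "out-of-fold predictions requested for subjects that are not "
                    f"training controls: {missing[:5]}"
                )
            return self.oof_predictions.loc[group.subject_ids]
        X = group.features(self.spec.feature_set).to_numpy()
        return pd.Series(
            self.full_model.predict(X),
            index=pd.Index(group.subject_ids, name="subject_id"),
        )

    def compute_deltas(self, group: CohortTable, use_oof: bool = False) -> pd.DataFrame:
        """Bias-corrected deltas (years) for ``group``.

        Returns a DataFrame indexed by subject with columns ``age``,
        ``label`` and ``delta`` (= corrected predicted age − age).
        """
        raw = self.predict_raw(group, use_oof=use_oof)
        y = group.ages.to_numpy()
        a, b = self.bias_coefficients
        if self.spec.bias_correction == "predicted_on_age":
            if a == 0:
                raise ZeroDivisionError(
                    "degenerate bias correction: fitted slope a = 0"
                )
            corrected = (raw.to_numpy() - b) / a
            delta = corrected - y
        else:  # delta_on_age: subtract the fitted age trend from the raw delta
            delta = (raw.to_numpy() - y) - (a * y + b)
        return pd.DataFrame(
            {"age": y, "label": group.labels.to_numpy(), "delta": delta},
            index=pd.Index(group.subject_ids, name="subject_id"),
        )

    def summary(self) -> str:
        a, b = self.bias_coefficients
        lines = [
            "Brain-age model results",
            "=" * 46,
            f"regressor:          {self.spec.regressor}",
            f"features (k={len(self.spec.feature_set)}):    "
            + ", ".join(self.spec.feature_set),
            f"controls:           {self.model.controls.n_subjects} "
            f"({self.model.control_label})",
            f"folds / seed:       {self.spec.n_folds} / {self.spec.seed}",
            f"MAE (uncorrected):  {self.mae_uncorrected:.3f} ± {self.mae_ci95:.3f} years",
            f"bias correction:    {self.spec.bias_correction}  "
            f"(a={a:.4f}, b={b:.3f})",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> Path:
        """Reproducibility sidecar: fold assignments, MAE, bias coefficients."""
        path = Path(path)
        doc = {
            "regressor": self.spec.regressor,
            "feature_set": list(self.spec.feature_set),
            "n_folds": self.spec.n_folds,
            "seed": self.spec.seed,
            "bias_correction": self.spec.bias_correction,
            "mae_uncorrected": self.mae_uncorrected,
            "fold_maes": self.fold_maes,
            "bias_coefficients": list(self.bias_coefficients),
            "fold_assignments": {
                s: int(f) for s, f in self.fold_assignments.items()
            },
        }
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
        return path


# -- functional façade ------------------------------------------------------

def fit_age_model(
    controls: CohortTable, spec: AgeModelSpec, control_label: str = "CN"
) -> BrainAgeResults:
    """Fit a brain-age pipeline on controls; see :class:`BrainAgeModel`."""
    return BrainAgeModel(controls, spec, control_label=control_label).fit()


def compute_deltas(
    results: BrainAgeResults, group: CohortTable, use_oof: bool = False
) -> pd.DataFrame:
    """Bias-corrected deltas for ``group``; see
    :meth:`BrainAgeResults.compute_deltas`."""
    return results.compute_deltas(group, use_oof=use_oof)
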
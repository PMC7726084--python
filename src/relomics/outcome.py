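"""Model / Results interface for lesion outcome prediction.

``LesionResponseModel`` (binary overall response, logistic / AUC) and
``LesionProgressionModel`` (time to progression, Cox / c-index) wrap the
bootstrap-LASSO nested-CV machinery in a statsmodels-like API::

    model = LesionResponseModel.from_dataframe(df, features=[...])
    res = model.fit()            # final full-data model + nested CV
    print(res.summary())
    res.params                   # standardized-scale coefficients
    res.cv_performance.mean      # nested-CV AUC

The final reported model is ranked, order-selected and refit on the full
dataset; generalisation estimates come exclusively from the nested CV.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .modeling import (
    CVPerformance,
    FittedModel,
    ModelOrderCurve,
    ModelingConfig,
    calibration_curve,
    fit_final_model,
    km_stratify,
    nested_cv_evaluate,
    univariate_screen,
)

__all__ = ["LesionResponseModel", "LesionProgressionModel", "LesionOutcomeResults"]


class _LesionOutcomeModel:
    """Shared scaffolding; use the endpoint-specific subclasses."""

    endpoint: str = ""

    def __init__(
        self,
        data: pd.DataFrame,
        features: list[str] | None = None,
        config: ModelingConfig | None = None,
        subgroup_col: str | None = "subgroup",
    ):
        self.data = data.reset_index(drop=True)
        if features is None:
            reserved = {"lesion_id", "subgroup", "OR", "time", "event", "dose_Gy"}
            features = [
                c for c in self.data.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(self.data[c])
            ]
        if not features:
            raise ValueError("no candidate feature columns")
        missing = [c for c in features if c not in self.data.columns]
        if missing:
            raise ValueError(f"features not in data: {missing}")
        self.features = list(features)
        base = config or ModelingConfig()
        self.config = replace(base, endpoint=self.endpoint)
        self.subgroup_col = subgroup_col if subgroup_col in self.data.columns else None

    @classmethod
    def from_dataframe(cls, data, features=None, **kwargs):
        return cls(data, features=features, **kwargs)

    @classmethod
    def from_csv(cls, path, features=None, **kwargs):
        return cls(pd.read_csv(path), features=features, **kwargs)

    # subclasses define _outcome()
    def _outcome(self):
        raise NotImplementedError

    def fit(self, evaluate: bool = True) -> "LesionOutcomeResults":
        """Fit the final model on all lesions; optionally run the nested
        CV evaluation (the expensive part)."""
        outcome = self._outcome()
        X = self.data[self.features]
        model, ranking, curve = fit_final_model(X, outcome, self.config)
        cv = None
        if evaluate:
            sub = self.data[self.subgroup_col] if self.subgroup_col else None
            cv = nested_cv_evaluate(X, outcome, self.config, subgroups=sub)
        return LesionOutcomeResults(self, model, ranking, curve, cv)


class LesionResponseModel(_LesionOutcomeModel):
    """Logistic model of lesion overall response at first follow-up."""

    endpoint = "OR"

    def __init__(self, data, features=None, response_col="OR", **kwargs):
        super().__init__(data, features=features, **kwargs)
        self.response_col = response_col
        y = self.data[response_col]
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("response column must be binary 0/1")

    def _outcome(self):
        return self.data[self.response_col].to_numpy(int)


class LesionProgressionModel(_LesionOutcomeModel):
    """Cox model of lesion time to progression with right-censoring."""

    endpoint = "progression"

    def __init__(self, data, features=None, time_col="time", event_col="event", **kwargs):
        super().__init__(data, features=features, **kwargs)
        self.time_col, self.event_col = time_col, event_col
        if (self.data[time_col] <= 0).any():
            raise ValueError("times must be positive")
        if set(np.unique(self.data[event_col])) - {0, 1}:
            raise ValueError("event column must be binary 0/1")

    def _outcome(self):
        return (
            self.data[self.time_col].to_numpy(float),
            self.data[self.event_col].to_numpy(int),
        )


class LesionOutcomeResults:
    """Fitted final model, feature ranking, order curve and CV metrics."""

    def __init__(
        self,
        model_spec: _LesionOutcomeModel,
        model: FittedModel,
        ranking: pd.DataFrame,
        order_curve: ModelOrderCurve,
        cv_performance: CVPerformance | None,
    ):
        self.model_spec = model_spec
        self.model = model
        self.ranking = ranking
        self.order_curve = order_curve
        self.cv_performance = cv_performance

    @property
    def endpoint(self) -> str:
        return self.model_spec.endpoint

    @property
    def selected_features(self) -> list[str]:
        return list(self.model.features)

    @property
    def params(self) -> pd.Series:
        """Coefficients on the standardized feature scale (plus
        intercept for the response endpoint)."""
        s = pd.Series(self.model.coef, index=self.model.features)
        if self.endpoint == "OR":
            s = pd.concat([pd.Series({"intercept": self.model.intercept}), s])
        return s

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Response probability (OR) or relative risk score (progression)."""
        if self.endpoint == "OR":
            return self.model.predict_proba(data)
        return self.model.predict_risk(data)

    def univariate(self, alpha: float = 0.05) -> pd.DataFrame:
        spec = self.model_spec
        return univariate_screen(spec.data, spec.features, alpha=alpha)

    def calibration(self) -> tuple[float, float]:
        """Logistic recalibration slope and intercept (OR endpoint).

        Uses out-of-fold CV predicted probabilities (mean per lesion
        across repeats) when the nested CV was run; the in-sample
        fallback is trivially well calibrated for an MLE fit and only
        useful as a smoke check.
        """
        if self.endpoint != "OR":
            raise ValueError("calibration is defined for the OR endpoint")
        spec = self.model_spec
        y = spec.data[spec.response_col]
        cv = self.cv_performance
        if cv is not None and cv.predictions is not None and len(cv.predictions):
            per_lesion = cv.predictions.groupby("row")["score"].mean()
            rows = per_lesion.index.to_numpy()
            p = np.clip(per_lesion.to_numpy(), 1e-9, 1 - 1e-9)
            return calibration_curve(p, y.iloc[rows])
        return calibration_curve(self.model.predict_proba(spec.data), y)

    def km_stratification(self) -> dict:
        """Median-risk Kaplan-Meier split with log-rank p (progression)."""
        if self.endpoint != "progression":
            raise ValueError("KM stratification is for the progression endpoint")
        spec = self.model_spec
        cv = self.cv_performance
        if cv is not None and cv.predictions is not None and len(cv.predictions):
            per_lesion = cv.predictions.groupby("row")["score"].mean()
            rows = per_lesion.index.to_numpy()
            return km_stratify(
                per_lesion.to_numpy(),
                spec.data[spec.time_col].iloc[rows],
                spec.data[spec.event_col].iloc[rows],
            )
        return km_stratify(
            self.model.predict_risk(spec.data),
            spec.data[spec.time_col],
            spec.data[spec.event_col],
        )

    def summary(self) -> str:
        metric = "AUC" if self.endpoint == "OR" else "c-index"
        lines = []
        title = f"Lesion {'response' if self.endpoint == 'OR' else 'progression'} model"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"endpoint: {self.endpoint}    n lesions: {len(self.model_spec.data)}")
        lines.append(
            f"model order (one-SE rule): {self.order_curve.chosen_order} "
            f"of {len(self.ranking)} ranked features"
        )
        lines.append("")
        lines.append("coefficients (standardized scale)")
        lines.append("---------------------------------")
        freq = self.ranking["frequency"]
        if self.endpoint == "OR":
            lines.append(f"  {'intercept':<16}{self.model.intercept:>10.3f}")
        for name, c in zip(self.model.features, self.model.coef):
            lines.append(f"  {name:<16}{c:>10.3f}   (selection freq {freq.get(name, np.nan):.2f})")
        if self.cv_performance is not None:
            lines.append("")
            lines.append(f"nested-CV {metric}")
            lines.append("-" * (10 + len(metric)))
            for g, row in self.cv_performance.summary.iterrows():
                lines.append(
                    f"  {g:<10}{row['mean']:.3f}  (95% CI {row['ci_lo']:.3f}-"
                    f"{row['ci_hi']:.3f}, {int(row['n_folds'])} folds)"
                )
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<LesionOutcomeResults endpoint={self.endpoint} features={self.selected_features}>"
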
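"""Quadratic response-surface fitting on coded factors.

Each response is modelled by the full second-order polynomial in the three
coded factors,

.. math::

   Y = b_0 + b_1 x_1 + b_2 x_2 + b_3 x_3
       + b_{12} x_1 x_2 + b_{13} x_1 x_3 + b_{23} x_2 x_3
       + b_{11} x_1^2 + b_{22} x_2^2 + b_{33} x_3^2,

fitted by ordinary least squares to the per-run response means.  Fitting on
the coded scale makes coefficients directly comparable across factors and
matches response-surface software convention; predictions are invariant to
the choice of scale.  No term selection is performed — the 10-term model is
always fitted in full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .doe import DesignTable, FactorSpec, code_setting

__all__ = [
    "TERM_NAMES",
    "RankError",
    "ExtrapolationWarning",
    "QuadraticModel",
    "quadratic_terms",
    "fit_quadratic",
    "predict_response",
    "checkpoint_analysis",
]

#: the 10 model terms in canonical order
TERM_NAMES = ("b0", "b1", "b2", "b3", "b12", "b13", "b23", "b11", "b22", "b33")


class RankError(ValueError):
    """Design cannot support the 10-term quadratic model."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested far outside the design cuboid (|coded| > 2)."""


def quadratic_terms(coded: np.ndarray) -> np.ndarray:
    """Expand coded settings (n × 3) into the 10-column model matrix."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    x1, x2, x3 = coded[:, 0], coded[:, 1], coded[:, 2]
    return np.column_stack(
        [
            np.ones_like(x1),
            x1,
            x2,
            x3,
            x1 * x2,
            x1 * x3,
            x2 * x3,
            x1**2,
            x2**2,
            x3**2,
        ]
    )


@dataclass
class QuadraticModel:
    """A fitted 10-coefficient quadratic response surface.

    Coefficients are in response units on the coded factor scale, ordered as
    :data:`TERM_NAMES` (intercept, linear, interaction, pure quadratic).
    """

    response_name: str
    factors: list[FactorSpec]
    coefficients: np.ndarray = field(repr=False)
    r_squared: float = float("nan")
    r_squared_adj: float = float("nan")
    residual_sd: float = float("nan")
    df_resid: int = 0
    f_statistic: float = float("nan")
    f_pvalue: float = float("nan")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("a quadratic model has exactly 10 coefficients")

    @property
    def coef_dict(self) -> dict[str, float]:
        return dict(zip(TERM_NAMES, self.coefficients))

    def code_settings(self, actual_settings: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Code a per-factor actual-units setting vector for this model."""
        if isinstance(actual_settings, Mapping):
            missing = [f.name for f in self.factors if f.name not in actual_settings]
            if missing:
                raise ValueError(f"missing settings for factors: {missing}")
            vals = [float(actual_settings[f.name]) for f in self.factors]
        else:
            vals = [float(v) for v in actual_settings]
            if len(vals) != len(self.factors):
                raise ValueError(
                    f"expected {len(self.factors)} settings, got {len(vals)}"
                )
        return np.array(
            [code_setting(f, v) for f, v in zip(self.factors, vals)], dtype=float
        )

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        """Evaluate the polynomial at coded settings (n × 3 or length-3)."""
        return quadratic_terms(coded) @ self.coefficients

    def predict(self, actual_settings: Mapping[str, float] | Sequence[float]) -> float:
        return predict_response(self, actual_settings)

    # flat key-value record so fits are diffable in version control
    def to_record(self) -> str:
        lines = [f"response: {self.response_name}"]
        lines.append("factors: " + ", ".join(f.name for f in self.factors))
        for name, value in self.coef_dict.items():
            lines.append(f"{name}: {float(value)!r}")
        lines.append(f"r_squared: {float(self.r_squared)!r}")
        lines.append(f"r_squared_adj: {float(self.r_squared_adj)!r}")
        lines.append(f"residual_sd: {float(self.residual_sd)!r}")
        lines.append(f"df_resid: {self.df_resid}")
        lines.append(f"f_statistic: {float(self.f_statistic)!r}")
        lines.append(f"f_pvalue: {float(self.f_pvalue)!r}")
        return "\n".join(lines) + "\n"


def fit_quadratic(design: DesignTable, response_name: str) -> QuadraticModel:
    """Fit the full quadratic model to one response by OLS on coded levels.

    Raises
    ------
    RankError
        If fewer than 10 runs carry the response or the design matrix is
        rank-deficient (e.g. replicated centre points only).
    """
    y = design.response(response_name)
    mask = np.isfinite(y)
    coded = design.coded_matrix()[mask]
    y = y[mask]
    if len(y) < len(TERM_NAMES):
        raise RankError(
            f"need >= {len(TERM_NAMES)} runs with {response_name!r} values, have {len(y)}"
        )
    X = quadratic_terms(coded)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError(
            "design matrix is rank-deficient for the 10-term quadratic model; "
            "the runs do not span all linear, interaction and squared terms"
        )
    res = sm.OLS(y, X).fit()
    return QuadraticModel(
        response_name=response_name,
        factors=list(design.factors),
        coefficients=np.asarray(res.params, dtype=float),
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        df_resid=int(res.df_resid),
        f_statistic=float(res.fvalue) if res.df_resid > 0 else float("nan"),
        f_pvalue=float(res.f_pvalue) if res.df_resid > 0 else float("nan"),
    )


def predict_response(
    model: QuadraticModel, actual_settings: Mapping[str, float] | Sequence[float]
) -> float:
    """Predict the response at actual-units settings.

    Settings are coded with the model's factors and fed through the
    polynomial.  Settings beyond twice the design half-range raise
    :class:`ExtrapolationWarning` (the value is still returned).
    """
    coded = model.code_settings(actual_settings)
    if np.any(np.abs(coded) > 2.0):
        warnings.warn(
            f"{model.response_name}: settings {np.round(coded, 3).tolist()} (coded) "
            "are far outside the design cuboid; prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(model.predict_coded(coded)[0])


def checkpoint_analysis(model: QuadraticModel, checkpoints: DesignTable) -> pd.DataFrame:
    """Compare observed checkpoint responses against model predictions.

    Returns one row per checkpoint run with observed, predicted, residual
    (observed − predicted) and relative error |residual| / |observed|.
    """
    if checkpoints.n_runs == 0:
        raise ValueError("checkpoint set is empty")
    observed = checkpoints.response(model.response_name)
    predicted = model.predict_coded(checkpoints.coded_matrix())
    residual = observed - predicted
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(residual) / np.abs(observed)
    return pd.DataFrame(
        {
            "run_id": checkpoints.data["run_id"].to_numpy(),
            "observed": observed,
            "predicted": predicted,
            "residual": residual,
            "relative_error": rel,
        }
    )
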
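"""Regression models linking fruit geometry to mass and volume.

Model family
------------
Univariate forms on a single predictor X (one of a, b, PA1, PA2, PA3, CPA,
V, Vellip, Vparab):

* ``linear``       Y = k1 + k2*X
* ``quadratic``    Y = k1 + k2*X + k3*X^2
* ``exponential``  Y = k1 * exp(k2*X)
* ``power``        Y = k1 * X^k2

Multivariate forms:

* ``multilinear``  Y = k1 + k2*X1 + ... (two axes a, b or three areas
  PA1..PA3)
* ``geometric``    Y = X (a direct geometric volume estimate, no fitting)

Goodness of fit is summarized by R^2, a Pearson-style chi-square
``sum((y - yhat)^2 / yhat)``, RMSE with denominator n, and the accuracy score
``phi = (100 - RMSE) / 100 * 100%``.  Model selection ranks by larger R^2,
then smaller chi-square, then smaller RMSE.

``reference_models()`` exposes the published coefficient registry for
*Rosa roxburghii* fruits (60-fruit field dataset): mass/volume models on
dimensions, projected areas, and geometric volumes, each with its reported
R^2, chi-square, and RMSE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DomainError,
    ModelKeyError,
    SchemaError,
    SingularFitError,
    UngradableError,
)
from .morphometry import FruitRecord, records_to_frame

__all__ = [
    "ModelForm",
    "FitMetrics",
    "RegressionModel",
    "SizeClass",
    "fit",
    "predict",
    "fit_metrics",
    "accuracy_from_rmse",
    "rank_models",
    "reference_models",
    "correlation_matrix",
    "grade",
    "default_size_classes",
    "REFERENCE_SIZE_SUMMARY",
    "dimension_model_forms",
    "projected_area_model_forms",
    "geometric_volume_model_forms",
    "fit_report",
    "model_to_json",
    "model_from_json",
]

_UNIVARIATE = ("linear", "quadratic", "exponential", "power")
_KINDS = _UNIVARIATE + ("multilinear", "geometric")
_PREDICTORS = ("a", "b", "PA1", "PA2", "PA3", "CPA", "V", "Vellip", "Vparab")
_RESPONSES = ("M", "V")


@dataclass(frozen=True)
class ModelForm:
    """A model shape: kind, predictor name(s), and response (M or V)."""

    kind: str
    predictors: tuple[str, ...]
    response: str

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise DomainError(f"unknown model kind {self.kind!r}")
        if self.response not in _RESPONSES:
            raise DomainError(f"response must be one of {_RESPONSES}")
        preds = tuple(self.predictors)
        object.__setattr__(self, "predictors", preds)
        for p in preds:
            if p not in _PREDICTORS:
                raise DomainError(f"unknown predictor {p!r}")
        if self.kind in _UNIVARIATE + ("geometric",) and len(preds) != 1:
            raise DomainError(f"{self.kind} form takes exactly one predictor")
        if self.kind == "multilinear" and len(preds) not in (2, 3):
            raise DomainError("multilinear form takes two or three predictors")

    @property
    def n_coefficients(self) -> int:
        return {
            "linear": 2,
            "quadratic": 3,
            "exponential": 2,
            "power": 2,
            "multilinear": len(self.predictors) + 1,
            "geometric": 0,
        }[self.kind]

    @property
    def key(self) -> tuple[str, str, tuple[str, ...]]:
        return (self.response, self.kind, self.predictors)


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    chi2: float
    rmse: float

    @property
    def phi(self) -> float:
        """Accuracy score (100 - RMSE)/100 x 100, in percent."""
        return accuracy_from_rmse(self.rmse)


@dataclass(frozen=True)
class RegressionModel:
    form: ModelForm
    coefficients: tuple[float, ...]
    metrics: FitMetrics | None = None
    note: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(self.coefficients))
        if len(self.coefficients) != self.form.n_coefficients:
            raise DomainError(
                f"{self.form.kind} form needs {self.form.n_coefficients} "
                f"coefficients, got {len(self.coefficients)}"
            )


def accuracy_from_rmse(rmse: float) -> float:
    """phi = (100 - RMSE) / 100 x 100%, taking RMSE in response units."""
    return (100.0 - rmse) / 100.0 * 100.0


# ---------------------------------------------------------------------------
# prediction


def _predictor_arrays(form: ModelForm, data) -> list[np.ndarray]:
    if isinstance(data, pd.DataFrame):
        getter = data.get
    elif isinstance(data, Mapping):
        getter = data.get
    else:
        raise DomainError("predictors must be a mapping or DataFrame")
    out = []
    for name in form.predictors:
        val = getter(name)
        if val is None:
            raise DomainError(f"missing predictor {name!r}")
        out.append(np.asarray(val, dtype=float))
    return out

def predict(model: RegressionModel, data):
    """Evaluate a model on a mapping / DataFrame of predictor values.

    Returns a scalar for scalar inputs, an ndarray otherwise.
    """
    xs = _predictor_arrays(model.form, data)
    k = model.coefficients
    kind = model.form.kind
    x = xs[0]
    if kind == "linear":
        out = k[0] + k[1] * x
    elif kind == "quadratic":
        out = k[0] + k[1] * x + k[2] * x**2
    elif kind == "exponential":
        out = k[0] * np.exp(k[1] * x)
    elif kind == "power":
        out = k[0] * np.power(x, k[1])
    elif kind == "multilinear":
        out = np.full_like(x, k[0], dtype=float)
        for coef, xi in zip(k[1:], xs):
            out = out + coef * xi
    elif kind == "geometric":
        out = x.astype(float)
    else:  # pragma: no cover - guarded by ModelForm
        raise DomainError(f"unknown kind {kind!r}")
    arr = np.asarray(out, dtype=float)
    return float(arr) if arr.ndim == 0 else arr


# ---------------------------------------------------------------------------
# metrics and ranking


def fit_metrics(y, y_hat, n_params: int | None = None) -> FitMetrics:
    """R^2, Pearson-style chi-square, RMSE (denominator n) of predictions.

    ``n_params`` is accepted for interface symmetry with the fitted models;
    the metrics here are deliberately unadjusted (RMSE uses n, not n - p).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise DomainError("y and y_hat must have equal nonzero length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("R^2 undefined: response has zero variance")
    if (y_hat <= 0).any():
        raise DomainError("chi-square requires all predictions > 0")
    sse = float(np.sum((y - y_hat) ** 2))
    return FitMetrics(
        r2=1.0 - sse / sst,
        chi2=float(np.sum((y - y_hat) ** 2 / y_hat)),
        rmse=math.sqrt(sse / y.size),
    )


def rank_models(models: Sequence[RegressionModel]) -> list[RegressionModel]:
    """Stable sort: R^2 descending, ties by chi-square then RMSE ascending."""
    if not models:
        raise DomainError("rank_models needs at least one model")
    for m in models:
        if m.metrics is None:
            raise DomainError("all models must carry metrics to be ranked")
    return sorted(models, key=lambda m: (-m.metrics.r2, m.metrics.chi2, m.metrics.rmse))


# ---------------------------------------------------------------------------
# fitting


def fit(data, form: ModelForm, response=None) -> RegressionModel:
    """Fit a model form by (non)linear least squares on training data.

    ``data`` is a DataFrame holding the predictor columns and, unless
    ``response`` is given separately, the response column.  Linear, quadratic
    and multilinear forms use ordinary least squares; exponential and power
    forms use nonlinear least squares on the original scale, initialized from
    the log-linearized fit.  Metrics are computed on the training data.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(data)
    if response is None:
        if form.response not in data.columns:
            raise SchemaError(f"data lacks response column {form.response!r}")
        y = np.asarray(data[form.response], dtype=float)
    else:
        y = np.asarray(response, dtype=float)
    xs = _predictor_arrays(form, data)
    n = y.size
    if form.kind == "geometric":
        model = RegressionModel(form=form, coefficients=())
        return RegressionModel(
            form=form, coefficients=(), metrics=fit_metrics(y, predict(model, data))
        )
    if n < form.n_coefficients + 1:
        raise SingularFitError(
            f"need at least {form.n_coefficients + 1} points, got {n}"
        )

    if form.kind in ("linear", "quadratic", "multilinear"):
        if form.kind == "linear":
            design = np.column_stack([np.ones(n), xs[0]])
        elif form.kind == "quadratic":
            design = np.column_stack([np.ones(n), xs[0], xs[0] ** 2])
        else:
            design = np.column_stack([np.ones(n), *xs])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SingularFitError("design matrix is rank deficient")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        coefficients = tuple(float(c) for c in coef)
    else:
        if (y <= 0).any():
            raise DomainError(f"{form.kind} fit requires all responses > 0")
        x = xs[0]
        if form.kind == "power" and (x <= 0).any():
            raise DomainError("power fit requires all predictors > 0")
        log_y = np.log(y)
        if form.kind == "exponential":
            slope, intercept = np.polyfit(x, log_y, 1)
            p0 = (math.exp(intercept), slope)
            func = lambda x, k1, k2: k1 * np.exp(k2 * x)  # noqa: E731
        else:
            slope, intercept = np.polyfit(np.log(x), log_y, 1)
            p0 = (math.exp(intercept), slope)
            func = lambda x, k1, k2: k1 * np.power(x, k2)  # noqa: E731
        try:
            coef, _ = curve_fit(func, x, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise SingularFitError(f"nonlinear fit failed to converge: {exc}") from exc
        coefficients = tuple(float(c) for c in coef)

    model = RegressionModel(form=form, coefficients=coefficients)
    y_hat = predict(model, data)
    return RegressionModel(
        form=form, coefficients=coefficients, metrics=fit_metrics(y, y_hat)
    )


# ---------------------------------------------------------------------------
# reference model registry
#
# Published coefficients and fit statistics for Rosa roxburghii fruits
# (n = 60).  Tuples: (response, kind, predictors, coefficients, R2, chi2,
# RMSE).  Two registry quirks are kept as notes on the entries: the mass
# block of the dimension table lists the exponential-in-b model twice and has
# no exponential-in-a slot, and the geometric ellipsoid volume row's R^2 was
# typeset with a stray leading digit in the source text (stored as 0.902).

_REFERENCE_TABLE = [
    # dimension-based: mass
    ("M", "linear", ("a",), (-27.485, 2.307), 0.929, 7.26, 1.43),
    ("M", "linear", ("b",), (-31.952, 3.384), 0.759, 23.69, 2.63),
    ("M", "quadratic", ("a",), (5.428, -0.960, 0.080), 0.935, 6.26, 1.37),
    ("M", "quadratic", ("b",), (44.588, -6.947, 0.346), 0.782, 19.89, 2.50),
    ("M", "exponential", ("b",), (1.168, 0.183), 0.779, 20.28, 2.52),
    ("M", "power", ("a",), (0.012, 2.446), 0.935, 6.29, 1.37),
    ("M", "power", ("b",), (0.009, 2.805), 0.778, 20.95, 2.53),
    ("M", "multilinear", ("a", "b"), (-31.970, 1.829, 0.941), 0.948, 5.38, 1.22),
    # dimension-based: volume
    ("V", "linear", ("a",), (-27.203, 2.271), 0.848, 17.48, 2.15),
    ("V", "linear", ("b",), (-34.525, 3.530), 0.778, 24.80, 2.60),
    ("V", "quadratic", ("a",), (-15.486, 1.108, 0.028), 0.849, 17.33, 2.15),
    ("V", "quadratic", ("b",), (3.190, -1.561, 0.170), 0.775, 23.43, 2.57),
    ("V", "exponential", ("a",), (1.691, 0.117), 0.839, 18.51, 2.22),
    ("V", "exponential", ("b",), (1.031, 0.190), 0.776, 23.78, 2.61),
    ("V", "power", ("a",), (0.012, 2.443), 0.846, 17.59, 2.16),
    ("V", "power", ("b",), (0.007, 2.920), 0.782, 23.38, 2.58),
    ("V", "multilinear", ("a", "b"), (-34.539, 1.490, 1.540), 0.896, 11.63, 1.78),
    # projected-area-based: mass
    ("M", "linear", ("PA1",), (-8.512, 2.793), 0.934, 6.94, 1.38),
    ("M", "linear", ("PA2",), (-7.987, 2.774), 0.923, 7.49, 1.48),
    ("M", "linear", ("PA3",), (-5.671, 1.934), 0.964, 3.39, 1.02),
    ("M", "linear", ("CPA",), (-8.109, 2.519), 0.978, 2.17, 0.79),
    ("M", "quadratic", ("PA1",), (4.864, 0.036, 0.137), 0.941, 5.92, 1.30),
    ("M", "quadratic", ("PA2",), (7.561, -0.400, 0.166), 0.933, 6.28, 1.39),
    ("M", "quadratic", ("PA3",), (0.838, 0.861, 0.042), 0.965, 3.24, 1.01),
    ("M", "quadratic", ("CPA",), (0.280, 0.940, 0.071), 0.981, 1.82, 0.73),
    ("M", "exponential", ("PA1",), (4.475, 0.143), 0.938, 6.07, 1.33),
    ("M", "exponential", ("PA2",), (4.479, 0.145), 0.932, 6.31, 1.39),
    ("M", "exponential", ("PA3",), (5.336, 0.096), 0.954, 4.01, 1.15),
    ("M", "exponential", ("CPA",), (4.620, 0.128), 0.976, 2.25, 0.82),
    ("M", "power", ("PA1",), (0.691, 1.445), 0.939, 6.26, 1.32),
    ("M", "power", ("PA2",), (0.696, 1.448), 0.929, 6.80, 1.42),
    ("M", "power", ("PA3",), (0.635, 1.332), 0.965, 3.22, 1.01),
    ("M", "power", ("CPA",), (0.620, 1.435), 0.981, 1.86, 0.74),
    ("M", "multilinear", ("PA1", "PA2", "PA3"), (-7.659, 0.714, 0.560, 1.114), 0.980, 27.75, 2.83),
    # projected-area-based: volume
    ("V", "linear", ("PA1",), (-8.618, 2.759), 0.858, 17.89, 2.08),
    ("V", "linear", ("PA2",), (-8.500, 2.783), 0.875, 13.96, 1.95),
    ("V", "linear", ("PA3",), (-5.463, 1.882), 0.860, 15.87, 2.07),
    ("V", "linear", ("CPA",), (-8.170, 2.483), 0.896, 12.18, 1.78),
    ("V", "quadratic", ("PA1",), (0.333, 0.915, 0.092), 0.861, 17.49, 2.06),
    ("V", "quadratic", ("PA2",), (-3.141, 1.655, 0.057), 0.876, 13.86, 1.94),
    ("V", "quadratic", ("PA3",), (-6.582, 2.060, -0.007), 0.860, 15.85, 2.07),
    ("V", "quadratic", ("CPA",), (-7.181, 2.297, 0.008), 0.896, 12.19, 1.78),
    ("V", "exponential", ("PA1",), (4.327, 0.144), 0.857, 18.03, 2.08),
    ("V", "exponential", ("PA2",), (4.301, 0.146), 0.870, 14.85, 1.99),
    ("V", "exponential", ("PA3",), (5.262, 0.096), 0.845, 17.93, 2.17),
    ("V", "exponential", ("CPA",), (4.502, 0.128), 0.886, 13.93, 1.87),
    ("V", "power", ("PA1",), (0.626, 1.476), 0.861, 17.51, 2.06),
    ("V", "power", ("PA2",), (0.648, 1.469), 0.876, 13.89, 1.94),
    ("V", "power", ("PA3",), (0.690, 1.289), 0.858, 16.11, 2.08),
    ("V", "power", ("CPA",), (0.602, 1.438), 0.895, 12.44, 1.79),
    ("V", "multilinear", ("PA1", "PA2", "PA3"), (-8.467, 0.657, 1.294, 0.628), 0.898, 11.83, 1.76),
    # geometric-volume-based: mass
    ("M", "linear", ("V",), (1.809, 0.921), 0.901, 9.90, 1.68),
    ("M", "linear", ("Vellip",), (1.085, 0.679), 0.966, 3.54, 0.99),
    ("M", "linear", ("Vparab",), (0.462, 0.944), 0.913, 8.35, 1.58),
    ("M", "quadratic", ("V",), (7.128, 0.310, 0.016), 0.911, 8.32, 1.59),
    ("M", "quadratic", ("Vellip",), (3.159, 0.515, 0.003), 0.967, 3.34, 0.98),
    ("M", "quadratic", ("Vparab",), (2.981, 0.677, 0.006), 0.914, 8.04, 1.57),
    ("M", "exponential", ("V",), (7.572, 0.047), 0.907, 8.46, 1.63),
    ("M", "exponential", ("Vellip",), (7.476, 0.034), 0.957, 4.04, 1.10),
    ("M", "exponential", ("Vparab",), (7.227, 0.047), 0.906, 8.51, 1.64),
    ("M", "power", ("V",), (1.302, 0.917), 0.898, 10.38, 1.71),
    ("M", "power", ("Vellip",), (0.858, 0.947), 0.965, 3.64, 1.00),
    ("M", "power", ("Vparab",), (1.024, 0.981), 0.912, 4.40, 1.58),
    # geometric-volume-based: volume (direct estimates, no fitted constants)
    ("V", "geometric", ("Vellip",), (), 0.902, 206.46, 7.95),
    ("V", "geometric", ("Vparab",), (), 0.887, 17.41, 2.11),
]

_NOTES = {
    ("M", "exponential", ("b",)): (
        "listed twice in the source table; the exponential-in-a mass slot is "
        "absent there"
    ),
    ("V", "geometric", ("Vellip",)): (
        "R^2 typeset with a stray leading digit in the source text; stored as 0.902"
    ),
}


def reference_models() -> dict[tuple, RegressionModel]:
    """Registry of the published mass/volume models, keyed by
    ``(response, kind, predictors)``."""
    registry = {}
    for response, kind, preds, coefs, r2, chi2, rmse in _REFERENCE_TABLE:
        form = ModelForm(kind=kind, predictors=preds, response=response)
        registry[form.key] = RegressionModel(
            form=form,
            coefficients=coefs,
            metrics=FitMetrics(r2=r2, chi2=chi2, rmse=rmse),
            note=_NOTES.get(form.key),
        )
    return registry


def reference_model(response: str, kind: str, predictors) -> RegressionModel:
    """Single registry lookup; raises :class:`ModelKeyError` on unknown keys."""
    if isinstance(predictors, str):
        predictors = (predictors,)
    key = (response, kind, tuple(predictors))
    registry = reference_models()
    if key not in registry:
        raise ModelKeyError(f"no reference model for key {key}")
    return registry[key]


# ---------------------------------------------------------------------------
# correlations

_CORRELATION_COLUMNS = ("a", "b", "PA1", "PA2", "PA3", "CPA", "M", "V")


def correlation_matrix(records, columns=_CORRELATION_COLUMNS) -> pd.DataFrame:
    """Pairwise Pearson correlations over the physical-characteristic columns."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns for correlation: {missing}")
    sub = df[list(columns)].astype(float)
    if len(sub) < 3:
        raise DomainError("need at least 3 records for correlations")
    if sub.isna().any().any():
        raise DomainError("correlation input contains missing values")
    stds = sub.std(ddof=0)
    constant = [c for c in columns if stds[c] == 0]
    if constant:
        raise DomainError(f"correlation undefined for constant columns: {constant}")
    return sub.corr(method="pearson")


# ---------------------------------------------------------------------------
# size grading

# Per-class mass/volume summaries of the 60-fruit reference dataset
# (20 fruits per class): (max, min, mean, sd).
REFERENCE_SIZE_SUMMARY = {
    "Large": {"mass_g": (29.76, 20.17, 24.88, 2.96), "volume_ml": (30.0, 19.0, 23.95, 3.51)},
    "Medium": {"mass_g": (18.76, 14.78, 15.99, 1.04), "volume_ml": (20.0, 12.0, 16.45, 2.38)},
    "Small": {"mass_g": (14.46, 10.73, 13.15, 1.11), "volume_ml": (17.0, 9.0, 12.47, 2.03)},
}


@dataclass(frozen=True)
class SizeClass:
    """A mass interval [lo_g, hi_g) assigned a grading label.

    The topmost class treats its upper bound as inclusive so the largest
    observed fruit remains gradable.
    """

    label: str
    lo_g: float
    hi_g: float

    def __post_init__(self):
        if not self.lo_g < self.hi_g:
            raise DomainError("size class bounds must be ordered")


def default_size_classes() -> list[SizeClass]:
    """Small/Medium/Large classes with boundaries at the midpoints between
    the reference per-class mass extremes."""
    small = REFERENCE_SIZE_SUMMARY["Small"]["mass_g"]
    medium = REFERENCE_SIZE_SUMMARY["Medium"]["mass_g"]
    large = REFERENCE_SIZE_SUMMARY["Large"]["mass_g"]
    sm_boundary = (small[0] + medium[1]) / 2.0  # between Small max and Medium min
    ml_boundary = (medium[0] + large[1]) / 2.0  # between Medium max and Large min
    return [
        SizeClass("Small", small[1], sm_boundary),
        SizeClass("Medium", sm_boundary, ml_boundary),
        SizeClass("Large", ml_boundary, large[0]),
    ]


def grade(
    record_or_mass,
    classes: Sequence[SizeClass] | None = None,
    model: RegressionModel | None = None,
) -> str:
    """Assign a size label from measured mass (or model-predicted mass).

    Accepts a mass in grams or a :class:`FruitRecord`; for records with no
    measured mass a mass model must be supplied.
    """
    if classes is None:
        classes = default_size_classes()
    if isinstance(record_or_mass, FruitRecord):
        mass = record_or_mass.mass_g
        if mass is None:
            if model is None or model.form.response != "M":
                raise DomainError("record lacks mass; supply a mass model")
            mass = float(predict(model, record_or_mass.features()))
    else:
        mass = float(record_or_mass)
    ordered = sorted(classes, key=lambda c: c.lo_g)
    for i, cls in enumerate(ordered):
        upper_ok = mass <= cls.hi_g if i == len(ordered) - 1 else mass < cls.hi_g
        if cls.lo_g <= mass and upper_ok:
            return cls.label
    raise UngradableError(f"mass {mass:g} g falls outside every size class")


# ---------------------------------------------------------------------------
# form suites and reports


def dimension_model_forms(response: str) -> list[ModelForm]:
    """The nine dimension-based forms per response (axes a and b)."""
    forms = []
    for kind in _UNIVARIATE:
        for pred in ("a", "b"):
            forms.append(ModelForm(kind=kind, predictors=(pred,), response=response))
    forms.append(ModelForm(kind="multilinear", predictors=("a", "b"), response=response))
    return forms


def projected_area_model_forms(response: str) -> list[ModelForm]:
    """The seventeen projected-area-based forms per response."""
    forms = []
    for kind in _UNIVARIATE:
        for pred in ("PA1", "PA2", "PA3", "CPA"):
            forms.append(ModelForm(kind=kind, predictors=(pred,), response=response))
    forms.append(
        ModelForm(kind="multilinear", predictors=("PA1", "PA2", "PA3"), response=response)
    )
    return forms


def geometric_volume_model_forms(response: str) -> list[ModelForm]:
    """Geometric-volume-based forms (predictors V, Vellip, Vparab)."""
    forms = []
    for kind in _UNIVARIATE:
        for pred in ("V", "Vellip", "Vparab"):
            forms.append(ModelForm(kind=kind, predictors=(pred,), response=response))
    return forms


def fit_report(data: pd.DataFrame, forms: Iterable[ModelForm]) -> pd.DataFrame:
    """Fit a suite of forms and lay the results out as a coefficient table
    (model, k1..k4, R2, chi2, RMSE)."""
    rows = []
    for form in forms:
        model = fit(data, form)
        coefs = list(model.coefficients) + [None] * (4 - len(model.coefficients))
        rows.append(
            {
                "response": form.response,
                "kind": form.kind,
                "predictors": "+".join(form.predictors),
                "k1": coefs[0],
                "k2": coefs[1],
                "k3": coefs[2],
                "k4": coefs[3],
                "r2": model.metrics.r2,
                "chi2": model.metrics.chi2,
                "rmse": model.metrics.rmse,
                "phi_pct": model.metrics.phi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model JSON IO (bit-exact round trip)


def model_to_json(model: RegressionModel, path) -> None:
    payload = {
        "response": model.form.response,
        "form": model.form.kind,
        "predictors": list(model.form.predictors),
        "coefficients": [c.hex() for c in map(float, model.coefficients)],
        "metrics": None
        if model.metrics is None
        else {
            "r2": model.metrics.r2.hex(),
            "chi2": model.metrics.chi2.hex(),
            "rmse": model.metrics.rmse.hex(),
        },
        "note": model.note,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def model_from_json(path) -> RegressionModel:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        form = ModelForm(
            kind=raw["form"],
            predictors=tuple(raw["predictors"]),
            response=raw["response"],
        )
        coefs = tuple(float.fromhex(c) for c in raw["coefficients"])
        metrics = raw.get("metrics")
    except KeyError as exc:
        raise SchemaError(f"model file missing key {exc}") from exc
    fm = (
        None
        if metrics is None
        else FitMetrics(
            r2=float.fromhex(metrics["r2"]),
            chi2=float.fromhex(metrics["chi2"]),
            rmse=float.fromhex(metrics["rmse"]),
        )
    )
    return RegressionModel(form=form, coefficients=coefs, metrics=fm, note=raw.get("note"))
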
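"""Linear-in-features statistical models for gait-parameter prediction.

The walking model is a passive template and systematically underestimates
contact time; compensatory regression models close the gap.  Two kinds of
model live here:

* compensatory models -- the contact-time factor ``Atc`` (experimental over
  simulated contact time, one model per parameter constraint) and the
  vertical-GRF trough value ``Fv_min`` used as simulation input under the
  kinetic constraint F;
* direct reference predictors -- ``tc``, ``Fv_max``, ``Fap_max`` straight
  from the subject descriptors, used to benchmark the model-based pipeline.

All models are linear in the features ``{1, vG, sqrt(vG), h0, m0}`` with
``vG`` in m/s, ``h0`` in m and ``m0`` in kg.  Force-valued targets are in
body-weight units, ``tc`` in seconds, ``Atc`` dimensionless.  The builtin
registry carries the published calibration coefficients; :func:`fit`
recalibrates any model form from new trial data by ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

FEATURES = ("1", "vG", "sqrt_vG", "h0", "m0")

#: subject attribute backing each non-constant feature
_FEATURE_SOURCE = {"vG": "gait_speed", "sqrt_vG": "gait_speed",
                   "h0": "body_height", "m0": "body_mass"}


class MissingFieldError(ValueError):
    """A subject lacks a field required by the model's feature set."""


@dataclass(frozen=True)
class GoodnessOfFit:
    """R^2 and interquartile-normalized RMSE of a fit."""

    r_squared: float
    nrmse: float
    n: int


@dataclass(frozen=True)
class RegressionModel:
    """A linear-in-features model ``target = sum_i c_i * feature_i``.

    ``coefficients`` aligns with ``features``; ``coefficient_cis`` are the
    95% confidence half-widths.  ``r_squared``/``nrmse`` are metadata from
    calibration (``None`` when not applicable, e.g. constant models).
    """

    name: str
    target: str
    features: tuple
    coefficients: tuple
    coefficient_cis: tuple = None
    r_squared: float = None
    nrmse: float = None

    def __post_init__(self):
        if len(self.features) != len(self.coefficients):
            raise ValueError("coefficient count must equal feature count")
        for f in self.features:
            if f not in FEATURES:
                raise ValueError(f"unknown feature {f!r}")

    def design_row(self, subject) -> np.ndarray:
        return np.array([_evaluate_feature(f, subject) for f in self.features])

    def __call__(self, subject) -> float:
        return predict(self, subject)


def _get_field(subject, attr: str, feature: str) -> float:
    if isinstance(subject, (Mapping, pd.Series)):
        key = {"gait_speed": "vG", "body_height": "h0", "body_mass": "m0"}[attr]
        if key in subject:
            return float(subject[key])
        if attr in subject:
            return float(subject[attr])
        raise MissingFieldError(
            f"feature {feature!r} requires field {key!r} which is missing")
    value = getattr(subject, attr, None)
    if value is None:
        raise MissingFieldError(
            f"feature {feature!r} requires subject attribute {attr!r}")
    return float(value)


def _evaluate_feature(feature: str, subject) -> float:
    if feature == "1":
        return 1.0
    value = _get_field(subject, _FEATURE_SOURCE[feature], feature)
    if feature == "sqrt_vG":
        return math.sqrt(value)
    return value


def predict(model: RegressionModel, subject) -> float:
    """Evaluate a model for a subject (``SubjectProfile`` or mapping).

    Deterministic dot product of coefficients with evaluated features;
    units are those of the model target.
    """
    return float(np.dot(model.coefficients, model.design_row(subject)))


# ---------------------------------------------------------------------------
# Builtin registry (published calibration on 365 training trials)

def _m(name, target, feats, coefs, cis, r2, nrmse):
    return RegressionModel(name=name, target=target, features=tuple(feats),
                           coefficients=tuple(coefs), coefficient_cis=tuple(cis),
                           r_squared=r2, nrmse=nrmse)


_BUILTINS = (
    # Atc, constraint V: the constant model is the committed choice (low R^2
    # of the linear alternative).
    _m("Atc_V", "Atc", ("1",), (1.531,), (0.007,), None, 0.621),
    _m("Atc_V_lin", "Atc", ("vG", "h0", "m0", "1"),
       (0.0164, -0.126, -0.00166, 1.868), (0.0347, 0.093, 0.00085, 0.135),
       0.193, 0.561),
    # Atc, constraint F: the linear model is committed (clearly higher R^2).
    _m("Atc_F_const", "Atc", ("1",), (1.461,), (0.013,), None, 0.881),
    _m("Atc_F", "Atc", ("vG", "h0", "m0", "1"),
       (-0.436, 0.113, -0.000910, 1.973), (0.055, 0.150, 0.001358, 0.215),
       0.414, 0.677),
    # direct contact-time models (s); sqrt(vG) form committed
    _m("tc_lin", "tc", ("vG", "h0", "m0", "1"),
       (-0.298, 0.297, -0.000652, 0.627), (0.017, 0.046, 0.000419, 0.067),
       0.802, 0.407),
    _m("tc", "tc", ("sqrt_vG", "h0", "m0", "1"),
       (-0.696, 0.292, -0.000648, 1.034), (0.038, 0.045, 0.000407, 0.076),
       0.813, 0.395),
    _m("tc_full", "tc", ("vG", "sqrt_vG", "h0", "m0", "1"),
       (-3.246, 1.104, 0.280, 0.000483, 2.510),
       (0.790, 0.341, 0.043, 0.000389, 0.462), 0.832, 0.375),
    # maximum vertical GRF (body weights); sqrt(vG) form committed
    _m("Fv_max_lin", "Fv_max", ("vG", "h0", "1"),
       (0.212, -0.337, 1.523), (0.032, 0.058, 0.112), 0.446, 0.606),
    _m("Fv_max", "Fv_max", ("sqrt_vG", "h0", "1"),
       (0.490, -0.336, 1.240), (0.074, 0.058, 0.134), 0.446, 0.605),
    _m("Fv_max_full", "Fv_max", ("vG", "sqrt_vG", "h0", "1"),
       (0.529, -0.0171, -0.336, 1.217), (1.615, 0.6985, 0.058, 0.937),
       0.446, 0.606),
    # maximum absolute anteroposterior GRF (body weights)
    _m("Fap_max_lin", "Fap_max", ("vG", "h0", "1"),
       (0.111, -0.171, 0.386), (0.014, 0.025, 0.048), 0.537, 0.506),
    _m("Fap_max", "Fap_max", ("sqrt_vG", "h0", "1"),
       (0.258, -0.170, 0.237), (0.032, 0.025, 0.058), 0.537, 0.506),
    _m("Fap_max_full", "Fap_max", ("vG", "sqrt_vG", "h0", "1"),
       (0.143, 0.0495, -0.170, 0.303), (0.697, 0.3014, 0.025, 0.405),
       0.537, 0.507),
    # vertical-GRF trough value (body weights); the sqrt(vG) form is the
    # committed choice (it recovers Fv_min -> 1 BW as vG -> 0)
    _m("Fv_min_lin", "Fv_min", ("vG", "h0", "1"),
       (-0.346, 0.146, 0.919), (0.026, 0.048, 0.093), 0.658, 0.520),
    _m("Fv_min", "Fv_min", ("sqrt_vG", "h0", "1"),
       (-0.800, 0.146, 1.380), (0.061, 0.048, 0.111), 0.659, 0.519),
    _m("Fv_min_full", "Fv_min", ("sqrt_vG", "vG", "h0", "1"),
       (-0.745, -0.0238, 0.146, 1.348), (1.333, 0.5765, 0.048, 0.774),
       0.659, 0.520),
)

#: names of the committed (selected) model per target/constraint
SELECTED_MODELS = {
    "Atc_V": "Atc_V", "Atc_F": "Atc_F", "tc": "tc", "Fv_max": "Fv_max",
    "Fap_max": "Fap_max", "Fv_min": "Fv_min",
}


def builtin_models() -> dict:
    """Registry of calibrated models, keyed by name.

    The keys without suffix (``Atc_V``, ``Atc_F``, ``tc``, ``Fv_max``,
    ``Fap_max``, ``Fv_min``) are the committed selections; ``*_lin`` /
    ``*_full`` / ``*_const`` are the published alternatives.
    """
    return {m.name: m for m in _BUILTINS}


# ---------------------------------------------------------------------------
# Fitting and goodness of fit


def goodness(observed, predicted) -> GoodnessOfFit:
    """R^2 and NRMSE of predictions against observations.

    ``r_squared = 1 - SS_res / SS_tot``; ``nrmse = RMSE / (Q3 - Q1)`` of
    the observed values (linearly interpolated quartiles), so single
    outliers do not dominate the normalizer.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    iqr = np.percentile(obs, 75) - np.percentile(obs, 25)
    if iqr <= 0:
        raise ValueError("interquartile range of observations is zero; NRMSE undefined")
    resid = obs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    nrmse = math.sqrt(ss_res / n) / float(iqr)
    return GoodnessOfFit(r_squared=float(r2), nrmse=nrmse, n=n)


def fit(target: str, features: Sequence[str], data: pd.DataFrame,
        name: str = None) -> RegressionModel:
    """Calibrate a model form on trial data by ordinary least squares.

    ``data`` needs one column per non-constant feature source (``vG``,
    ``h0``, ``m0`` as required) and a column named ``target``.  95%
    coefficient confidence half-widths come from the t distribution.
    """
    features = tuple(features)
    for f in features:
        if f not in FEATURES:
            raise ValueError(f"unknown feature {f!r}")
    y = np.asarray(data[target], dtype=float)
    n = y.size
    if n <= len(features):
        raise ValueError(
            f"need more observations ({n}) than features ({len(features)})")
    cols = []
    for f in features:
        if f == "1":
            cols.append(np.ones(n))
        elif f == "vG":
            cols.append(np.asarray(data["vG"], dtype=float))
        elif f == "sqrt_vG":
            cols.append(np.sqrt(np.asarray(data["vG"], dtype=float)))
        else:
            cols.append(np.asarray(data[f], dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix; cannot fit")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    half = tuple(float(hw) for hw in (ci[:, 1] - ci[:, 0]) / 2.0)
    gof = goodness(y, res.predict(X))
    return RegressionModel(
        name=name or f"fit_{target}", target=target, features=features,
        coefficients=tuple(float(c) for c in res.params),
        coefficient_cis=half, r_squared=gof.r_squared, nrmse=gof.nrmse)


# ---------------------------------------------------------------------------
# Registry YAML round-trip (recalibrated models are drop-in replacements)


def registry_to_yaml(models: Mapping[str, RegressionModel], path) -> None:
    payload = {
        name: {
            "target": m.target,
            "features": list(m.features),
            "coefficients": [float(c) for c in m.coefficients],
            "coefficient_cis": [float(c) for c in m.coefficient_cis]
            if m.coefficient_cis is not None else None,
            "r_squared": None if m.r_squared is None else float(m.r_squared),
            "nrmse": None if m.nrmse is None else float(m.nrmse),
        }
        for name, m in models.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def registry_from_yaml(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = {}
    for name, spec in payload.items():
        out[name] = RegressionModel(
            name=name, target=spec["target"], features=tuple(spec["features"]),
            coefficients=tuple(spec["coefficients"]),
            coefficient_cis=tuple(spec["coefficient_cis"])
            if spec.get("coefficient_cis") else None,
            r_squared=spec.get("r_squared"), nrmse=spec.get("nrmse"))
    return out
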
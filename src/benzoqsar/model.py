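"""Activity models, validation statistics, binning and outlier rules.

Two regressors share the predict interface:

* :class:`PublishedActivityModel` — the fixed five-descriptor affine
  equation linking the descriptors to log 1/c (the published benzodiazepine
  GABA-A activity model);
* :class:`PLSActivityModel` — a PLS1 regression fitted to a training set,
  with the latent-variable count chosen by leave-one-out cross-validation
  when not given.

Validation follows the QSAR conventions: r² is the squared Pearson
correlation of predicted versus experimental activity (the correlation-plot
definition), xr² is its leave-one-out analogue
1 − Σ(y_i − ŷ₍₋ᵢ₎)² / Σ(y_i − ȳ)², and RMSE is the root mean squared
residual. Predicted activities are binned into low / medium / high potency
classes, and predictions deviating by more than 2.5 log units are flagged
as true outliers.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .descriptors import DESCRIPTOR_NAMES

# ---------------------------------------------------------------------------
# Published equation
# ---------------------------------------------------------------------------

PUBLISHED_INTERCEPT = 9.45416
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "h_log_pbo": 0.77505,
    "kier_flex": 1.24990,
    "q_vsa_hyd": -0.03382,
    "slogp_vsa7": -0.01507,
    "vsa_pol": -0.03849,
}


class PublishedActivityModel(RegressorMixin, BaseEstimator):
    """The fixed five-descriptor log 1/c equation.

    log 1/c = 9.45416 + 0.77505·h_log_pbo + 1.24990·KierFlex
              − 0.03382·Q_VSA_HYD − 0.01507·SlogP_VSA7 − 0.03849·vsa_pol

    ``fit`` only validates input shape — the constants are immutable.
    """

    intercept_ = PUBLISHED_INTERCEPT
    coef_ = np.array([PUBLISHED_COEFFICIENTS[n] for n in DESCRIPTOR_NAMES])
    feature_names_ = DESCRIPTOR_NAMES

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names_)
        if X.shape[1] != 5:
            raise ValueError(f"expected 5 descriptor columns, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("descriptor values must be finite")
        return self.intercept_ + X @ self.coef_

    def __sklearn_is_fitted__(self) -> bool:
        return True


def predict_published(descriptors) -> np.ndarray | float:
    """Evaluate the published equation on one vector or a matrix."""
    arr = np.asarray(
        descriptors.as_array() if hasattr(descriptors, "as_array")
        else descriptors, dtype=float)
    model = PublishedActivityModel()
    if arr.ndim == 1:
        return float(model.predict(arr.reshape(1, -1))[0])
    return model.predict(arr)


# ---------------------------------------------------------------------------
# PLS regression
# ---------------------------------------------------------------------------

class PLSActivityModel(RegressorMixin, BaseEstimator):
    """PLS1 activity regression with LOO-selected latent-variable count.

    Parameters
    ----------
    n_components : int or None
        Latent-variable count; when None the count maximising the
        leave-one-out xr² is chosen (capped at the descriptor count).
    scale : bool
        Autoscale descriptors inside the PLS fit (the coefficients reported
        in ``coef_``/``intercept_`` are always on the original scale).

    Attributes
    ----------
    coef_, intercept_ : original-scale regression coefficients.
    n_components_ : chosen latent-variable count.
    feature_names_in_ : descriptor names when fitted from a DataFrame.
    r2_train_, xr2_ : squared Pearson correlation of the fit and the
        leave-one-out cross-validated xr² on the training data.
    """

    def __init__(self, n_components: int | None = None, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if np.ptp(y) == 0:
            raise ValueError("constant activity vector: nothing to fit")

        keep = np.ptp(X, axis=0) > 0
        if not keep.all():
            dropped = [names[i] if names else str(i)
                       for i in np.flatnonzero(~keep)]
            warnings.warn(f"dropping zero-variance descriptor(s): {dropped}",
                          stacklevel=2)
        self._keep_ = keep
        self.feature_names_in_ = (np.asarray(names, dtype=object)
                                  if names is not None else None)
        Xk = X[:, keep]
        max_k = min(Xk.shape[1], Xk.shape[0] - 1)
        if self.n_components is None:
            xr2s = [loo_xr2(Xk, y, k, scale=self.scale)
                    for k in range(1, max_k + 1)]
            self.n_components_ = int(np.argmax(xr2s)) + 1
            self.xr2_ = float(xr2s[self.n_components_ - 1])
        else:
            if self.n_components > max_k:
                raise ValueError(
                    f"n_components={self.n_components} exceeds usable rank {max_k}")
            self.n_components_ = int(self.n_components)
            self.xr2_ = float(loo_xr2(Xk, y, self.n_components_,
                                      scale=self.scale))

        self._pls_ = PLSRegression(n_components=self.n_components_,
                                   scale=self.scale).fit(Xk, y)
        # Original-scale affine form extracted by linear probing, which is
        # robust to sklearn's coef_ orientation changes.
        zero = self._pls_.predict(np.zeros((1, Xk.shape[1]))).ravel()[0]
        probes = self._pls_.predict(np.eye(Xk.shape[1])).ravel() - zero
        self.intercept_ = float(zero)
        coef = np.zeros(X.shape[1])
        coef[keep] = probes
        self.coef_ = coef
        self.r2_train_ = float(pearson_r2(y, self.predict(X)))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_pls_")
        names = (list(self.feature_names_in_)
                 if self.feature_names_in_ is not None else None)
        X = np.asarray(_as_matrix(X, names), dtype=float)
        return self.intercept_ + X @ self.coef_

    def to_dict(self) -> dict:
        check_is_fitted(self, "_pls_")
        names = (list(self.feature_names_in_)
                 if self.feature_names_in_ is not None
                 else [f"x{i}" for i in range(len(self.coef_))])
        return {
            "descriptors": names,
            "coefficients": dict(zip(names, map(float, self.coef_))),
            "intercept": self.intercept_,
            "n_latent_variables": self.n_components_,
            "r2_train": self.r2_train_,
            "xr2_loo": self.xr2_,
        }


def fit_pls(X, y, n_latent: int | None = None) -> PLSActivityModel:
    """Fit a PLS activity model (thin wrapper over the estimator)."""
    return PLSActivityModel(n_components=n_latent).fit(X, y)


def loo_xr2(X, y, n_components: int, scale: bool = True) -> float:
    """Leave-one-out cross-validated xr².

    xr² = 1 − Σ(y_i − ŷ₍₋ᵢ₎)² / Σ(y_i − ȳ)², each ŷ₍₋ᵢ₎ predicted by a
    model fitted without sample i. Can be negative for uninformative models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant activity vector")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pls = PLSRegression(n_components=n_components, scale=scale)
        pls.fit(X[mask], y[mask])
        pred = pls.predict(X[i:i + 1]).ravel()[0]
        press += (y[i] - pred) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


# ---------------------------------------------------------------------------
# Validation statistics
# ---------------------------------------------------------------------------

def pearson_r2(observed, predicted) -> float:
    """Squared Pearson correlation (the correlation-plot r²)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    so, sp = observed.std(), predicted.std()
    if so == 0 or sp == 0:
        return 0.0
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def rmse(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


OUTLIER_THRESHOLD = 2.5


def flag_outliers(ids, experimental, predicted,
                  threshold: float = OUTLIER_THRESHOLD,
                  absolute: bool = True) -> list[tuple[str, float]]:
    """Flag molecules whose prediction deviates by more than ``threshold``.

    The deviation is |predicted − experimental| by default so that badly
    under-predicted compounds are caught too; with ``absolute=False`` only
    over-predictions (predicted − experimental > threshold) are flagged.
    The comparison is strict: a deviation of exactly 2.5 is not an outlier.
    """
    experimental = np.asarray(experimental, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (np.all(np.isfinite(experimental)) and np.all(np.isfinite(predicted))):
        raise ValueError("experimental and predicted values must be finite")
    deviation = predicted - experimental
    if absolute:
        deviation = np.abs(deviation)
    return [(str(i), float(d)) for i, d in zip(ids, deviation) if d > threshold]


@dataclass
class ValidationReport:
    """Train/test evaluation of an activity model."""

    r2_train: float | None
    xr2_loo: float | None
    r2_test: float
    rmse_train: float | None
    rmse_test: float
    outliers: list[tuple[str, float]] = field(default_factory=list)
    residuals: pd.DataFrame | None = None
    r2_test_explained: float | None = None   # 1 − SSres/SStot variant

    def summary(self) -> dict:
        return {
            "r2_train": self.r2_train, "xr2_loo": self.xr2_loo,
            "r2_test": self.r2_test, "rmse_train": self.rmse_train,
            "rmse_test": self.rmse_test,
            "r2_test_explained": self.r2_test_explained,
            "outliers": [{"id": i, "deviation": d} for i, d in self.outliers],
        }


def validate(model, X_test, y_test, ids=None,
             outlier_threshold: float = OUTLIER_THRESHOLD) -> ValidationReport:
    """External validation of a fitted model on a held-out test set.

    Descriptors must have been computed with the same parameters as the
    training set. r² is the squared Pearson correlation of predicted vs
    experimental; the explained-variance variant (which differs for PLS
    fits) is reported alongside.
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) == 0:
        raise ValueError("empty test set")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(y_test))]
    predicted = np.asarray(model.predict(X_test), dtype=float).ravel()
    ss_tot = np.sum((y_test - y_test.mean()) ** 2)
    explained = float(1 - np.sum((y_test - predicted) ** 2) / ss_tot) \
        if ss_tot > 0 else None
    residuals = pd.DataFrame({
        "id": ids, "experimental": y_test, "predicted": predicted,
        "residual": predicted - y_test})
    return ValidationReport(
        r2_train=getattr(model, "r2_train_", None),
        xr2_loo=getattr(model, "xr2_", None),
        r2_test=pearson_r2(y_test, predicted),
        rmse_train=None,
        rmse_test=rmse(y_test, predicted),
        outliers=flag_outliers(ids, y_test, predicted, outlier_threshold),
        residuals=residuals,
        r2_test_explained=explained,
    )


# ---------------------------------------------------------------------------
# Activity bins
# ---------------------------------------------------------------------------

class ActivityBin(str, enum.Enum):
    """Potency class of a predicted log 1/c value.

    low: [5.80, 7.00) — medium: [7.00, 8.00) — high: [8.00, ∞).
    Values below 5.80 fall outside the training activity span.
    """

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    OUT_OF_RANGE = "out_of_range"


BIN_EDGES = (5.80, 7.00, 8.00)


def bin_activity(value: float,
                 edges: tuple[float, float, float] = BIN_EDGES) -> ActivityBin:
    """Assign a predicted log 1/c to its potency bin (half-open intervals)."""
    if not np.isfinite(value):
        raise ValueError(f"activity value must be finite, got {value}")
    low, mid, high = edges
    if value < low:
        warnings.warn(f"predicted activity {value:.2f} below the modelled "
                      f"range (<{low})", stacklevel=2)
        return ActivityBin.OUT_OF_RANGE
    if value < mid:
        return ActivityBin.LOW
    if value < high:
        return ActivityBin.MEDIUM
    return ActivityBin.HIGH


def _as_matrix(X, names):
    if isinstance(X, pd.DataFrame):
        if names is not None and set(names).issubset(X.columns):
            return X.loc[:, list(names)].to_numpy(dtype=float)
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    return arr.reshape(1, -1) if arr.ndim == 1 else arr
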
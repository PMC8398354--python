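"""Two-stage descriptor selection.

Stage 1 keeps descriptors whose Pearson correlation with the activity has
|r| ≥ 0.5 (weakly correlated or non-contributory descriptors are deleted).
Stage 2 enforces mutual non-collinearity: while any surviving pair has
|r| > 0.7, the member with the weaker activity correlation is dropped.
The survivors therefore never contain a pair with mutual |r| > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

ACTIVITY_CORR_MIN = 0.5
COLLINEARITY_MAX = 0.7


@dataclass
class SelectionReport:
    """All correlations computed during selection."""

    activity_corr: pd.Series            # r(descriptor, activity), all inputs
    mutual_corr: pd.DataFrame           # pairwise r among stage-1 survivors
    dropped_low_corr: list[str]
    dropped_collinear: list[str]
    selected: list[str]


class CorrelationSelector(TransformerMixin, BaseEstimator):
    """Sklearn transformer implementing the two-stage selection cascade.

    Parameters
    ----------
    activity_corr_min : float
        Minimum |Pearson r| to the activity for a descriptor to survive.
    collinearity_max : float
        Maximum allowed mutual |Pearson r| between two survivors.

    Attributes
    ----------
    selected_ : list of surviving descriptor names.
    support_ : boolean mask over the input columns.
    report_ : :class:`SelectionReport` with every correlation computed.
    """

    def __init__(self, activity_corr_min: float = ACTIVITY_CORR_MIN,
                 collinearity_max: float = COLLINEARITY_MAX):
        self.activity_corr_min = activity_corr_min
        self.collinearity_max = collinearity_max

    def fit(self, X, y):
        X = pd.DataFrame(X).copy()
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] < 2:
            raise ValueError("need at least 2 candidate descriptors")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 samples for stable correlations")

        r_act = X.apply(lambda col: _pearson(col.to_numpy(dtype=float), y))
        stage1 = [c for c in X.columns
                  if abs(r_act[c]) >= self.activity_corr_min]
        dropped_low = [c for c in X.columns if c not in stage1]
        if not stage1:
            best = r_act.abs().sort_values(ascending=False).head(5)
            raise ValueError(
                "no descriptor reaches the activity-correlation threshold "
                f"{self.activity_corr_min}; best candidates: {best.to_dict()}")

        mutual = X[stage1].corr(method="pearson")
        survivors = list(stage1)
        dropped_coll: list[str] = []
        while True:
            worst_pair, worst_r = None, self.collinearity_max
            for i, a in enumerate(survivors):
                for b in survivors[i + 1:]:
                    r = abs(mutual.loc[a, b])
                    if r > worst_r:
                        worst_pair, worst_r = (a, b), r
            if worst_pair is None:
                break
            a, b = worst_pair
            loser = a if abs(r_act[a]) < abs(r_act[b]) else b
            survivors.remove(loser)
            dropped_coll.append(loser)

        self.selected_ = survivors
        self.support_ = np.array([c in survivors for c in X.columns])
        self.report_ = SelectionReport(
            activity_corr=r_act, mutual_corr=mutual,
            dropped_low_corr=dropped_low, dropped_collinear=dropped_coll,
            selected=survivors)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "selected_")
        return np.asarray(self.selected_, dtype=object)


def select_descriptors(X, y, activity_corr_min: float = ACTIVITY_CORR_MIN,
                       collinearity_max: float = COLLINEARITY_MAX,
                       ) -> tuple[list[str], SelectionReport]:
    """Functional wrapper: returns (selected names, correlation report)."""
    sel = CorrelationSelector(activity_corr_min, collinearity_max).fit(X, y)
    return sel.selected_, sel.report_


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
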
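"""Differential peak screening between response and progression groups.

A peak passes the screen when its two-sided Welch t-test p-value is below
``p_threshold`` (default 1e-4) *and* its oriented ROC AUC is at least
``auc_threshold`` (default 0.75).  The AUC is always reported >= 0.5 together
with an explicit direction flag (up or down in the progression group), the
convention used when pairing an AUC with an expression-change arrow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .spectra import PROGRESSION, RESPONSE, PeakMatrix

__all__ = [
    "DiffPeakResult",
    "welch_t_test",
    "roc_auc",
    "screen_differential_peaks",
    "DifferentialPeakScreen",
    "UP_IN_PROGRESSION",
    "DOWN_IN_PROGRESSION",
]

UP_IN_PROGRESSION = "up_in_progression"
DOWN_IN_PROGRESSION = "down_in_progression"


@dataclass
class DiffPeakResult:
    """Per-peak group summary mirroring a differential-peak table row."""

    reference_mz: float
    mean_response: float
    sd_response: float
    mean_progression: float
    sd_progression: float
    t_statistic: float
    p_value: float
    auc: float
    direction: str
    selected: bool


def welch_t_test(a: np.ndarray, b: np.ndarray, pooled: bool = False) -> tuple[float, float]:
    """Two-sided unequal-variance (Welch) t-test; ``pooled=True`` switches to
    the classic equal-variance test.

    Degenerate inputs: two constant groups with equal values give (0, 1) by
    convention; constant groups with unequal values give (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p)


def roc_auc(areas: np.ndarray, labels: np.ndarray) -> tuple[float, str]:
    """Oriented ROC AUC of a peak area for progression vs response.

    The raw AUC is the Mann-Whitney concordance P(area_progression >
    area_response), ties counting one half.  The reported AUC is
    max(raw, 1 - raw); the direction flag is ``up_in_progression`` iff the
    progression-group mean exceeds the response-group mean.
    """
    areas = np.asarray(areas, dtype=float)
    labels = np.asarray(labels, dtype=object)
    is_prog = labels == PROGRESSION
    if is_prog.all() or (~is_prog).all():
        raise ValueError("both group labels must be present")
    if np.ptp(areas) == 0:
        raw = 0.5
    else:
        raw = float(roc_auc_score(is_prog.astype(int), areas))
    direction = (
        UP_IN_PROGRESSION
        if areas[is_prog].mean() > areas[~is_prog].mean()
        else DOWN_IN_PROGRESSION
    )
    return max(raw, 1.0 - raw), direction


def screen_differential_peaks(
    m: PeakMatrix,
    p_threshold: float = 1e-4,
    auc_threshold: float = 0.75,
    bonferroni: bool = False,
    pooled: bool = False,
) -> pd.DataFrame:
    """Screen every reference peak; return all rows sorted by ascending p.

    The returned frame has one row per peak with the group means/SDs, Welch
    t, two-sided p, oriented AUC, direction flag and a boolean ``selected``
    column marking peaks that satisfy p < p_threshold and AUC >=
    auc_threshold.  ``bonferroni`` divides the p threshold by the number of
    peaks first (off by default: the screen applies the raw threshold).
    """
    labels = m.labels_array()
    is_resp = labels == RESPONSE
    is_prog = labels == PROGRESSION
    if not (is_resp.any() and is_prog.any()):
        raise ValueError("peak matrix must carry both group labels")
    p_cut = p_threshold / m.n_peaks if bonferroni else p_threshold
    rows = []
    for j, mz in enumerate(m.reference_mzs):
        a = m.areas[is_resp, j]
        b = m.areas[is_prog, j]
        t, p = welch_t_test(a, b, pooled=pooled)
        auc, direction = roc_auc(m.areas[is_resp | is_prog, j],
                                 labels[is_resp | is_prog])
        rows.append(
            {
                "reference_mz": float(mz),
                "mean_response": a.mean(),
                "sd_response": a.std(ddof=1),
                "mean_progression": b.mean(),
                "sd_progression": b.std(ddof=1),
                "t_statistic": t,
                "p_value": p,
                "auc": auc,
                "direction": direction,
                "selected": bool(p < p_cut and auc >= auc_threshold),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("p_value", kind="mergesort")
        .reset_index(drop=True)
    )


class DifferentialPeakScreen(BaseEstimator):
    """Sklearn-style transformer wrapping the differential screen.

    ``fit(X, y)`` expects a samples-by-peaks array and labels in
    {"response", "progression"}; ``transform(X)`` keeps the selected columns.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Full screening table sorted by ascending p-value.
    selected_idx_ : ndarray of int
        Column indices (into X) of the selected peaks, ascending.
    selected_mzs_ : ndarray of float
        Reference m/z of the selected peaks (column index when no
        ``feature_mzs`` are given).
    """

    def __init__(
        self,
        p_threshold: float = 1e-4,
        auc_threshold: float = 0.75,
        bonferroni: bool = False,
        pooled: bool = False,
    ):
        self.p_threshold = p_threshold
        self.auc_threshold = auc_threshold
        self.bonferroni = bonferroni
        self.pooled = pooled

    def fit(self, X, y, feature_mzs=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        mzs = (
            np.asarray(feature_mzs, dtype=float)
            if feature_mzs is not None
            else np.arange(X.shape[1], dtype=float)
        )
        m = PeakMatrix(
            [f"S{i}" for i in range(X.shape[0])], list(y), np.sort(mzs),
            X[:, np.argsort(mzs)],
        )
        self.results_ = screen_differential_peaks(
            m, self.p_threshold, self.auc_threshold, self.bonferroni, self.pooled
        )
        sel = self.results_.loc[self.results_["selected"], "reference_mz"].to_numpy()
        order = np.argsort(mzs)
        self.selected_mzs_ = np.sort(sel)
        self.selected_idx_ = np.sort(
            order[np.searchsorted(np.sort(mzs), self.selected_mzs_)]
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        return np.asarray(X, dtype=float)[:, self.selected_idx_]
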
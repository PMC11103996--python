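"""Blinded validation of a trained model and contingency-table statistics."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierModel, knn_predict
from .spectra import PeakMatrix

__all__ = [
    "ConfusionMatrix",
    "blind_classify",
    "confusion_metrics",
    "contingency_test",
    "round1",
]


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (the convention behind
    printed rates such as 91.4%)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts (true group x predicted label) with rates in %."""

    counts: pd.DataFrame
    overall_accuracy: float
    per_group_correct_rate: dict[str, float]

    def summary(self) -> str:
        lines = [self.counts.to_string(), ""]
        for g, r in self.per_group_correct_rate.items():
            lines.append(f"{g}: {round1(r):.1f}% correct")
        lines.append(f"overall accuracy: {round1(self.overall_accuracy):.1f}%")
        return "\n".join(lines)


def blind_classify(
    model: ClassifierModel,
    validation: PeakMatrix,
    alignment_tolerance: float = 0.002,
) -> np.ndarray:
    """Classify every validation sample without reading its group labels.

    Each of the model's selected peaks is matched to the nearest validation
    reference peak within ``alignment_tolerance`` (relative m/z); an
    unmatched peak is an error.
    """
    cols = []
    for mz in model.selected_mzs:
        j = int(np.argmin(np.abs(validation.reference_mzs - mz)))
        if abs(validation.reference_mzs[j] - mz) > alignment_tolerance * mz:
            raise ValueError(
                f"model peak m/z {mz:.2f} has no match in the validation frame"
            )
        cols.append(j)
    if validation.n_samples == 0:
        return np.array([], dtype=object)
    return np.asarray(knn_predict(model, validation.areas[:, cols]), dtype=object)


def confusion_metrics(true_labels, predicted_labels) -> ConfusionMatrix:
    """Confusion counts, overall accuracy and per-true-group correct rates."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    if len(t) == 0:
        raise ValueError("need at least one sample")
    groups = sorted(set(t) | set(p))
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for ti, pi in zip(t, p):
        counts.loc[ti, pi] += 1
    correct = int(np.sum(t == p))
    per_group = {
        g: 100.0 * float(np.mean(p[t == g] == g)) for g in groups if (t == g).any()
    }
    return ConfusionMatrix(
        counts=counts.rename_axis(index="true", columns="predicted"),
        overall_accuracy=100.0 * correct / len(t),
        per_group_correct_rate=per_group,
    )


def contingency_test(table) -> tuple[float, float, str]:
    """Pearson chi-square (no continuity correction) or Fisher's exact test.

    Pearson is used when every expected count is >= 5, otherwise Fisher's
    exact (statistic = odds ratio).  Returns (statistic, p, method).
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValueError("need a 2x2 table of non-negative integer counts")
    if tab.sum() <= 0:
        raise ValueError("empty table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero-margin table")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if np.all(expected >= 5):
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return float(chi2), float(p), "pearson-chi2"
    odds, p = stats.fisher_exact(tab.astype(int))
    return float(odds), float(p), "fisher-exact"
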
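"""Classifier evaluation against reference labels.

Per-class precision, recall and F-measure from confusion counts, macro and
count-weighted averages, the Hubert-Arabie Adjusted Rand Index, a
one-vs-rest ARI per class, and the two method-agreement summaries used to
compare abundance estimates: Pearson correlation and Bland-Altman bias with
95% limits of agreement. Rounding to the 2-decimal presentation convention
happens only in the report layer (:func:`round_half_up`,
:func:`class_metrics_table`), never inside the computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), the tabular convention."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_counts(
    pred_labels: np.ndarray, true_labels: np.ndarray, class_name: str
) -> tuple[int, int, int]:
    """(TP, predicted_n, true_n) for one class.

    TP counts cells carrying the class in both label vectors; predicted_n
    and true_n are the marginal totals.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise DataError(
            f"label vectors differ in length ({pred.size} vs {true.size})"
        )
    is_pred = pred == class_name
    is_true = true == class_name
    return int((is_pred & is_true).sum()), int(is_pred.sum()), int(is_true.sum())


def precision_recall_f(tp: int, pred_n: int, true_n: int) -> tuple[float, float, float]:
    """Precision TP/pred_n, recall TP/true_n, F = 2PR/(P+R).

    Empty marginals follow the 0/0 := 0 convention, so a class never
    predicted and never present scores (0, 0, 0) rather than erroring.
    """
    if pred_n < 0 or true_n < 0:
        raise ParameterError("counts must be nonnegative")
    if tp < 0 or tp > pred_n or tp > true_n:
        raise ParameterError(
            f"TP={tp} exceeds a marginal (pred_n={pred_n}, true_n={true_n})"
        )
    precision = tp / pred_n if pred_n else 0.0
    recall = tp / true_n if true_n else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def macro_average_f(per_class_f) -> float:
    """Unweighted arithmetic mean of per-class F values."""
    arr = np.asarray(list(per_class_f), dtype=float)
    if arr.size == 0:
        raise ParameterError("macro average of an empty vector is undefined")
    if np.any((arr < 0) | (arr > 1)):
        raise ParameterError("F values must lie in [0, 1]")
    return float(arr.mean())


def weighted_average_f(per_class_f, true_ns) -> float:
    """F averaged with true-count weights: sum(n_c * f_c) / sum(n_c).

    Distinct from the macro average; large classes dominate it.
    """
    f = np.asarray(list(per_class_f), dtype=float)
    n = np.asarray(list(true_ns), dtype=float)
    if f.shape != n.shape or f.size == 0:
        raise ParameterError("need matching nonempty f and count vectors")
    if n.sum() <= 0:
        raise ParameterError("total true count must be positive")
    return float(np.dot(f, n) / n.sum())


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie ARI from the contingency table.

    ARI = (sum_ij C(n_ij,2) - E) / (max_index - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max_index = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    Equals 1 iff the partitions coincide up to relabelling; 0 in
    expectation under independent random partitions with fixed marginals.
    When both partitions are single clusters the index is defined as 1
    (identical trivial partitions).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise DataError("label vectors differ in length")
    n = a.size
    if n < 2:
        raise DataError("ARI needs at least two items")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    sum_comb = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.asarray([float(n)]))[0]
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both sides trivial (all-singletons or one cluster)
        return 1.0 if sum_comb == expected else 0.0
    return float((sum_comb - expected) / (max_index - expected))


def one_vs_rest_ari(
    pred_labels, true_labels, class_name: str
) -> tuple[float, bool]:
    """ARI between the {class, rest} indicator partitions.

    Returns ``(ari, degenerate)``; degenerate is True when the class is
    absent from both vectors, in which case the index is undefined and 0.0
    is returned as a placeholder.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise DataError("label vectors differ in length")
    ind_pred = (pred == class_name).astype(int)
    ind_true = (true == class_name).astype(int)
    if ind_pred.sum() == 0 and ind_true.sum() == 0:
        return 0.0, True
    return adjusted_rand_index(ind_pred, ind_true), False


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    means: np.ndarray


def bland_altman(x, y) -> BlandAltman:
    """Agreement of two measurement methods on paired values.

    bias = mean(x - y); limits of agreement = bias +/- 1.96 * sd(x - y)
    with the sample (n-1) standard deviation. The per-point differences
    and means are returned for plotting difference-vs-mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired vectors differ in length")
    if x.size < 2:
        raise ParameterError("Bland-Altman needs at least two pairs")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        differences=diff,
        means=(x + y) / 2.0,
    )


def pearson_agreement(x, y) -> tuple[float, float, float]:
    """Sample Pearson r, r^2 and the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired vectors differ in length")
    if x.size < 3:
        raise ParameterError("correlation needs at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def class_metrics_table(
    pred_labels,
    true_labels,
    classes: list[str] | None = None,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Benchmark table: one row per class plus macro/weighted summary rows.

    Columns mirror the usual benchmarking layout: Counts (reference),
    Cluster cell counts (predicted), True positive, Precision, Recall,
    F-measure, ARI (one-vs-rest). ``decimals=None`` disables presentation
    rounding.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if classes is None:
        classes = sorted({str(c) for c in np.unique(true)})
    rows = []
    fs, true_ns = [], []
    for cls in classes:
        tp, pred_n, true_n = confusion_counts(pred, true, cls)
        precision, recall, f = precision_recall_f(tp, pred_n, true_n)
        ari, _ = one_vs_rest_ari(pred, true, cls)
        fs.append(f)
        true_ns.append(true_n)
        rows.append(
            {
                "class": cls,
                "counts": true_n,
                "cluster_cell_counts": pred_n,
                "true_positive": tp,
                "precision": precision,
                "recall": recall,
                "f_measure": f,
                "ari": ari,
            }
        )
    macro_f = macro_average_f(fs)
    weighted_f = weighted_average_f(fs, true_ns) if sum(true_ns) else 0.0
    overall_ari = adjusted_rand_index(pred, true)
    summary = {
        "class": "__macro__",
        "counts": int(sum(true_ns)),
        "cluster_cell_counts": int((np.isin(pred, classes)).sum()),
        "true_positive": int(sum(r["true_positive"] for r in rows)),
        "precision": np.nan,
        "recall": np.nan,
        "f_measure": macro_f,
        "ari": overall_ari,
    }
    df = pd.DataFrame(rows + [summary])
    df.attrs["macro_f"] = macro_f
    df.attrs["weighted_f"] = weighted_f
    df.attrs["ari"] = overall_ari
    if decimals is not None:
        for col in ("precision", "recall", "f_measure", "ari"):
            df[col] = df[col].map(
                lambda v: round_half_up(v, decimals) if pd.notna(v) else v
            )
    return df
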
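"""Concordance evaluation of predicted vs reference CMS labels.

Accuracy is reported over jointly-confident samples (non-NA in both label
vectors).  Because CMS cohorts are class-imbalanced, the headline metric is
the normalized Matthews correlation coefficient nMCC = (MCC + 1) / 2, in
[0, 1]: per-class values use one-vs-rest binarization and the overall value
uses the Gorodkin multiclass MCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CMS_CLASSES, CmskitError, LabelVector

_TABLE_ORDER = list(CMS_CLASSES) + ["NA"]


def mcc_binary(tp: float, tn: float, fp: float, fn: float) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); a zero factor
    in the denominator yields MCC = 0 by convention.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise CmskitError("confusion counts must be nonnegative")
    if all(c == 0 for c in counts):
        raise CmskitError("confusion table is empty")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def nmcc(mcc: float) -> float:
    """Rescale an MCC from [-1, 1] to [0, 1] via (MCC + 1) / 2."""
    if not -1.0 - 1e-12 <= mcc <= 1.0 + 1e-12:
        raise CmskitError(f"MCC out of range [-1, 1]: {mcc}")
    return (min(max(mcc, -1.0), 1.0) + 1.0) / 2.0


def mcc_multiclass(table: np.ndarray) -> float:
    """Gorodkin generalized MCC from a K x K confusion table
    (rows = predicted, columns = reference).

    MCC = (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with c = trace, s = total, p_k = predicted totals, t_k = true totals; a
    degenerate denominator yields 0.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise CmskitError("confusion table must be square")
    if np.any(t < 0):
        raise CmskitError("confusion counts must be nonnegative")
    s = t.sum()
    if s == 0:
        raise CmskitError("confusion table is empty")
    c = np.trace(t)
    p = t.sum(axis=1)  # predicted-class totals
    q = t.sum(axis=0)  # true-class totals
    num = c * s - p @ q
    d1 = s * s - p @ p
    d2 = s * s - q @ q
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(num / math.sqrt(d1 * d2))


@dataclass
class ConcordanceResult:
    """Cross-tabulation and metrics for predicted vs reference labels.

    ``table`` is 5x5 (CMS1..CMS4, NA), predicted rows x reference columns.
    ``accuracy_confident`` and the nMCC values are computed only over samples
    labeled non-NA by both vectors; they are NaN when that subset is empty.
    """

    table: pd.DataFrame
    accuracy_confident: float
    nmcc_overall: float
    nmcc_per_class: dict[str, float]
    nmcc_per_class_mean: float
    n_jointly_confident: int
    accuracy_all: float

    def to_dict(self) -> dict:
        return {
            "table": {r: self.table.loc[r].to_dict() for r in self.table.index},
            "accuracy_confident": self.accuracy_confident,
            "nmcc_overall": self.nmcc_overall,
            "nmcc_per_class": self.nmcc_per_class,
            "nmcc_per_class_mean": self.nmcc_per_class_mean,
            "n_jointly_confident": self.n_jointly_confident,
            "accuracy_all": self.accuracy_all,
        }


def concordance(pred: LabelVector, ref: LabelVector) -> ConcordanceResult:
    """Compare predicted against reference labels on the same samples.

    ``accuracy_all`` additionally treats any NA mismatch as an error, for the
    all-sample view; the headline numbers follow the jointly-confident
    convention.
    """
    if set(pred.sample_ids) != set(ref.sample_ids):
        only_p = sorted(set(pred.sample_ids) - set(ref.sample_ids))
        only_r = sorted(set(ref.sample_ids) - set(pred.sample_ids))
        raise CmskitError(
            "sample ids differ between prediction and reference; "
            f"prediction-only: {only_p[:5]}, reference-only: {only_r[:5]}"
        )
    ps = pred.as_series()
    rs = ref.as_series().reindex(ps.index)

    table = pd.DataFrame(0, index=_TABLE_ORDER, columns=_TABLE_ORDER, dtype=int)
    for p, r in zip(ps, rs):
        table.loc[p, r] += 1

    conf = (ps != "NA") & (rs != "NA")
    n_conf = int(conf.sum())
    if n_conf == 0:
        acc = float("nan")
        overall = float("nan")
        per_class = {c: float("nan") for c in CMS_CLASSES}
        per_mean = float("nan")
    else:
        sub = table.loc[list(CMS_CLASSES), list(CMS_CLASSES)].to_numpy()
        acc = float(np.trace(sub) / n_conf)
        overall = nmcc(mcc_multiclass(sub))
        per_class = {}
        for k, c in enumerate(CMS_CLASSES):
            tp = sub[k, k]
            fp = sub[k, :].sum() - tp
            fn = sub[:, k].sum() - tp
            tn = n_conf - tp - fp - fn
            per_class[c] = nmcc(mcc_binary(tp, tn, fp, fn))
        per_mean = float(np.mean(list(per_class.values())))
    acc_all = float((ps == rs).sum() / len(ps)) if len(ps) else float("nan")
    return ConcordanceResult(
        table=table,
        accuracy_confident=acc,
        nmcc_overall=overall,
        nmcc_per_class=per_class,
        nmcc_per_class_mean=per_mean,
        n_jointly_confident=n_conf,
        accuracy_all=acc_all,
    )
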
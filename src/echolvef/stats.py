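"""Evaluation statistics for predicted-versus-reference LVEF.

Pearson correlation with its exact t-based p-value, the paired Student
t-test between two EF estimation strategies, ROC/AUC (Mann-Whitney tie
handling) for HFrEF discrimination, the confusion matrix of HFrEF
flags, and percentile bootstrap confidence intervals (resampling
subjects, 100 resamples, 95% range by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance sample")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float]:
    """Paired Student t-test on d = x - y; two-sided p with n-1 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of at least 2 values")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("paired t-test degenerate: zero-variance differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    ci: tuple[float, float] | None = None


def roc_auc(scores, labels, ci_seed: int | None = None, n_boot: int = 100) -> ROCResult:
    """ROC curve and AUC; ties count one half (Mann-Whitney convention).

    With ``ci_seed`` given, a percentile bootstrap CI over subjects is
    attached.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    ci = None
    if ci_seed is not None:
        def _stat(idx):
            lab = labels[idx]
            if lab.min() == lab.max():
                raise ValueError("single-class resample")
            return roc_auc_score(lab, scores[idx])

        ci = bootstrap_ci(_stat, np.arange(labels.size), n_boot=n_boot, seed=ci_seed,
                          index_mode=True)
    return ROCResult(auc=auc, thresholds=thresholds, tpr=tpr, fpr=fpr, ci=ci)


def bootstrap_ci(
    stat,
    data,
    n_boot: int = 100,
    level: float = 95.0,
    seed: int = 0,
    index_mode: bool = False,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``stat`` over subject resamples.

    ``stat`` receives a resampled copy of ``data`` (or, with
    ``index_mode``, an index array to apply to parallel arrays).  A
    resample on which the statistic fails is redrawn, at most 10 times.
    """
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, data.shape[0], size=data.shape[0])
            try:
                values.append(float(stat(idx if index_mode else data[idx])))
                break
            except Exception:
                if attempt == 10:
                    raise
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred, ref) -> ConfusionMatrix:
    """Confusion counts between predicted and reference HFrEF flags."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )
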
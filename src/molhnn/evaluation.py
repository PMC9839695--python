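"""Classifier evaluation and the unsupervised cluster-agreement test.

ROC/AUC makes the reported performance independent of the decision
threshold; precision/recall are reported per class at chosen
thresholds.  The cluster-agreement test asks whether the predicted
probability distributions of structurally related conformation
clusters are statistically indistinguishable: for every cluster pair a
Wilcoxon signed-rank test (pairing by sample index) is run, and the
outcome is compared with the expectation that same-family clusters are
similar (p >= alpha) and cross-family clusters differ (p < alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult", "AgreementMatrix", "roc_auc", "precision_recall",
    "cluster_agreement", "wilcoxon_pvalue",
]


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> RocResult:
    """ROC points and trapezoidal AUC (equals the Mann-Whitney statistic).

    ``labels``: 1 for the positive (low free-energy) class.  Requires
    both classes to be present.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def precision_recall(labels: Sequence[int], probabilities: Sequence[float],
                     t: float = 0.5) -> pd.DataFrame:
    """Per-class precision (tp/(tp+fp)) and recall (tp/(tp+fn)) at t.

    The decision rule is p >= t -> low class (labels: 1 = low, 0 =
    high).  A class never predicted has undefined precision, reported
    as NaN with a warning.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    y = np.asarray(labels, dtype=int)
    pred = (np.asarray(probabilities, dtype=float) >= t).astype(int)
    rows = []
    for cls, name in ((1, "low"), (0, "high")):
        tp = int(np.sum((pred == cls) & (y == cls)))
        fp = int(np.sum((pred == cls) & (y != cls)))
        fn = int(np.sum((pred != cls) & (y == cls)))
        if tp + fp == 0:
            import warnings
            warnings.warn(f"no conformation predicted as {name!r} at t={t}; "
                          "precision undefined", stacklevel=2)
            precision = np.nan
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn > 0 else np.nan
        rows.append({"class": name, "threshold": t,
                     "precision": precision, "recall": recall})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# cluster agreement

def wilcoxon_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value, paired by sample index.

    Zero differences are dropped (standard convention); if every
    difference is zero the distributions are identical by construction
    and p = 1.0 is returned.  The exact null is used for n <= 25,
    otherwise the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            "paired test needs equal cluster sizes; truncate both clusters "
            "to the common size first"
        )
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class AgreementMatrix:
    """Pairwise p-values plus the expectation-coded outcome matrix.

    Outcome codes follow the expectation that same-family clusters have
    similar prediction distributions: ``expected-different`` (p < alpha,
    different family), ``expected-similar`` (p >= alpha, same family),
    and the two ``unexpected-*`` codes otherwise.
    """

    clusters: list
    p_values: np.ndarray          # symmetric, NaN diagonal
    same_family: np.ndarray       # boolean expectation matrix
    outcome: np.ndarray           # object array of codes, "" diagonal
    alpha: float

    def fraction_expected(self) -> float:
        """Fraction of off-diagonal pairs whose outcome matches expectation."""
        iu = np.triu_indices(len(self.clusters), k=1)
        codes = self.outcome[iu]
        return float(np.mean([c.startswith("expected") for c in codes]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.clusters,
                            columns=self.clusters)


def cluster_agreement(predictions: Mapping, family_map: Mapping,
                      alpha: float = 0.01,
                      use_rank_sum: bool = False,
                      bonferroni: bool = False) -> AgreementMatrix:
    """Pairwise distribution tests over prediction clusters.

    ``predictions`` maps cluster id -> array of predicted probabilities
    (equal sizes required, pairing by index); ``family_map`` maps
    cluster id -> family name.  ``use_rank_sum`` switches to the
    unpaired Mann-Whitney test; ``bonferroni`` multiplies p-values by
    the number of pairs before thresholding.
    """
    clusters = sorted(predictions)
    sizes = {len(np.asarray(predictions[c])) for c in clusters}
    if not use_rank_sum and len(sizes) > 1:
        raise ValueError(
            f"clusters have unequal sizes {sorted(sizes)}; the signed-rank "
            "test pairs by index — truncate all clusters to the common size"
        )
    k = len(clusters)
    n_pairs = k * (k - 1) // 2
    P = np.full((k, k), np.nan)
    same = np.zeros((k, k), dtype=bool)
    outcome = np.full((k, k), "", dtype=object)
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(predictions[clusters[i]], dtype=float)
            b = np.asarray(predictions[clusters[j]], dtype=float)
            if use_rank_sum:
                p = float(stats.mannwhitneyu(a, b,
                                             alternative="two-sided").pvalue)
            else:
                p = wilcoxon_pvalue(a, b)
            if bonferroni:
                p = min(1.0, p * n_pairs)
            P[i, j] = P[j, i] = p
            fam_same = family_map[clusters[i]] == family_map[clusters[j]]
            same[i, j] = same[j, i] = fam_same
            if p < alpha:
                code = "unexpected-different" if fam_same else "expected-different"
            else:
                code = "expected-similar" if fam_same else "unexpected-similar"
            outcome[i, j] = outcome[j, i] = code
    return AgreementMatrix(clusters=clusters, p_values=P, same_family=same,
                           outcome=outcome, alpha=alpha)
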
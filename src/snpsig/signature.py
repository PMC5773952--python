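"""Minimal-signature search by prefix scan over the ranked SNP list.

Given SNPs ranked by discriminatory power, the search evaluates the
leave-one-out cross-validated (LOOCV) accuracy of every rank prefix
{top-1, top-2, ..., top-k_max}. Scanning prefixes upward is equivalent to
recursively eliminating the lowest-ranked SNP starting from the top-k_max set;
the returned signature is the *smallest* prefix attaining the maximum observed
accuracy, i.e. the minimum amount of high-discrimination detail needed to
classify optimally under LOOCV.

The nearest-centroid LOOCV has a closed-form fast path: leaving sample i out
only shifts its own class's centroid, so the held-out distances can be
computed for all samples at once from the class sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifierSpec
from .containers import CASE, CONTROL, GenotypeMatrix

__all__ = [
    "AccuracyReport",
    "Signature",
    "predict",
    "loocv_accuracy",
    "find_minimal_signature",
]


@dataclass(frozen=True)
class AccuracyReport:
    """Classification rates over a set of evaluated samples."""

    accuracy: float
    tpr: float  # proportion of case samples predicted case
    tnr: float  # proportion of control samples predicted control
    n_evaluated: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "n_evaluated": self.n_evaluated,
        }


@dataclass(frozen=True)
class Signature:
    """An ordered SNP subset with its LOOCV performance."""

    snp_ids: tuple
    loocv: AccuracyReport

    @property
    def size(self) -> int:
        return len(self.snp_ids)

    def as_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "size": self.size,
            "loocv": self.loocv.as_dict(),
        }


def _to_xy(m, y, subset=None):
    if isinstance(m, GenotypeMatrix):
        if m.has_missing:
            raise ValueError("genotype matrix contains missing entries; impute first")
        y = y.aligned_to(m)
        X = np.asarray(m.codes, dtype=float)
        labels = y.labels
        if subset is not None:
            X = X[:, m.snp_index(subset)]
        return X, labels
    X = np.asarray(m, dtype=float)
    labels = np.asarray(y)
    if subset is not None:
        idx = []
        for s in subset:
            if isinstance(s, (int, np.integer)):
                idx.append(int(s))
            else:
                # default feature names "x<j>" assigned by snp_statistics
                name = str(s)
                if name.startswith("x") and name[1:].isdigit():
                    idx.append(int(name[1:]))
                else:
                    raise KeyError(f"unknown feature id {s!r} for a plain array")
        X = X[:, np.asarray(idx, dtype=np.intp)]
    return X, labels


def _rates(y_true, y_pred) -> AccuracyReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    case = y_true == CASE
    ctrl = y_true == CONTROL
    correct = y_true == y_pred
    return AccuracyReport(
        accuracy=float(correct.mean()),
        tpr=float(correct[case].mean()) if case.any() else float("nan"),
        tnr=float(correct[ctrl].mean()) if ctrl.any() else float("nan"),
        n_evaluated=len(y_true),
    )


def predict(train_m, train_y, test_rows, subset, spec: ClassifierSpec | None = None):
    """Train on ``train_m`` restricted to ``subset`` SNPs, predict ``test_rows``.

    ``test_rows`` is a GenotypeMatrix (or plain array) of samples to label.
    """
    spec = spec or ClassifierSpec()
    X, labels = _to_xy(train_m, train_y, subset)
    if isinstance(test_rows, GenotypeMatrix):
        Xt = np.asarray(test_rows.codes, dtype=float)[:, test_rows.snp_index(subset)]
    else:
        Xt = np.asarray(test_rows, dtype=float)
    clf = spec.make().fit(X, labels)
    return clf.predict(Xt)


def _loocv_centroid_predictions(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized nearest-centroid LOOCV with the fixed tie rules."""
    case = labels == CASE
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("LOOCV needs >= 2 samples per class")
    S1 = X[case].sum(axis=0)
    S2 = X[~case].sum(axis=0)
    cen1_full = S1 / n1
    cen2_full = S2 / n2

    d1 = np.empty(len(X))
    d2 = np.empty(len(X))
    # held-out case rows: own centroid recomputed without the row
    Xc = X[case]
    C1 = (S1[None, :] - Xc) / (n1 - 1)
    d1[case] = ((Xc - C1) ** 2).sum(axis=1)
    d2[case] = ((Xc - cen2_full[None, :]) ** 2).sum(axis=1)
    # held-out control rows
    Xk = X[~case]
    C2 = (S2[None, :] - Xk) / (n2 - 1)
    d2[~case] = ((Xk - C2) ** 2).sum(axis=1)
    d1[~case] = ((Xk - cen1_full[None, :]) ** 2).sum(axis=1)

    pred = np.where(d1 < d2, CASE, CONTROL).astype(np.int8)
    tie = d1 == d2
    if tie.any():
        # majority of the N-1 training samples; count tie -> case class
        maj_for_case = CASE if (n1 - 1) >= n2 else CONTROL
        maj_for_ctrl = CASE if n1 >= (n2 - 1) else CONTROL
        pred[tie & case] = maj_for_case
        pred[tie & ~case] = maj_for_ctrl
    return pred


def loocv_accuracy(m, y, subset=None, spec: ClassifierSpec | None = None) -> AccuracyReport:
    """Leave-one-out cross-validated accuracy/tpr/tnr on a SNP subset.

    Each sample is predicted by a classifier trained on the other N-1;
    the procedure is deterministic.
    """
    spec = spec or ClassifierSpec()
    X, labels = _to_xy(m, y, subset)
    if X.shape[1] == 0:
        raise ValueError("SNP subset is empty")
    if len(X) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if spec.method == "nearest_centroid":
        pred = _loocv_centroid_predictions(X, labels)
    else:
        pred = np.empty(len(X), dtype=labels.dtype)
        idx = np.arange(len(X))
        for i in idx:
            rest = idx != i
            clf = spec.make().fit(X[rest], labels[rest])
            pred[i] = clf.predict(X[i : i + 1])[0]
    return _rates(labels, pred)


def find_minimal_signature(
    m,
    y,
    ranked,
    k_max: int | None = None,
    spec: ClassifierSpec | None = None,
) -> tuple[Signature, pd.DataFrame]:
    """Smallest rank-prefix with maximal LOOCV accuracy, plus the full curve.

    ``ranked`` is the ranked statistics table from
    :func:`snpsig.stats.select_discriminatory` (or any ordered sequence of SNP
    ids / column indices, most discriminatory first). ``k_max`` caps the
    scanned prefix length and defaults to ``min(len(ranked), 400)``.

    Returns ``(signature, curve)`` where ``curve`` has one row per prefix size
    with its accuracy, tpr and tnr. When several prefixes tie at the maximum
    accuracy the smallest is returned.
    """
    spec = spec or ClassifierSpec()
    if isinstance(ranked, pd.DataFrame):
        ranked_ids = list(ranked["snp_id"])
    else:
        ranked_ids = list(ranked)
    if not ranked_ids:
        raise ValueError("ranked SNP list is empty")
    k_max = min(len(ranked_ids), 400) if k_max is None else k_max
    if not (1 <= k_max <= len(ranked_ids)):
        raise ValueError(f"k_max must lie in [1, {len(ranked_ids)}]")

    X, labels = _to_xy(m, y, ranked_ids[:k_max])
    rows = []
    best: AccuracyReport | None = None
    best_k = 0
    for k in range(1, k_max + 1):
        rep = loocv_accuracy(X[:, :k], labels, spec=spec)
        rows.append(
            {"size": k, "accuracy": rep.accuracy, "tpr": rep.tpr, "tnr": rep.tnr}
        )
        if best is None or rep.accuracy > best.accuracy:
            best, best_k = rep, k
    curve = pd.DataFrame(rows)
    signature = Signature(snp_ids=tuple(ranked_ids[:best_k]), loocv=best)
    return signature, curve
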
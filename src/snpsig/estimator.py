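"""End-to-end signature discovery as a scikit-learn estimator.

``SnpSignatureClassifier.fit(X, y)`` runs the whole discovery chain on an
``(n_samples, n_snps)`` array of genotype codes: per-SNP statistics, the
fold-change-tail + Fisher's-ratio filter with FR ranking, and the minimal
LOOCV rank-prefix search; the final classifier is then refit on the selected
signature columns so ``predict`` labels new samples. The class composes with
sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classify import ClassifierSpec
from .signature import find_minimal_signature
from .stats import DiscriminatorySnpSelector

__all__ = ["SnpSignatureClassifier"]


class SnpSignatureClassifier(ClassifierMixin, BaseEstimator):
    """Filter SNPs, find the minimal LOOCV signature, and classify with it.

    Parameters
    ----------
    tail_fraction, fr_min :
        Filter settings (see :class:`snpsig.stats.DiscriminatorySnpSelector`).
    k_max :
        Longest rank prefix scanned; ``None`` means ``min(n_survivors, 400)``.
    method, k :
        Final classifier (nearest_centroid by default, or odd-k knn).

    Attributes
    ----------
    selector_ : DiscriminatorySnpSelector
        Fitted filter with the full statistics table.
    signature_indices_ : ndarray
        Column indices of the discovered signature, in rank order.
    curve_ : DataFrame
        LOOCV accuracy against prefix size.
    loocv_ : AccuracyReport
        LOOCV performance of the signature.
    """

    def __init__(
        self,
        tail_fraction: float = 0.01,
        fr_min: float = 1.5,
        k_max: int | None = None,
        method: str = "nearest_centroid",
        k: int = 5,
    ):
        self.tail_fraction = tail_fraction
        self.fr_min = fr_min
        self.k_max = k_max
        self.method = method
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        spec = ClassifierSpec(self.method, self.k)
        selector = DiscriminatorySnpSelector(self.tail_fraction, self.fr_min).fit(X, y)
        if len(selector.ranking_) == 0:
            raise ValueError(
                "no SNP survives the discriminatory filter; "
                "relax tail_fraction/fr_min"
            )
        k_max = None if self.k_max is None else min(self.k_max, len(selector.ranking_))
        signature, curve = find_minimal_signature(
            X, y, list(selector.ranking_), k_max=k_max, spec=spec
        )
        self.selector_ = selector
        self.classes_ = selector.classes_
        self.n_features_in_ = X.shape[1]
        self.signature_indices_ = np.array([int(j) for j in signature.snp_ids], dtype=np.intp)
        self.signature_ = signature
        self.curve_ = curve
        self.loocv_ = signature.loocv
        self.classifier_ = spec.make().fit(X[:, self.signature_indices_], y)
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        X = np.asarray(X, dtype=float)
        return self.classifier_.predict(X[:, self.signature_indices_])
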
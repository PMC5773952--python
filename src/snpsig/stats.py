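"""Per-SNP discriminatory statistics and the two-stage filter.

For encoded genotype codes x in {1,2,3} and a two-class phenotype (class 1 =
cases, class 2 = controls) each SNP j gets:

* fold change  FC_j = log2(mu_j1 / mu_j2), the log ratio of class means of the
  codes. Because means lie in [1, 3], |FC_j| <= log2(3) ~= 1.585, the value
  attained by a perfect separator (all cases 3, all controls 1).
* Fisher's ratio  FR_j = (mu_j1 - mu_j2)^2 / (s2_j1 + s2_j2), the squared mean
  separation over the summed within-class variances (unbiased, n-1). Large FR
  marks SNPs that push the classes apart while staying homogeneous within each
  class. When both class variances vanish and the means differ, FR is reported
  as the infinite-separation sentinel ``inf`` and ranks above every finite
  value; when the means also agree FR is 0.

The filter keeps the extreme tails of the fold-change distribution (default
1% in total, split over both tails) and then requires FR above a threshold
(default 1.5); survivors are ranked by decreasing FR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import GenotypeMatrix, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = [
    "class_moments",
    "fold_change",
    "fisher_ratio",
    "snp_statistics",
    "select_discriminatory",
    "DiscriminatorySnpSelector",
]

STAT_COLUMNS = ["snp_id", "mu1", "mu2", "var1", "var2", "fold_change", "fisher_ratio"]


def _as_arrays(m, y):
    """Accept (GenotypeMatrix, PhenotypeLabels) or plain (X, case_mask)."""
    if isinstance(m, GenotypeMatrix):
        if m.has_missing:
            raise ValueError("genotype matrix contains missing entries; impute first")
        y = y.aligned_to(m)
        return np.asarray(m.codes, dtype=float), y.case_mask, m.snp_ids
    X = np.asarray(m, dtype=float)
    mask = np.asarray(y, dtype=bool)
    return X, mask, np.array([f"x{j}" for j in range(X.shape[1])], dtype=object)


def class_moments(X: np.ndarray, case_mask: np.ndarray):
    """Per-column class means and unbiased (n-1) variances: (mu1, mu2, v1, v2)."""
    X1, X2 = X[case_mask], X[~case_mask]
    if len(X1) == 0 or len(X2) == 0:
        raise ValueError("both classes must be non-empty")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    v1 = X1.var(axis=0, ddof=1) if len(X1) > 1 else np.full(X.shape[1], np.nan)
    v2 = X2.var(axis=0, ddof=1) if len(X2) > 1 else np.full(X.shape[1], np.nan)
    return mu1, mu2, v1, v2


def fold_change(m, y) -> np.ndarray:
    """Per-SNP log2 ratio of case-class to control-class mean code.

    Positive values mark codes elevated in cases.
    """
    X, case_mask, _ = _as_arrays(m, y)
    mu1, mu2, _, _ = class_moments(X, case_mask)
    return np.log2(mu1 / mu2)


def fisher_ratio(m, y) -> np.ndarray:
    """Per-SNP Fisher's ratio (mu1 - mu2)^2 / (var1 + var2).

    Requires at least two samples per class (n-1 variances). Columns with zero
    pooled variance yield ``inf`` when the means differ, 0 otherwise.
    """
    X, case_mask, _ = _as_arrays(m, y)
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each class needs >= 2 samples for class variances (got {n1}, {n2})"
        )
    mu1, mu2, v1, v2 = class_moments(X, case_mask)
    num = (mu1 - mu2) ** 2
    denom = v1 + v2
    fr = np.empty_like(num)
    zero = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fr[~zero] = num[~zero] / denom[~zero]
    fr[zero] = np.where(num[zero] > 0, np.inf, 0.0)
    return fr


def snp_statistics(m, y) -> pd.DataFrame:
    """Full per-SNP statistics table (one row per SNP, unranked)."""
    X, case_mask, snp_ids = _as_arrays(m, y)
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each class needs >= 2 samples for class variances (got {n1}, {n2})"
        )
    mu1, mu2, v1, v2 = class_moments(X, case_mask)
    num = (mu1 - mu2) ** 2
    denom = v1 + v2
    zero = denom == 0
    fr = np.empty_like(num)
    with np.errstate(divide="ignore", invalid="ignore"):
        fr[~zero] = num[~zero] / denom[~zero]
    fr[zero] = np.where(num[zero] > 0, np.inf, 0.0)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "mu1": mu1,
            "mu2": mu2,
            "var1": v1,
            "var2": v2,
            "fold_change": np.log2(mu1 / mu2),
            "fisher_ratio": fr,
        }
    )


def select_discriminatory(
    stats: pd.DataFrame,
    tail_fraction: float = 0.01,
    fr_min: float = 1.5,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Apply the fold-change tail filter then the Fisher's-ratio threshold.

    A SNP survives the first stage when its fold change lies at or below the
    ``tail_fraction/2`` empirical quantile of the panel's fold-change
    distribution, or at or above the ``1 - tail_fraction/2`` quantile; it then
    must have Fisher's ratio strictly greater than ``fr_min``. Survivors are
    ranked (column ``rank``, 1 = most discriminatory) by decreasing FR with the
    infinite-separation sentinel first, ties broken by decreasing |fold
    change| and then lexicographic SNP id. ``top_k`` optionally truncates the
    ranked list. An empty result is returned (with a logged warning) when no
    SNP survives.
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must lie in (0, 1]")
    fc = stats["fold_change"].to_numpy()
    if tail_fraction >= 1.0:
        in_tail = np.ones(len(fc), dtype=bool)
    else:
        lo = np.quantile(fc, tail_fraction / 2)
        hi = np.quantile(fc, 1 - tail_fraction / 2)
        in_tail = (fc <= lo) | (fc >= hi)
    survivors = stats.loc[in_tail & (stats["fisher_ratio"].to_numpy() > fr_min)].copy()
    if survivors.empty:
        logger.warning(
            "no SNP survives the filter (tail_fraction=%g, fr_min=%g)",
            tail_fraction,
            fr_min,
        )
        out = survivors
        out["rank"] = pd.Series(dtype=int)
        return out.reset_index(drop=True)
    order = sorted(
        range(len(survivors)),
        key=lambda i: (
            -survivors["fisher_ratio"].iat[i],
            -abs(survivors["fold_change"].iat[i]),
            str(survivors["snp_id"].iat[i]),
        ),
    )
    ranked = survivors.iloc[order].reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if top_k is not None:
        ranked = ranked.iloc[:top_k].copy()
    return ranked


def write_statistics_tsv(stats: pd.DataFrame, path) -> None:
    """Write a statistics table as TSV; the FR sentinel renders as ``inf``."""
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")


class DiscriminatorySnpSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector wrapping the two-stage SNP filter.

    Parameters
    ----------
    tail_fraction : float, default 0.01
        Total fold-change tail mass kept, split evenly over both tails.
    fr_min : float, default 1.5
        Strict lower bound on Fisher's ratio for survivors.
    top_k : int or None
        Optional truncation of the ranked list.

    Attributes
    ----------
    stats_ : DataFrame
        Per-feature statistics on the full panel.
    ranked_ : DataFrame
        Surviving features with their ranks.
    ranking_ : ndarray
        Column indices of survivors, most discriminatory first.
    """

    def __init__(self, tail_fraction: float = 0.01, fr_min: float = 1.5, top_k: int | None = None):
        self.tail_fraction = tail_fraction
        self.fr_min = fr_min
        self.top_k = top_k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        case_mask = y == classes[0]
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.stats_ = snp_statistics(X, case_mask)
        self.ranked_ = select_discriminatory(
            self.stats_, self.tail_fraction, self.fr_min, self.top_k
        )
        idx = {s: j for j, s in enumerate(self.stats_["snp_id"])}
        self.ranking_ = np.array(
            [idx[s] for s in self.ranked_["snp_id"]], dtype=np.intp
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask
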
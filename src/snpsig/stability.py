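"""Repeated stratified hold-out experiments for signature stability.

The discovered signature is held fixed while the classifier is retrained on
random 75/25 train/validation partitions; the spread of the validation
accuracies over many splits quantifies how stable the signature's predictive
accuracy is when the training set shrinks. Splits are stratified so that the
heavily unbalanced arm (controls) is represented in every partition.

``rederive=True`` switches to the nested variant in which the filter and the
prefix search are re-run inside each training partition, measuring the
stability of the whole discovery procedure rather than of one fixed signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierSpec
from .containers import CASE, CONTROL
from .signature import Signature, _rates, _to_xy, find_minimal_signature
from .stats import select_discriminatory, snp_statistics

__all__ = ["HoldoutSummary", "holdout_sampler", "accuracy_cdf", "stratified_split"]


@dataclass(frozen=True)
class HoldoutSummary:
    """Validation accuracies over repeated hold-out splits, with summaries.

    Quantiles use linear interpolation of the empirical distribution; the
    standard deviation is the n-1 sample estimate (0 when n_splits = 1).
    """

    accuracies: np.ndarray = field(repr=False)
    tprs: np.ndarray = field(repr=False)
    tnrs: np.ndarray = field(repr=False)
    n_splits: int
    train_fraction: float
    seed: int
    median: float
    q25: float
    q75: float
    iqr: float
    mean: float
    sd: float
    min: float
    max: float
    cdf: np.ndarray = field(repr=False)  # (accuracy, cumulative probability) pairs

    def as_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "iqr": self.iqr,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
        }


def accuracy_cdf(accuracies) -> np.ndarray:
    """Empirical CDF: at each distinct accuracy a, the fraction of values <= a.

    Returns an array of (value, cumulative probability) pairs, sorted by value
    and ending at probability 1.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("accuracy vector is empty")
    values, counts = np.unique(acc, return_counts=True)
    cum = np.cumsum(counts) / acc.size
    return np.column_stack([values, cum])


def stratified_split(labels: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Class-stratified random train/validation split (indices).

    Per class the training share is rounded to the nearest integer, then
    clamped so both partitions keep at least one sample of each class.
    """
    train_idx: list[np.ndarray] = []
    valid_idx: list[np.ndarray] = []
    for c in (CASE, CONTROL):
        idx = np.flatnonzero(labels == c)
        n_c = len(idx)
        if n_c < 2:
            raise ValueError(
                f"class {c} has {n_c} sample(s); cannot stratify a hold-out split"
            )
        n_train = int(round(train_fraction * n_c))
        n_train = min(max(n_train, 1), n_c - 1)
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        valid_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(valid_idx))


def holdout_sampler(
    m,
    y,
    signature: Signature | list,
    n_splits: int = 5000,
    train_fraction: float = 0.75,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    rederive: bool = False,
    tail_fraction: float = 0.01,
    fr_min: float = 1.5,
    k_max: int | None = None,
) -> HoldoutSummary:
    """Repeated stratified hold-out validation of a signature.

    For each of ``n_splits`` splits the classifier is trained on the training
    partition (default 75%) restricted to the signature SNPs and evaluated on
    the blind validation partition. The result is a pure function of ``seed``.

    With ``rederive=True`` the signature argument is ignored: the filter
    (``tail_fraction``, ``fr_min``) and the minimal-prefix search (``k_max``)
    are re-run inside every training partition.
    """
    spec = spec or ClassifierSpec()
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    snp_ids = list(signature.snp_ids) if isinstance(signature, Signature) else list(signature)
    if not snp_ids and not rederive:
        raise ValueError("signature is empty")

    if rederive:
        X, labels = _to_xy(m, y)
    else:
        X, labels = _to_xy(m, y, snp_ids)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_splits)
    tprs = np.empty(n_splits)
    tnrs = np.empty(n_splits)
    for s in range(n_splits):
        tr, va = stratified_split(labels, train_fraction, rng)
        if rederive:
            stats = snp_statistics(X[tr], labels[tr] == CASE)
            ranked = select_discriminatory(stats, tail_fraction, fr_min)
            if ranked.empty:
                cols = np.arange(X.shape[1])[:1]  # no survivors: fall back to one column
            else:
                sig, _ = find_minimal_signature(
                    X[tr], labels[tr], ranked, k_max=k_max, spec=spec
                )
                cols = np.array([int(str(sid)[1:]) for sid in sig.snp_ids])
            Xtr, Xva = X[tr][:, cols], X[va][:, cols]
        else:
            Xtr, Xva = X[tr], X[va]
        clf = spec.make().fit(Xtr, labels[tr])
        rep = _rates(labels[va], clf.predict(Xva))
        accs[s], tprs[s], tnrs[s] = rep.accuracy, rep.tpr, rep.tnr

    q25, med, q75 = np.quantile(accs, [0.25, 0.5, 0.75])
    return HoldoutSummary(
        accuracies=accs,
        tprs=tprs,
        tnrs=tnrs,
        n_splits=n_splits,
        train_fraction=train_fraction,
        seed=seed,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        iqr=float(q75 - q25),
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)) if n_splits > 1 else 0.0,
        min=float(accs.min()),
        max=float(accs.max()),
        cdf=accuracy_cdf(accs),
    )
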
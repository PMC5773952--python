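"""Core in-memory containers for case-control genotype analysis.

Genotypes of biallelic SNPs are encoded as small integers:

* ``1`` — homozygous reference,
* ``2`` — heterozygous,
* ``3`` — homozygous alternate.

This additive-style encoding bounds the per-SNP log2 fold change between the
case and control class means by ``±log2(3)``. Entries that were missing in the
source data carry the placeholder ``0`` until :func:`snpsig.io.impute_missing`
fills them; the ``missing_mask`` keeps track of which entries were originally
absent even after imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CASE",
    "CONTROL",
    "MISSING_CODE",
    "VALID_CODES",
    "GenotypeMatrix",
    "PhenotypeLabels",
]

#: Class label of case samples (toxicity-positive arm).
CASE: int = 1
#: Class label of control samples (toxicity-free arm).
CONTROL: int = 2

#: Placeholder stored in ``codes`` where the original call was missing.
MISSING_CODE: int = 0

VALID_CODES = frozenset({1, 2, 3})


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} id: {x!r}")
            seen.add(x)


@dataclass
class GenotypeMatrix:
    """An N-samples x M-SNPs matrix of encoded genotype codes.

    Parameters
    ----------
    sample_ids :
        Ordered, unique sample identifiers (length N).
    snp_ids :
        Ordered, unique SNP identifiers (length M), e.g. rsIDs.
    codes :
        ``(N, M)`` integer array with entries in {1, 2, 3}, or the missing
        placeholder ``0`` where ``missing_mask`` is true and the matrix has
        not yet been imputed.
    missing_mask :
        ``(N, M)`` boolean array; ``True`` marks entries that were missing in
        the source (and were, or still have to be, imputed).
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (samples x SNPs) array")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.codes.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.codes.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"codes has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if len(self.snp_ids) != m:
            raise ValueError(f"codes has {m} columns but {len(self.snp_ids)} SNP ids")
        if self.missing_mask.shape != self.codes.shape:
            raise ValueError("missing_mask shape differs from codes shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        observed = self.codes[~self.missing_mask]
        bad = (observed < 1) | (observed > 3)
        if bad.any():
            raise ValueError(
                f"non-missing genotype codes outside {{1,2,3}}: "
                f"{sorted(set(observed[bad].tolist()))}"
            )

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        """True if any entry still carries the missing placeholder."""
        return bool((self.codes == MISSING_CODE).any())

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids, in the order given."""
        lookup = {s: j for j, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown SNP id: {exc.args[0]!r}") from None

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.snp_index(snp_ids)
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            snp_ids=self.snp_ids[idx],
            codes=self.codes[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


@dataclass
class PhenotypeLabels:
    """Binary case/control assignment per sample.

    Labels are stored as integers: :data:`CASE` (1) for the case arm and
    :data:`CONTROL` (2) for the control arm.
    """

    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.sample_ids.shape != self.labels.shape:
            raise ValueError("sample_ids and labels must have equal length")
        _check_unique(self.sample_ids, "sample")
        bad = set(self.labels.tolist()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be {CASE} (case) or {CONTROL} (control), got {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError(
                "both classes must be non-empty "
                f"(cases={self.n_cases}, controls={self.n_controls})"
            )

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeLabels":
        """Reorder labels to match the sample order of ``genotypes``.

        Every genotype sample must be labelled exactly once.
        """
        lookup = {s: l for s, l in zip(self.sample_ids, self.labels)}
        missing = [s for s in genotypes.sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing[:5]}")
        labels = np.array([lookup[s] for s in genotypes.sample_ids], dtype=np.int8)
        return PhenotypeLabels(sample_ids=genotypes.sample_ids.copy(), labels=labels)
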
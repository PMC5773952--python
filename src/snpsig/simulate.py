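"""Synthetic case-control genotype cohorts with planted discriminatory SNPs.

The generator emulates the statistical structure of a small, unbalanced
pharmacogenomic case-control study: two phenotype arms, a large panel of null
SNPs whose genotypes follow Hardy-Weinberg proportions at a random minor-allele
frequency, and a small planted subset of causal SNPs whose alternate-allele
frequency is shifted upward in cases by ``effect_delta``. Genotype codes are
1/2/3 (hom-ref/het/hom-alt); allele counts are Binomial(2, p), which yields the
Hardy-Weinberg genotype proportions (1-p)^2, 2p(1-p), p^2.

Generation is a pure function of the seed: the same :class:`CohortSpec`
produces bit-identical cohorts on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CASE, CONTROL, MISSING_CODE, GenotypeMatrix, PhenotypeLabels

__all__ = ["CohortSpec", "CohortTruth", "generate_cohort", "extreme_separation_cohort"]

#: Causal-arm allele frequencies are capped here so planted columns stay
#: polymorphic (monomorphic separators are produced only by
#: :func:`extreme_separation_cohort`, where degeneracy is the point).
CASE_FREQ_CAP = 0.95


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case-control cohort.

    Defaults mirror a small unbalanced clinical cohort (roughly three cases
    per control) screened on a desk-scale SNP panel.
    """

    n_cases: int = 123
    n_controls: int = 39
    n_snps: int = 10_000
    n_causal: int = 70
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_delta: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValueError("n_causal must lie in [0, n_snps]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.effect_delta <= 0.5):
            raise ValueError("effect_delta must lie in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a generated cohort: which SNPs carry signal."""

    causal_snp_ids: frozenset
    control_freq: np.ndarray = field(repr=False)  # per-SNP generating frequency
    case_freq: np.ndarray = field(repr=False)


def _ids(prefix: str, n: int, width: int) -> np.ndarray:
    return np.array([f"{prefix}{i:0{width}d}" for i in range(n)], dtype=object)


def _labels(n_cases: int, n_controls: int) -> PhenotypeLabels:
    sample_ids = np.concatenate(
        [_ids("case", n_cases, 4), _ids("ctrl", n_controls, 4)]
    )
    labels = np.array([CASE] * n_cases + [CONTROL] * n_controls, dtype=np.int8)
    return PhenotypeLabels(sample_ids=sample_ids, labels=labels)


def generate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, PhenotypeLabels, CohortTruth]:
    """Draw a cohort under the spec's Hardy-Weinberg null plus planted signal.

    Null SNPs share one generating frequency across both arms; causal SNPs use
    ``p`` in controls and ``min(p + effect_delta, 0.95)`` in cases. Missing
    entries are introduced independently at ``missing_rate`` and left missing
    (the caller imputes), so the imputation path is exercised end to end.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)

    causal_idx = np.sort(rng.choice(spec.n_snps, size=spec.n_causal, replace=False))
    control_freq = p.copy()
    case_freq = p.copy()
    case_freq[causal_idx] = np.minimum(p[causal_idx] + spec.effect_delta, CASE_FREQ_CAP)

    codes = np.empty((n, spec.n_snps), dtype=np.int8)
    codes[: spec.n_cases] = rng.binomial(2, case_freq, size=(spec.n_cases, spec.n_snps)) + 1
    codes[spec.n_cases :] = rng.binomial(
        2, control_freq, size=(spec.n_controls, spec.n_snps)
    ) + 1

    mask = np.zeros(codes.shape, dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random(codes.shape) < spec.missing_rate
        codes[mask] = MISSING_CODE

    snp_ids = _ids("snp", spec.n_snps, 6)
    y = _labels(spec.n_cases, spec.n_controls)
    m = GenotypeMatrix(sample_ids=y.sample_ids.copy(), snp_ids=snp_ids, codes=codes, missing_mask=mask)
    truth = CohortTruth(
        causal_snp_ids=frozenset(snp_ids[causal_idx].tolist()),
        control_freq=control_freq,
        case_freq=case_freq,
    )
    return m, y, truth


def extreme_separation_cohort(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    n_perfect: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeLabels, CohortTruth]:
    """Cohort whose first ``n_perfect`` SNPs separate the classes perfectly.

    Perfect columns are code 3 in every case and code 1 in every control, so
    they attain the theoretical fold-change maximum log2(3) and have zero
    within-class variance (infinite-separation Fisher's ratio). The remaining
    columns are Hardy-Weinberg null SNPs.
    """
    if n_perfect < 1 or n_perfect > n_snps:
        raise ValueError("n_perfect must lie in [1, n_snps]")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    codes = np.empty((n, n_snps), dtype=np.int8)
    codes[:n_cases, :n_perfect] = 3
    codes[n_cases:, :n_perfect] = 1
    n_null = n_snps - n_perfect
    control_freq = np.zeros(n_snps)
    control_freq[:n_perfect] = 0.0
    case_freq = np.zeros(n_snps)
    case_freq[:n_perfect] = 1.0
    if n_null:
        p = rng.uniform(0.05, 0.5, size=n_null)
        codes[:, n_perfect:] = rng.binomial(2, p, size=(n, n_null)) + 1
        control_freq[n_perfect:] = p
        case_freq[n_perfect:] = p
    snp_ids = np.concatenate(
        [_ids("perf", n_perfect, 4), _ids("null", max(n_null, 0), 6)]
    )
    y = _labels(n_cases, n_controls)
    m = GenotypeMatrix(sample_ids=y.sample_ids.copy(), snp_ids=snp_ids, codes=codes)
    truth = CohortTruth(
        causal_snp_ids=frozenset(snp_ids[:n_perfect].tolist()),
        control_freq=control_freq,
        case_freq=case_freq,
    )
    return m, y, truth
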
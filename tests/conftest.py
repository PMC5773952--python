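import numpy as np
import pytest

from snpsig import GenotypeMatrix, PhenotypeLabels, extreme_separation_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, sample_ids, records):
    """Write a minimal single-contig VCF.

    ``records`` is a list of (pos, snp_id, ref, alt_field, gt_strings).
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for pos, snp_id, ref, alt, gts in records:
            fh.write(
                f"1\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf


@pytest.fixture
def perfect_cohort():
    """15 samples, one perfect separator among 20 SNPs."""
    return extreme_separation_cohort(n_cases=10, n_controls=5, n_snps=20, n_perfect=1, seed=7)


def random_matrix(rng, n, m, missing_rate=0.0):
    codes = rng.integers(1, 4, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    codes[mask] = 0
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        codes=codes,
        missing_mask=mask,
    )


def labels_for(n_cases, n_controls):
    return PhenotypeLabels(
        sample_ids=np.array(
            [f"s{i}" for i in range(n_cases + n_controls)], dtype=object
        ),
        labels=np.array([1] * n_cases + [2] * n_controls, dtype=np.int8),
    )
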
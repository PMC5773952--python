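"""Readers and writers for genotype matrices and phenotype tables.

Two on-disk genotype representations are supported:

* VCF 4.x with GT fields (biallelic records only), read through ``cyvcf2``;
* a plain genotype TSV: header row ``sample_id <TAB> snp1 <TAB> snp2 ...``,
  one row per sample with codes ``1``/``2``/``3`` or ``NA`` for a missing call.

Phenotypes are a two-column TSV ``sample_id <TAB> label`` where the label is
(case-insensitively) ``case``/``control`` or the numeric aliases ``1``/``2``.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, MISSING_CODE, GenotypeMatrix, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "impute_missing",
]

_LABEL_TOKENS = {"case": CASE, "1": CASE, "control": CONTROL, "2": CONTROL}


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    GT ``0/0`` (or ``0|0``) maps to code 1, heterozygous calls to 2,
    ``1/1`` to 3 and ``./.`` to a missing entry. The SNP id is the ID
    column, falling back to ``CHROM:POS:REF:ALT`` when the ID is ``.``.
    Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    try:
        for variant in vcf:
            if len(variant.ALT) != 1:
                raise ValueError(
                    f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                    f"(ALT={variant.ALT}) is not supported"
                )
            snp_id = variant.ID
            if snp_id is None or snp_id == ".":
                snp_id = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = variant.gt_types
            col = np.empty(len(samples), dtype=np.int8)
            miss = gt == 2
            col[gt == 0] = 1
            col[gt == 1] = 2
            col[gt == 3] = 3
            col[miss] = MISSING_CODE
            snp_ids.append(snp_id)
            columns.append(col)
            masks.append(miss)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc

    if not columns:
        raise ValueError(f"VCF {path!r} contains no variant records")
    codes = np.column_stack(columns)
    mask = np.column_stack(masks)
    return GenotypeMatrix(
        sample_ids=np.array(samples, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        codes=codes,
        missing_mask=mask,
    )


def read_genotype_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the genotype TSV dialect (codes 1/2/3, ``NA`` = missing)."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path!r}: first header field must be 'sample_id', got {df.columns[0]!r}"
        )
    sample_ids = df["sample_id"].to_numpy(dtype=object)
    snp_ids = np.array(df.columns[1:], dtype=object)
    values = df.iloc[:, 1:].to_numpy(dtype=object)
    codes = np.zeros(values.shape, dtype=np.int8)
    mask = np.zeros(values.shape, dtype=bool)
    for (i, j), tok in np.ndenumerate(values):
        if tok == "NA":
            mask[i, j] = True
            codes[i, j] = MISSING_CODE
        elif tok in ("1", "2", "3"):
            codes[i, j] = int(tok)
        else:
            raise ValueError(
                f"{path!r}: invalid genotype token {tok!r} at sample "
                f"{sample_ids[i]!r}, SNP {snp_ids[j]!r} (expected 1, 2, 3 or NA)"
            )
    return GenotypeMatrix(sample_ids=sample_ids, snp_ids=snp_ids, codes=codes, missing_mask=mask)


def write_genotype_tsv(m: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a matrix in the genotype TSV dialect (missing entries as ``NA``)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(str(s) for s in m.snp_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            toks = [
                "NA" if m.missing_mask[i, j] and m.codes[i, j] == MISSING_CODE
                else str(int(m.codes[i, j]))
                for j in range(m.n_snps)
            ]
            fh.write(str(sid) + "\t" + "\t".join(toks) + "\n")


def read_phenotypes(path: str | os.PathLike) -> PhenotypeLabels:
    """Read a two-column phenotype TSV into :class:`PhenotypeLabels`."""
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(
            f"{path!r}: header must be 'sample_id<TAB>label', got {list(df.columns)}"
        )
    labels = []
    for sid, tok in zip(df["sample_id"], df["label"]):
        key = tok.strip().lower()
        if key not in _LABEL_TOKENS:
            raise ValueError(
                f"{path!r}: unknown label {tok!r} for sample {sid!r} "
                "(expected case/control/1/2)"
            )
        labels.append(_LABEL_TOKENS[key])
    y = PhenotypeLabels(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        labels=np.array(labels, dtype=np.int8),
    )
    y.require_both_classes()
    return y


def write_phenotypes(y: PhenotypeLabels, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(y.sample_ids, y.labels):
            fh.write(f"{sid}\t{'case' if lab == CASE else 'control'}\n")


def impute_missing(m: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with the per-SNP mode over all non-missing samples.

    Both classes are pooled; ties among modes break toward the smaller code.
    A SNP missing in every sample cannot be imputed and is dropped with a
    logged warning. A matrix without missing entries is returned unchanged.
    """
    if not m.missing_mask.any():
        return m
    codes = m.codes.copy()
    keep = np.ones(m.n_snps, dtype=bool)
    for j in range(m.n_snps):
        miss = m.missing_mask[:, j]
        if not miss.any():
            continue
        observed = codes[~miss, j]
        if observed.size == 0:
            keep[j] = False
            logger.warning("SNP %s is missing in all samples; dropped", m.snp_ids[j])
            continue
        counts = np.bincount(observed, minlength=4)[1:4]
        mode = int(np.argmax(counts)) + 1  # argmax takes the first (smallest) max
        codes[miss, j] = mode
    return GenotypeMatrix(
        sample_ids=m.sample_ids.copy(),
        snp_ids=m.snp_ids[keep],
        codes=codes[:, keep],
        missing_mask=m.missing_mask[:, keep].copy(),
    )
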
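"""End-to-end pipeline orchestration: simulate/read -> impute -> filter ->
discover -> stability -> networks, with a manifest of every artifact.

The configuration is a single declarative mapping (typically a YAML file).
Every stochastic stage takes an explicit seed derived from the top-level
``seed``; there is no global random state, so a rerun with the same
configuration reproduces every output byte for byte (the manifest additionally
records a timestamp).

Example configuration::

    seed: 1
    output_dir: out
    input:
      simulate: {n_cases: 120, n_controls: 40, n_snps: 2000, n_causal: 20,
                 effect_delta: 0.3}
      # or: genotypes: cohort.tsv / cohort.vcf, phenotypes: phenotypes.tsv
    filter: {tail_fraction: 0.01, fr_min: 1.5}
    classifier: {method: nearest_centroid}
    signature: {k_max: 100}
    stability: {n_splits: 500, train_fraction: 0.75}
    networks: {n_samples: 200, threshold_offset: 0.02}
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec
from .containers import GenotypeMatrix, PhenotypeLabels
from .io import (
    impute_missing,
    read_genotype_tsv,
    read_phenotypes,
    read_vcf,
    write_genotype_tsv,
    write_phenotypes,
)
from .network import max_spanning_tree, pearson_matrix, sample_networks, tree_to_networkx
from .signature import find_minimal_signature
from .simulate import CohortSpec, generate_cohort
from .stability import holdout_sampler
from .stats import select_discriminatory, snp_statistics, write_statistics_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


@_stage("input")
def _load_input(config: dict, outdir: str, seed: int):
    inp = config.get("input", {})
    if "simulate" in inp:
        sim = dict(inp["simulate"])
        sim.setdefault("seed", seed)
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        spec = CohortSpec(**sim)
        m, y, truth = generate_cohort(spec)
        write_genotype_tsv(m, os.path.join(outdir, "genotypes.tsv"))
        write_phenotypes(y, os.path.join(outdir, "phenotypes.tsv"))
        _write_json(
            {"causal_snp_ids": sorted(truth.causal_snp_ids)},
            os.path.join(outdir, "truth.json"),
        )
        return m, y
    gpath = inp.get("genotypes")
    ppath = inp.get("phenotypes")
    for path in (gpath, ppath):
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"input file not found: {path!r}")
    m = read_vcf(gpath) if str(gpath).endswith(".vcf") else read_genotype_tsv(gpath)
    y = read_phenotypes(ppath)
    return m, y


def run_pipeline(config: dict | str | os.PathLike) -> dict:
    """Execute the full discovery pipeline and write all artifacts.

    Returns a dict with the in-memory results and the manifest. Any stage
    error aborts with :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        import yaml

        with open(os.fspath(config)) as fh:
            config = yaml.safe_load(fh)

    seed = int(config.get("seed", 0))
    outdir = os.fspath(config.get("output_dir", "snpsig_out"))
    os.makedirs(outdir, exist_ok=True)
    spec = ClassifierSpec(**config.get("classifier", {}))

    m, y = _load_input(config, outdir, seed)

    @_stage("impute")
    def do_impute(m):
        return impute_missing(m)

    m = do_impute(m)
    y = y.aligned_to(m)

    @_stage("filter")
    def do_filter(m, y):
        fcfg = config.get("filter", {})
        stats = snp_statistics(m, y)
        ranked = select_discriminatory(
            stats,
            tail_fraction=fcfg.get("tail_fraction", 0.01),
            fr_min=fcfg.get("fr_min", 1.5),
            top_k=fcfg.get("top_k"),
        )
        write_statistics_tsv(stats, os.path.join(outdir, "snp_statistics.tsv"))
        write_statistics_tsv(ranked, os.path.join(outdir, "ranked_snps.tsv"))
        return ranked

    ranked = do_filter(m, y)
    if ranked.empty:
        raise PipelineError("stage 'filter' retained no SNPs; relax the thresholds")

    @_stage("discover")
    def do_discover(m, y, ranked):
        k_max = config.get("signature", {}).get("k_max")
        if k_max is not None:
            k_max = min(k_max, len(ranked))
        sig, curve = find_minimal_signature(m, y, ranked, k_max=k_max, spec=spec)
        _write_json(sig.as_dict(), os.path.join(outdir, "signature.json"))
        curve.to_csv(
            os.path.join(outdir, "accuracy_curve.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        return sig

    signature = do_discover(m, y, ranked)

    @_stage("stability")
    def do_stability(m, y, signature):
        scfg = config.get("stability", {})
        summary = holdout_sampler(
            m,
            y,
            signature,
            n_splits=scfg.get("n_splits", 5000),
            train_fraction=scfg.get("train_fraction", 0.75),
            spec=spec,
            seed=scfg.get("seed", seed + 1),
            rederive=scfg.get("rederive", False),
            tail_fraction=config.get("filter", {}).get("tail_fraction", 0.01),
            fr_min=config.get("filter", {}).get("fr_min", 1.5),
            k_max=config.get("signature", {}).get("k_max"),
        )
        pd.DataFrame(
            {
                "split": np.arange(summary.n_splits),
                "accuracy": summary.accuracies,
                "tpr": summary.tprs,
                "tnr": summary.tnrs,
            }
        ).to_csv(
            os.path.join(outdir, "holdout_accuracies.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        pd.DataFrame(summary.cdf, columns=["accuracy", "cumulative_probability"]).to_csv(
            os.path.join(outdir, "holdout_cdf.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        _write_json(summary.as_dict(), os.path.join(outdir, "holdout_summary.json"))
        return summary

    stability = do_stability(m, y, signature)

    @_stage("networks")
    def do_networks(m, y, ranked, signature):
        ncfg = config.get("networks", {})
        posterior = sample_networks(
            m,
            y,
            ranked,
            network_size=ncfg.get("network_size", signature.size),
            n_samples=ncfg.get("n_samples", 1000),
            threshold_offset=ncfg.get("threshold_offset", 0.02),
            spec=spec,
            seed=ncfg.get("seed", seed + 2),
        )
        posterior.posterior_frequency.rename_axis("snp_id").reset_index().to_csv(
            os.path.join(outdir, "network_posterior.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        tree = None
        if signature.size >= 2:
            corr = pearson_matrix(m, list(signature.snp_ids))
            tree = max_spanning_tree(corr, minimum=ncfg.get("minimum", False))
            pd.DataFrame(
                list(tree.edges), columns=["snp_a", "snp_b", "pearson_r"]
            ).to_csv(
                os.path.join(outdir, "tree_edges.tsv"), sep="\t", index=False,
                float_format="%.10g",
            )
            import networkx as nx

            nx.write_graphml(tree_to_networkx(tree), os.path.join(outdir, "tree.graphml"))
        return posterior, tree

    posterior, tree = do_networks(m, y, ranked, signature)

    files = sorted(
        f for f in os.listdir(outdir)
        if os.path.isfile(os.path.join(outdir, f)) and f != "manifest.json"
    )
    manifest = {
        "snpsig_version": __version__,
        "config": config,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {f: _sha256(os.path.join(outdir, f)) for f in files},
    }
    _write_json(manifest, os.path.join(outdir, "manifest.json"))

    return {
        "genotypes": m,
        "phenotypes": y,
        "ranked": ranked,
        "signature": signature,
        "stability": stability,
        "posterior": posterior,
        "tree": tree,
        "manifest": manifest,
        "output_dir": outdir,
    }
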
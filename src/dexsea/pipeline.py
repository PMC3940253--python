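"""End-to-end orchestration: normalize -> differential expression ->
per-tissue enrichment -> candidate overlap -> clustering, with a run
manifest for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    TISSUES,
    ExpressionMatrix,
    filter_sets_by_size,
    read_design,
    read_expression,
    read_gene_list,
    read_gmt,
    read_homolog_map,
    translate_ids,
)
from .cluster import cluster_bimodal, tissue_genotype_separation
from .diffexpr import fit_gene_models, tissue_nonspecific_fraction
from .gsea import run_gsea
from .overlap import hypergeometric_overlap
from .preprocess import quantile_normalize

logger = logging.getLogger(__name__)

# fixed offsets fanning the run seed out to per-stage child seeds
SEED_OFFSETS = {"gsea_blood": 101, "gsea_cerebellum": 202}
_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    """Paths and parameters of a full analysis run."""

    matrix: str
    design: str
    gmt: str
    out_dir: str
    candidates: str | None = None
    homolog_map: str | None = None
    scale: str = "linear"
    alpha: float = 0.01
    n_draws: int = 2000
    min_size: int = 15
    max_size: int = 500
    tissues: tuple[str, ...] = TISSUES
    seed: int = 0

    def validate(self) -> None:
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("invalid set size bounds")
        for t in self.tissues:
            if t not in TISSUES:
                raise ValueError(f"unknown tissue {t!r}")


def load_pipeline_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` config file (one pair per line, '#'
    comments)."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
    kwargs: dict = {}
    casts = {
        "alpha": float, "n_draws": int, "min_size": int, "max_size": int,
        "seed": int,
    }
    for key, val in values.items():
        if key == "tissues":
            kwargs[key] = tuple(t.strip() for t in val.split(","))
        else:
            kwargs[key] = casts.get(key, str)(val)
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + SEED_OFFSETS.get(stage, 0)) % _SEED_MOD


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and write result tables to the output
    directory.

    Outputs: norm.tsv, de.tsv, gsea_<tissue>.tsv, overlap.tsv (if a
    candidate list is given), cluster_matrix.tsv + dendrogram Newicks, and
    manifest.json recording seed, parameters and stage completion.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "dexsea",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "n_draws": config.n_draws,
            "set_size_bounds": [config.min_size, config.max_size],
            "tissues": list(config.tissues),
        },
        "stages": {},
    }

    def finish(stage: str, ok: bool = True) -> None:
        manifest["stages"][stage] = "ok" if ok else "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    stage = "load"
    try:
        matrix = read_expression(config.matrix, scale_hint=config.scale)
        design = read_design(config.design).aligned_to(matrix.sample_ids)
        collection = read_gmt(config.gmt)
        finish(stage)

        stage = "normalize"
        norm = quantile_normalize(matrix.to_log2())
        norm.data.rename_axis("gene").to_csv(out / "norm.tsv", sep="\t",
                                             float_format="%.17g")
        finish(stage)

        stage = "diffexpr"
        de = fit_gene_models(norm, design)
        de.to_csv(out / "de.tsv", sep="\t", float_format="%.17g")
        n_sig, n_flat, frac = tissue_nonspecific_fraction(de, config.alpha)
        manifest["n_significant"] = n_sig
        manifest["tissue_flat_fraction"] = frac
        finish(stage)

        stage = "gsea"
        filtered = filter_sets_by_size(
            collection, norm.gene_ids, config.min_size, config.max_size
        )
        gsea_results = {}
        for tissue in config.tissues:
            res = run_gsea(
                norm, design, tissue, filtered,
                n_draws=config.n_draws,
                seed=_stage_seed(config.seed, f"gsea_{tissue}"),
            )
            res.to_csv(out / f"gsea_{tissue}.tsv", sep="\t",
                       float_format="%.17g")
            gsea_results[tissue] = res
        finish(stage)

        stage = "overlap"
        overlap_result = None
        if config.candidates:
            de_genes = list(de.index[de["p"] < config.alpha])
            universe = list(de.index)
            candidates = read_gene_list(config.candidates)
            if config.homolog_map:
                mapping = read_homolog_map(config.homolog_map)
                de_genes = translate_ids(de_genes, mapping)
                universe = translate_ids(universe, mapping)
            overlap_result = hypergeometric_overlap(universe, candidates, de_genes)
            pd.DataFrame([vars(overlap_result)]).to_csv(
                out / "overlap.tsv", sep="\t", index=False,
                float_format="%.17g",
            )
        finish(stage)

        stage = "cluster"
        sig_genes = de.index[de["p"] < config.alpha]
        cluster_report = None
        if len(sig_genes) >= 2:
            sig_matrix = ExpressionMatrix(norm.data.loc[sig_genes], scale="log2")
            genes_tree, samples_tree, ordered = cluster_bimodal(sig_matrix)
            ordered.data.rename_axis("gene").to_csv(
                out / "cluster_matrix.tsv", sep="\t", float_format="%.17g"
            )
            (out / "genes.nwk").write_text(genes_tree.to_newick() + "\n")
            (out / "samples.nwk").write_text(samples_tree.to_newick() + "\n")
            cluster_report = tissue_genotype_separation(samples_tree, design)
            manifest["tissue_separated"] = bool(cluster_report["tissue_separated"])
            manifest["cell_separated"] = bool(cluster_report["cell_separated"])
        else:
            logger.warning("cluster: fewer than 2 significant genes; skipped")
        finish(stage)
    except Exception as exc:
        finish(stage, ok=False)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "de": de,
        "gsea": gsea_results,
        "overlap": overlap_result,
        "cluster": cluster_report,
        "manifest": manifest,
    }
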
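"""Synthetic two-genotype x two-tissue expression data with planted truth.

The generator emulates a paired-tissue microarray study: every gene has a
baseline log2 intensity, a fraction of genes carry a strong tissue main
effect, a small set of genes carry a genotype (transgenic vs wildtype) shift,
and one or more planted pathways carry a coherent sub-significance shift
across their members — the regime in which per-gene tests fail but gene-set
enrichment succeeds. Values are exported on the linear intensity scale
(2**x), mirroring summarized absolute intensities; preprocessing re-logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
    write_design,
    write_expression,
    write_gmt,
)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its constraints."""


@dataclass
class PlantedSet:
    """A pathway with a coherent genotype shift planted across its members.

    Members are drawn at random unless ``members`` pins them to specific
    gene ids, which lets several simulated datasets perturb the same
    pathway definition (a fixed database shared across studies).
    """

    name: str
    size: int
    mean_shift_log2: float  # magnitude of the per-member genotype shift
    direction: str = "up"  # "up" | "down"
    members: list[str] | None = None


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate a small paired-design microarray study: 10,000 genes,
    5 replicates per tissue x genotype cell, strong tissue effects on most
    genes (sd 1.0 log2), a handful of genotype-responsive genes at 1.0 log2,
    and i.i.d. Gaussian noise (sd 0.5 log2).
    """

    n_genes: int = 10_000
    n_per_cell: int = 5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    tissue_effect_sd: float = 1.0
    frac_tissue_affected: float = 0.7
    n_de_genes: int = 50
    de_effect_log2: float = 1.0
    frac_de_tissue_flat: float = 0.0  # fraction of DE genes with no tissue effect
    planted_sets: list[PlantedSet] = field(default_factory=list)
    n_background_sets: int = 50
    set_size_range: tuple[int, int] = (15, 500)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_per_cell < 1:
            raise ConfigError("n_per_cell must be >= 1")
        if not 0 <= self.frac_tissue_affected <= 1:
            raise ConfigError("frac_tissue_affected must be in [0, 1]")
        if not 0 <= self.frac_de_tissue_flat <= 1:
            raise ConfigError("frac_de_tissue_flat must be in [0, 1]")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes must satisfy 0 <= n_de_genes <= n_genes")
        for sd_name in ("tissue_effect_sd", "noise_sd", "baseline_sd_log2"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be >= 0")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("set_size_range must satisfy 1 <= min <= max")
        if self.n_background_sets < 0:
            raise ConfigError("n_background_sets must be >= 0")
        if hi > self.n_genes:
            raise ConfigError("set_size_range max exceeds n_genes")
        seen = set()
        for ps in self.planted_sets:
            size = len(ps.members) if ps.members is not None else ps.size
            if size < 1 or size > self.n_genes:
                raise ConfigError(f"planted set {ps.name!r}: size out of range")
            if ps.members is not None and len(set(ps.members)) != len(ps.members):
                raise ConfigError(f"planted set {ps.name!r}: duplicate members")
            if ps.direction not in ("up", "down"):
                raise ConfigError(
                    f"planted set {ps.name!r}: direction must be 'up' or 'down'"
                )
            if ps.name in seen:
                raise ConfigError(f"duplicate planted set name {ps.name!r}")
            seen.add(ps.name)


@dataclass
class SimulationTruth:
    """Ground truth of the planted effects."""

    de_gene_ids: list[str]
    planted_set_names: list[str]
    per_gene_true_effect: dict[str, float]  # gene id -> log2 genotype shift
    tissue_flat_de_gene_ids: list[str] = field(default_factory=list)


def _sample_ids(n_per_cell: int) -> tuple[list[str], list[str], list[str]]:
    samples, tissues, genotypes = [], [], []
    for tissue in ("blood", "cerebellum"):
        for genotype in ("transgenic", "wildtype"):
            for i in range(1, n_per_cell + 1):
                samples.append(f"{tissue[:2]}_{genotype[:2]}_{i:02d}")
                tissues.append(tissue)
                genotypes.append(genotype)
    return samples, tissues, genotypes


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, GeneSetCollection, SimulationTruth]:
    """Generate a linear-scale expression matrix, its design, gene sets and
    the planted truth. Identical configs (including seed) give identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]

    samples, tissues, genotypes = _sample_ids(config.n_per_cell)
    tissue_ind = np.array([t == "cerebellum" for t in tissues], dtype=float)
    geno_ind = np.array([g == "transgenic" for g in genotypes], dtype=float)

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)

    # Tissue main effects on a random majority of genes.
    tissue_effect = np.zeros(n)
    n_tissue = int(round(config.frac_tissue_affected * n))
    tissue_idx = rng.choice(n, size=n_tissue, replace=False)
    tissue_effect[tissue_idx] = rng.normal(0.0, config.tissue_effect_sd, size=n_tissue)

    # Genotype effects: individually significant DE genes ...
    geno_effect = np.zeros(n)
    de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    geno_effect[de_idx] = signs * config.de_effect_log2
    de_gene_ids = [gene_ids[i] for i in sorted(de_idx)]

    # ... a sub-fraction of which has its tissue effect zeroed (tissue-flat).
    # When that fraction is requested, the remaining DE genes get a
    # guaranteed-nonzero tissue effect (magnitude >= tissue_effect_sd / 2) so
    # the planted flat fraction is recoverable, not blurred by near-zero draws.
    n_flat = int(round(config.frac_de_tissue_flat * config.n_de_genes))
    flat_idx = np.array(sorted(de_idx))[:n_flat] if n_flat else np.array([], dtype=int)
    if n_flat:
        tissue_effect[flat_idx] = 0.0
        nonflat = np.array(sorted(de_idx))[n_flat:]
        if nonflat.size:
            mag = config.tissue_effect_sd * (
                0.5 + np.abs(rng.standard_normal(nonflat.size))
            )
            tissue_effect[nonflat] = rng.choice([-1.0, 1.0], size=nonflat.size) * mag
    tissue_flat_ids = [gene_ids[i] for i in flat_idx]

    # ... and coherent sub-significance shifts across planted pathway members.
    sets: dict[str, tuple[str, list[str]]] = {}
    non_de = np.setdiff1d(np.arange(n), de_idx)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for ps in config.planted_sets:
        if ps.members is not None:
            unknown = [g for g in ps.members if g not in gene_pos]
            if unknown:
                raise ConfigError(
                    f"planted set {ps.name!r}: unknown gene ids {unknown[:5]}"
                )
            member_idx = np.array([gene_pos[g] for g in ps.members])
        else:
            pool = non_de if len(non_de) >= ps.size else np.arange(n)
            member_idx = rng.choice(pool, size=ps.size, replace=False)
        shift = ps.mean_shift_log2 * (1.0 if ps.direction == "up" else -1.0)
        geno_effect[member_idx] += shift
        members = [gene_ids[i] for i in sorted(member_idx)]
        sets[ps.name] = (f"planted {ps.direction} {ps.mean_shift_log2} log2", members)

    # Background sets: random members, overlap across sets allowed.
    lo, hi = config.set_size_range
    for k in range(1, config.n_background_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        member_idx = rng.choice(n, size=size, replace=False)
        members = [gene_ids[i] for i in sorted(member_idx)]
        sets[f"BG{k:04d}"] = ("background", members)

    log2_values = (
        baseline[:, None]
        + tissue_effect[:, None] * tissue_ind[None, :]
        + geno_effect[:, None] * geno_ind[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n, len(samples)))
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, log2_values), index=gene_ids, columns=samples),
        scale="linear",
    )
    design = SampleDesign(
        pd.DataFrame(
            {"tissue": tissues, "genotype": genotypes}, index=pd.Index(samples, name="sample")
        )
    )
    truth = SimulationTruth(
        de_gene_ids=de_gene_ids,
        planted_set_names=[ps.name for ps in config.planted_sets],
        per_gene_true_effect={
            gene_ids[i]: float(geno_effect[i]) for i in np.nonzero(geno_effect)[0]
        },
        tissue_flat_de_gene_ids=tissue_flat_ids,
    )
    return matrix, design, GeneSetCollection(sets), truth


def write_outputs(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    collection: GeneSetCollection,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write matrix.tsv, design.tsv, sets.gmt and truth.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "design": out / "design.tsv",
        "gmt": out / "sets.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression(matrix, paths["matrix"])
    write_design(design, paths["design"])
    write_gmt(collection, paths["gmt"])
    rows = [
        {
            "gene": g,
            "true_effect_log2": e,
            "is_de": g in set(truth.de_gene_ids),
            "is_tissue_flat_de": g in set(truth.tissue_flat_de_gene_ids),
        }
        for g, e in truth.per_gene_true_effect.items()
    ]
    pd.DataFrame(rows, columns=["gene", "true_effect_log2", "is_de", "is_tissue_flat_de"]).to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.17g"
    )
    return paths
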
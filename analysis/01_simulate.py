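"""Generate the two synthetic mouse-model datasets used by the downstream
analyses.

Model A emulates a 5-transgenic vs 5-wildtype study, model B a smaller
3 vs 3 study; both profile paired blood and cerebellum samples over the
same 4,000-gene universe and are analyzed against one shared gene-set
collection, as two studies would be against one pathway database. Each
model carries a handful of genotype-responsive genes and strong tissue
main effects. One pathway (PATHWAY_SHARED) is perturbed in both models —
the same member genes in each — one pathway is private to model A
(PATHWAY_A_ONLY) and one background set (BG0001) is perturbed only in
model B, standing in for a model-private pathway. Member shifts of
0.8-1.0 log2 are too subtle for per-gene significance at these sample
sizes, the regime where pathway-level analysis outperforms per-gene
testing.

Writes matrix/design/truth per model under results/data/<model>/ and the
shared collection to results/data/sets.gmt.
"""

from pathlib import Path

from dexsea.io import write_gmt
from dexsea.simulate import (
    PlantedSet,
    SimulationConfig,
    simulate_experiment,
    write_outputs,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config_a = SimulationConfig(
        n_genes=4000, n_per_cell=5, n_de_genes=40, de_effect_log2=1.5,
        tissue_effect_sd=2.5, frac_de_tissue_flat=0.15,
        planted_sets=[
            PlantedSet("PATHWAY_SHARED", 60, 0.8, "up"),
            PlantedSet("PATHWAY_A_ONLY", 40, 1.0, "down"),
        ],
        n_background_sets=40, set_size_range=(15, 400), seed=101,
    )
    matrix_a, design_a, collection, truth_a = simulate_experiment(config_a)
    write_outputs(OUT / "model_a", matrix_a, design_a, collection, truth_a)
    write_gmt(collection, OUT / "sets.gmt")
    print(f"model_a: {len(matrix_a.gene_ids)} genes x "
          f"{len(matrix_a.sample_ids)} samples; shared collection of "
          f"{len(collection)} sets -> {OUT / 'sets.gmt'}")

    # model B perturbs the same PATHWAY_SHARED members, plus one background
    # set of the shared collection; its own set draws are discarded.
    config_b = SimulationConfig(
        n_genes=4000, n_per_cell=3, n_de_genes=40, de_effect_log2=1.5,
        tissue_effect_sd=2.5, frac_de_tissue_flat=0.5,
        planted_sets=[
            PlantedSet("PATHWAY_SHARED", 60, 0.8, "up",
                       members=collection.members("PATHWAY_SHARED")),
            PlantedSet("B_PRIVATE", 0, 1.0, "up",
                       members=collection.members("BG0001")),
        ],
        n_background_sets=0, set_size_range=(15, 400), seed=202,
    )
    matrix_b, design_b, _, truth_b = simulate_experiment(config_b)
    write_outputs(OUT / "model_b", matrix_b, design_b, collection, truth_b)
    print(f"model_b: {len(matrix_b.gene_ids)} genes x "
          f"{len(matrix_b.sample_ids)} samples; perturbed PATHWAY_SHARED "
          f"and BG0001 of the shared collection")


if __name__ == "__main__":
    main()
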
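"""Compare the two models: shared significant genes, the shared-pathway
matrix, the leading-edge intersection of the commonly enriched pathway,
and a candidate-gene overlap test.

The candidate list is a synthetic stand-in for a curated disease-gene
database: 30 genes, one third drawn from model A's true planted DE genes,
the rest random. Writes shared_genes.tsv, shared_pathways.tsv and
candidate_overlap.tsv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dexsea.gsea import leading_edge_overlap
from dexsea.overlap import cross_model_shared_genes, hypergeometric_overlap

ROOT = Path(__file__).resolve().parent.parent / "results"
ALPHA = 0.01


def load(model: str):
    de = pd.read_csv(ROOT / model / "de.tsv", sep="\t", index_col=0)
    gsea = {
        tissue: pd.read_csv(ROOT / model / f"gsea_{tissue}.tsv", sep="\t",
                            index_col=0)
        for tissue in ("blood", "cerebellum")
    }
    return de, gsea


def main() -> None:
    de_a, gsea_a = load("model_a")
    de_b, gsea_b = load("model_b")

    shared = cross_model_shared_genes(de_a, de_b, alpha=ALPHA)
    shared.to_csv(ROOT / "shared_genes.tsv", sep="\t", float_format="%.17g")
    print(f"genes significant in both models at p < {ALPHA}: {len(shared)}")
    for gene, row in shared.iterrows():
        print(f"    {gene}: {row['direction_a']} in A, {row['direction_b']} in B")

    # pathway-by-analysis significance matrix across the two models
    cells = {}
    for model, gsea in (("A", gsea_a), ("B", gsea_b)):
        for tissue, res in gsea.items():
            cells[f"{model}_{tissue}"] = (res["perm_p"] < 0.05)
    matrix = pd.DataFrame(cells)
    if matrix.isna().any().any():  # sets absent from one analysis
        matrix = matrix.fillna(False).astype(bool)
    matrix.to_csv(ROOT / "shared_pathways.tsv", sep="\t")
    both_brain = matrix.index[matrix["A_cerebellum"] & matrix["B_cerebellum"]]
    print(f"pathways enriched in cerebellum of both models: {list(both_brain)}")

    for name in both_brain:
        core = leading_edge_overlap(gsea_a["cerebellum"], gsea_b["cerebellum"],
                                    name)
        print(f"    {name}: {core[:8]}{'...' if len(core) > 8 else ''} "
              f"({len(core)} shared leading-edge genes)")

    # synthetic candidate list: a third true positives, the rest random
    truth_a = pd.read_csv(ROOT / "data" / "model_a" / "truth.tsv", sep="\t")
    de_genes_a = truth_a.loc[truth_a["is_de"], "gene"].tolist()
    rng = np.random.default_rng(7)
    candidates = (list(rng.choice(de_genes_a, 10, replace=False))
                  + list(rng.choice(de_a.index, 20, replace=False)))
    observed_de = list(de_a.index[de_a["p"] < ALPHA])
    test = hypergeometric_overlap(list(de_a.index), candidates, observed_de)
    pd.DataFrame([vars(test)]).to_csv(ROOT / "candidate_overlap.tsv", sep="\t",
                                      index=False, float_format="%.17g")
    print(f"candidate overlap (model A): {test.overlap} of "
          f"{test.de_in_universe} significant genes in the candidate list, "
          f"hypergeometric p = {test.p_value:.3g}")


if __name__ == "__main__":
    main()
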
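"""Hypergeometric overlap tests and cross-model gene-list comparison.

The universe is the set of genes actually measured (after any filtering),
not the whole genome; candidate and differential lists are intersected with
it before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats


@dataclass
class OverlapTest:
    universe_size: int
    candidates_in_universe: int
    de_in_universe: int
    overlap: int
    p_value: float


def hypergeometric_overlap(
    universe: Iterable[str], candidates: Iterable[str], de_list: Iterable[str]
) -> OverlapTest:
    """Upper-tail hypergeometric test of candidate / DE list overlap.

    p = P(X >= k) for X ~ Hypergeometric(universe, candidates, draws=DE),
    computed as an exact tail sum.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    cand = set(candidates) & uni
    de = set(de_list) & uni
    k = len(cand & de)
    # survival function at k-1 gives P(X >= k) exactly
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(cand), len(de)))
    return OverlapTest(
        universe_size=len(uni),
        candidates_in_universe=len(cand),
        de_in_universe=len(de),
        overlap=k,
        p_value=min(max(p, 0.0), 1.0),
    )


def cross_model_shared_genes(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Genes significant (p < alpha) in both models, with each model's
    direction of change.

    Both result tables must share a common gene universe. Returns a
    DataFrame indexed by gene with p and effect-direction columns for each
    model.
    """
    common = de_a.index.intersection(de_b.index)
    if len(common) == 0:
        raise ValueError("the two results share no genes")
    a = de_a.loc[common]
    b = de_b.loc[common]
    mask = (a["p"] < alpha) & (b["p"] < alpha)
    shared = common[mask]
    return pd.DataFrame(
        {
            "p_a": a.loc[shared, "p"],
            "direction_a": ["up" if e >= 0 else "down"
                            for e in a.loc[shared, "genotype_effect"]],
            "p_b": b.loc[shared, "p"],
            "direction_b": ["up" if e >= 0 else "down"
                            for e in b.loc[shared, "genotype_effect"]],
        },
        index=pd.Index(shared, name="gene"),
    )
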
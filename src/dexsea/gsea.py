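"""Gene-set enrichment with a size-matched random-gene-set permutation null.

The procedure, designed for studies too small for phenotype-label
permutation:

1. Rank all genes by signal-to-noise: (mean_tg - mean_wt) / (sd_tg + sd_wt),
   transgenic vs wildtype within one tissue, descending.
2. Walk the ranked list with a running sum that rises by 1/Nh at gene-set
   members and falls by 1/(N - Nh) elsewhere; the enrichment score (ES) is
   the signed maximum deviation from zero, and the members encountered up to
   the extremum form the leading-edge subset.
3. The null distribution of ES for a set of size s is built by scoring
   random gene subsets of size s on the same fixed ranking (default 2,000
   draws, so the smallest attainable permutation p is 1/2000 = 0.0005).
4. ES is normalized by the mean |ES| of same-sign null draws (NES); FDR q
   for each set compares its |NES| tail fraction in the pooled normalized
   null against the tail fraction among the observed NES of the same sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SampleDesign
from .diffexpr import DesignError

SD_FLOOR_FRACTION = 0.2  # each group sd floored at this fraction of |group mean|
SD_FLOOR_ABS = 1e-8


@dataclass
class RankedList:
    """Genes ordered best-to-worst by the ranking metric."""

    gene_ids: list[str]
    metric: np.ndarray  # non-increasing
    grouping: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene_ids and metric lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class NullDistribution:
    """Background ES values from size-matched random gene sets."""

    set_size: int
    n_draws: int
    null_es: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.null_es) != self.n_draws:
            raise ValueError("null_es length must equal n_draws")


def signal_to_noise(
    matrix: ExpressionMatrix, design: SampleDesign, tissue: str
) -> RankedList:
    """Rank genes by (mean_tg - mean_wt) / (sd_tg + sd_wt) within a tissue.

    Each group sd is floored at max(sd, 0.2*|group mean|, 1e-8) so constant
    genes cannot produce infinite metrics. Ties keep input gene order.
    """
    if matrix.scale != "log2":
        raise ValueError("signal_to_noise expects a log2-scale matrix")
    design = design.aligned_to(matrix.sample_ids)
    in_tissue = (design.table["tissue"] == tissue).to_numpy()
    geno = (design.table["genotype"] == "transgenic").to_numpy()
    tg_cols = in_tissue & geno
    wt_cols = in_tissue & ~geno
    if tg_cols.sum() < 2 or wt_cols.sum() < 2:
        raise DesignError(
            f"need >= 2 samples per genotype in tissue {tissue!r} "
            f"(got {int(tg_cols.sum())} transgenic, {int(wt_cols.sum())} wildtype)"
        )
    x = matrix.values
    tg, wt = x[:, tg_cols], x[:, wt_cols]

    def floored_sd(g: np.ndarray) -> np.ndarray:
        sd = g.std(axis=1, ddof=1)
        return np.maximum(sd, np.maximum(SD_FLOOR_FRACTION * np.abs(g.mean(axis=1)),
                                         SD_FLOOR_ABS))

    metric = (tg.mean(axis=1) - wt.mean(axis=1)) / (floored_sd(tg) + floored_sd(wt))
    order = np.argsort(-metric, kind="stable")
    return RankedList(
        gene_ids=[matrix.gene_ids[i] for i in order],
        metric=metric[order],
        grouping=f"transgenic vs wildtype in {tissue}",
    )


def enrichment_score(
    ranked: RankedList, members
) -> tuple[float, list[str], np.ndarray]:
    """Running-sum enrichment score for one gene set.

    Returns (es, leading_edge, running_sum). ES is the signed maximum
    deviation of the running sum, which rises 1/Nh at members and falls
    1/(N-Nh) elsewhere and always returns to zero. For positive ES the
    leading edge is the members at or before the maximum, in rank order;
    for negative ES, the members at or after the minimum, in reverse rank
    order. An exact |max| = |min| tie resolves to the positive extremum.
    """
    member_set = set(members)
    hits = np.fromiter((g in member_set for g in ranked.gene_ids), dtype=bool,
                       count=len(ranked))
    n = hits.size
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list")
    steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [g for g, h in zip(ranked.gene_ids[: i_max + 1], hits) if h]
    else:
        es = float(running[i_min])
        tail = [
            ranked.gene_ids[i] for i in range(i_min, n) if hits[i]
        ]
        leading = tail[::-1]
    return es, leading, running


def _es_from_hit_positions(pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many draws given sorted 1-based hit positions.

    ``pos`` is (n_draws, s). The running-sum extrema can only occur just
    after a hit (local max) or just before a hit (local min), which this
    evaluates in closed form.
    """
    n_draws, s = pos.shape
    i = np.arange(1, s + 1)[None, :]
    miss_before = (pos - i) / (n - s)
    after = i / s - miss_before       # running sum right after each hit
    before = (i - 1) / s - miss_before  # right before each hit
    top = after.max(axis=1)
    bottom = np.minimum(before.min(axis=1), 0.0)
    return np.where(top >= -bottom, top, bottom)


def sample_null(
    ranked: RankedList,
    set_size: int,
    n_draws: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Null ES distribution from uniform without-replacement gene subsets.

    The draws depend only on the ranked universe's size, so one null serves
    every gene set of the same size on the same ranking.
    """
    n = len(ranked)
    if not 1 <= set_size < n:
        raise ValueError(f"set_size must be in [1, {n - 1}], got {set_size}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # Rank each draw's uniform keys; the set_size smallest give a uniform
    # without-replacement subset of positions.
    keys = rng.random((n_draws, n))
    idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    pos = np.sort(idx, axis=1) + 1  # 1-based hit positions
    null_es = _es_from_hit_positions(pos, n)
    return NullDistribution(set_size=set_size, n_draws=n_draws, null_es=null_es,
                            seed=seed)


def permutation_p(es: float, null: NullDistribution) -> float:
    """Permutation p: null draws at least as extreme in magnitude.

    p = max(#{|null ES| >= |es|}, 1) / n_draws, so with 2,000 draws the
    smallest attainable p is 0.0005 and p is exactly uniform when the
    observed set is itself a random draw. (Counting only same-sign draws
    against the full denominator would double the type-I rate under a
    sign-symmetric null.) es = 0 gives p = 1.
    """
    if null.n_draws == 0:
        raise ValueError("empty null distribution")
    if es == 0.0:
        return 1.0
    count = int((np.abs(null.null_es) >= abs(es)).sum())
    return max(count, 1) / null.n_draws


def normalized_es(es: float, null: NullDistribution) -> float:
    """NES: ES divided by the mean |ES| of same-sign null draws."""
    if es == 0.0:
        return 0.0
    same_sign = null.null_es > 0 if es > 0 else null.null_es < 0
    if not same_sign.any():
        raise ValueError("no same-sign null ES values; NES undefined")
    return float(es / np.abs(null.null_es[same_sign]).mean())


def _normalize_null(null_es: np.ndarray) -> np.ndarray:
    """Normalize each null draw by its own distribution's same-sign mean |ES|."""
    out = np.zeros_like(null_es)
    pos = null_es > 0
    neg = null_es < 0
    if pos.any():
        out[pos] = null_es[pos] / np.abs(null_es[pos]).mean()
    if neg.any():
        out[neg] = null_es[neg] / np.abs(null_es[neg]).mean()
    return out


def gsea_fdr(nes_observed: np.ndarray, nulls: list[NullDistribution]) -> np.ndarray:
    """FDR q per set from the pooled normalized null.

    q(nes*) = [same-sign pooled-null tail fraction at |nes*|] /
              [same-sign observed tail fraction at |nes*|], clipped to
    [0, 1] and made monotone non-increasing in |nes| within each sign.
    """
    nes = np.asarray(nes_observed, dtype=float)
    pooled = np.concatenate([_normalize_null(nd.null_es) for nd in nulls])
    q = np.ones_like(nes)
    for sign in (1.0, -1.0):
        obs_mask = nes * sign > 0
        if not obs_mask.any():
            continue
        null_side = pooled[pooled * sign > 0]
        obs_side = np.abs(nes[obs_mask])
        for i in np.nonzero(obs_mask)[0]:
            a = abs(nes[i])
            null_frac = (
                (np.abs(null_side) >= a).mean() if null_side.size else 0.0
            )
            obs_frac = (obs_side >= a).mean()
            q[i] = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 0.0
        # monotone: each set may take the smallest raw q among equally or
        # less extreme sets of its sign, so q never increases with |NES|
        idx = np.nonzero(obs_mask)[0]
        order = np.argsort(-np.abs(nes[idx]), kind="stable")
        q_desc = q[idx[order]]
        q[idx[order]] = np.minimum.accumulate(q_desc[::-1])[::-1]
    return q


def run_gsea(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    tissue: str,
    collection: GeneSetCollection,
    n_draws: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full enrichment analysis for one tissue.

    The collection should already be size-filtered to the measured universe.
    One seeded random stream drives all null draws; null distributions are
    cached by set size and shared across equally sized sets. Returns a
    DataFrame indexed by set name with columns size, es, nes, perm_p, fdr_q,
    leading_edge (comma-joined, rank order).
    """
    ranked = signal_to_noise(matrix, design, tissue)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, NullDistribution] = {}
    rows = []
    nulls_per_set: list[NullDistribution] = []
    measured = set(ranked.gene_ids)
    for name in collection.names():
        members = [g for g in collection.members(name) if g in measured]
        es, leading, _ = enrichment_score(ranked, members)
        size = len(members)
        if size not in null_cache:
            null_cache[size] = sample_null(ranked, size, n_draws=n_draws, rng=rng)
        null = null_cache[size]
        rows.append(
            {
                "name": name,
                "size": size,
                "es": es,
                "nes": normalized_es(es, null),
                "perm_p": permutation_p(es, null),
                "leading_edge": ",".join(leading),
            }
        )
        nulls_per_set.append(null)
    columns = ["size", "es", "nes", "perm_p", "fdr_q", "leading_edge"]
    if not rows:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="name"))
    result = pd.DataFrame(rows).set_index("name")
    result["fdr_q"] = gsea_fdr(result["nes"].to_numpy(), nulls_per_set)
    return result[columns]


def leading_edge_overlap(
    result_a: pd.DataFrame, result_b: pd.DataFrame, set_name: str
) -> list[str]:
    """Genes shared by a set's leading edges in two analyses, ordered as in
    the first."""
    for res in (result_a, result_b):
        if set_name not in res.index:
            raise KeyError(f"set {set_name!r} missing from enrichment result")
    le_a = [g for g in str(result_a.loc[set_name, "leading_edge"]).split(",") if g]
    le_b = {g for g in str(result_b.loc[set_name, "leading_edge"]).split(",") if g}
    return [g for g in le_a if g in le_b]
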
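import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dexsea.diffexpr import DesignError
from dexsea.gsea import (
    NullDistribution,
    RankedList,
    _es_from_hit_positions,
    enrichment_score,
    gsea_fdr,
    leading_edge_overlap,
    normalized_es,
    permutation_p,
    run_gsea,
    sample_null,
    signal_to_noise,
)
from dexsea.io import filter_sets_by_size
from dexsea.simulate import PlantedSet, SimulationConfig, simulate_experiment

from conftest import make_design, make_matrix


def ranked(genes, metric=None) -> RankedList:
    if metric is None:
        metric = np.arange(len(genes), 0, -1, dtype=float)
    return RankedList(gene_ids=list(genes), metric=np.asarray(metric, float))


def brute_force_es(n: int, hit_mask: np.ndarray):
    """Prefix-sum oracle: walk the list, track every partial sum."""
    nh = hit_mask.sum()
    total = 0.0
    sums = []
    for h in hit_mask:
        total += 1.0 / nh if h else -1.0 / (n - nh)
        sums.append(total)
    sums = np.array(sums)
    hi, lo = sums.max(), sums.min()
    es = hi if hi >= -lo else lo
    return es, sums


class TestSignalToNoise:
    def make(self, tg_rows, wt_rows):
        """One tissue (cerebellum) with 2 transgenic and 2 wildtype samples."""
        design = make_design(2)
        values = np.zeros((len(tg_rows), 8))
        ce_tg = [i for i, s in enumerate(design.sample_ids) if s.startswith("ce_tr")]
        ce_wt = [i for i, s in enumerate(design.sample_ids) if s.startswith("ce_wi")]
        for r, (tg, wt) in enumerate(zip(tg_rows, wt_rows)):
            values[r, ce_tg] = tg
            values[r, ce_wt] = wt
        return make_matrix(values, design), design

    def test_hand_example(self):
        matrix, design = self.make([[2, 4]], [[1, 3]])
        rl = signal_to_noise(matrix, design, "cerebellum")
        assert rl.metric[0] == pytest.approx(1 / (2 * np.sqrt(2)), abs=1e-5)
        assert rl.metric[0] == pytest.approx(0.35355, abs=1e-5)

    def test_identical_groups_score_zero(self):
        matrix, design = self.make([[3, 5]], [[3, 5]])
        rl = signal_to_noise(matrix, design, "cerebellum")
        assert rl.metric[0] == 0.0

    def test_sd_floor_on_constant_groups(self):
        # sds are 0, floored at 0.2*|mean|: (5-3)/(1.0+0.6) = 1.25
        matrix, design = self.make([[5, 5]], [[3, 3]])
        rl = signal_to_noise(matrix, design, "cerebellum")
        assert rl.metric[0] == pytest.approx(1.25)

    def test_descending_order_and_stable_ties(self, rng):
        matrix, design = self.make([[5, 5], [3, 3], [5, 5]],
                                   [[3, 3], [5, 5], [3, 3]])
        rl = signal_to_noise(matrix, design, "cerebellum")
        assert (np.diff(rl.metric) <= 1e-12).all()
        # the two tied top genes keep input order
        assert rl.gene_ids[:2] == ["G0001", "G0003"]

    def test_too_few_samples_per_group(self):
        design = make_design(1)
        values = np.zeros((2, 4))
        with pytest.raises(DesignError, match="cerebellum"):
            signal_to_noise(make_matrix(values, design), design, "cerebellum")


class TestEnrichmentScore:
    def test_top_members(self):
        es, le, running = enrichment_score(ranked("abcde"), {"a", "b"})
        np.testing.assert_allclose(running, [0.5, 1.0, 2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        assert es == pytest.approx(1.0) and le == ["a", "b"]

    def test_bottom_members_negative(self):
        es, le, _ = enrichment_score(ranked("abcde"), {"d", "e"})
        assert es == pytest.approx(-1.0)
        assert le == ["e", "d"]

    def test_split_members(self):
        es, le, _ = enrichment_score(ranked("abcde"), {"a", "d"})
        assert es == pytest.approx(0.5) and le == ["a"]

    def test_no_members_or_all_members_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(ranked("abcde"), {"z"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked("abc"), {"a", "b", "c"})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(3, 50), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_conserves(self, n, seed):
        rng = np.random.default_rng(seed)
        nh = int(rng.integers(1, n))
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, nh, replace=False)] = True
        genes = [f"g{i}" for i in range(n)]
        members = {g for g, h in zip(genes, hits) if h}
        es, _, running = enrichment_score(ranked(genes), members)
        es_ref, sums_ref = brute_force_es(n, hits)
        assert abs(es - es_ref) < 1e-12
        np.testing.assert_allclose(running, sums_ref, atol=1e-12)
        assert abs(running[-1]) < 1e-12

    def test_depends_only_on_order(self):
        genes = "abcdef"
        es1, *_ = enrichment_score(ranked(genes, [9, 5, 4, 3, 2, 1]), {"b", "c"})
        es2, *_ = enrichment_score(ranked(genes, [0.6, 0.5, 0.1, 0, -1, -2]),
                                   {"b", "c"})
        assert es1 == es2

    def test_antisymmetry_under_list_reversal(self, rng):
        genes = [f"g{i}" for i in range(30)]
        members = set(rng.choice(genes, 8, replace=False))
        es_fwd, le_fwd, _ = enrichment_score(ranked(genes), members)
        es_rev, le_rev, _ = enrichment_score(ranked(genes[::-1]), members)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)
        assert le_rev == le_fwd

    def test_vectorized_null_kernel_matches_exact_walk(self, rng):
        """The closed-form hit-position ES equals the explicit running sum."""
        n = 200
        genes = [f"g{i}" for i in range(n)]
        for s in (1, 7, 50, 199):
            pos = np.sort(rng.choice(n, size=s, replace=False))
            vec = _es_from_hit_positions((pos + 1)[None, :], n)[0]
            members = {genes[i] for i in pos}
            exact, _, _ = enrichment_score(ranked(genes), members)
            assert vec == pytest.approx(exact, abs=1e-12)


class TestNullAndP:
    def test_same_seed_reproducible(self):
        rl = ranked([f"g{i}" for i in range(100)])
        n1 = sample_null(rl, 10, n_draws=200, seed=5)
        n2 = sample_null(rl, 10, n_draws=200, seed=5)
        np.testing.assert_array_equal(n1.null_es, n2.null_es)

    def test_null_distribution_symmetric_under_random_sets(self):
        rl = ranked([f"g{i}" for i in range(500)])
        null = sample_null(rl, 20, n_draws=2000, seed=3)
        assert abs(null.null_es.mean()) < 3 * null.null_es.std() / np.sqrt(2000)

    def test_complement_boundary_has_few_distinct_values(self):
        rl = ranked([f"g{i}" for i in range(20)])
        null = sample_null(rl, 19, n_draws=500, seed=1)
        assert len(np.unique(null.null_es)) <= 20

    def test_set_size_out_of_range(self):
        rl = ranked("abc")
        with pytest.raises(ValueError, match="set_size"):
            sample_null(rl, 3, n_draws=10, seed=0)

    def test_permutation_floor_and_brute_force(self, rng):
        null = NullDistribution(10, 2000, rng.normal(0, 0.2, 2000))
        assert permutation_p(5.0, null) == 0.0005
        assert permutation_p(-5.0, null) == 0.0005
        for es in rng.normal(0, 0.3, size=20):
            expected = max(int((np.abs(null.null_es) >= abs(es)).sum()), 1)
            assert permutation_p(es, null) == pytest.approx(expected / 2000,
                                                            abs=1e-15)

    def test_permutation_p_uniform_for_random_sets(self):
        """A random set's p against the random-set null is KS-uniform."""
        rl = ranked([f"g{i}" for i in range(400)])
        null = sample_null(rl, 25, n_draws=2000, seed=8)
        probe = sample_null(rl, 25, n_draws=500, seed=9)
        pvals = np.array([permutation_p(es, null) for es in probe.null_es])
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").statistic < 0.08

    def test_median_es_gives_half(self, rng):
        null = NullDistribution(10, 1000, np.abs(rng.normal(size=1000)))
        med = float(np.median(null.null_es))
        assert permutation_p(med, null) == pytest.approx(0.5, abs=0.01)

    def test_zero_es_and_empty_null(self):
        null = NullDistribution(5, 10, np.ones(10))
        assert permutation_p(0.0, null) == 1.0
        with pytest.raises(ValueError, match="empty"):
            permutation_p(1.0, NullDistribution(5, 0, np.array([])))


class TestNes:
    def test_direct_rule(self):
        null = NullDistribution(5, 4, np.array([0.4, 0.4, -0.5, -0.1]))
        assert normalized_es(0.8, null) == pytest.approx(2.0)
        assert normalized_es(-0.6, null) == pytest.approx(-2.0)

    def test_zero_es(self):
        null = NullDistribution(5, 2, np.array([0.5, -0.5]))
        assert normalized_es(0.0, null) == 0.0

    def test_no_same_sign_null_rejected(self):
        null = NullDistribution(5, 2, np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="same-sign"):
            normalized_es(-0.3, null)

    def test_negating_metric_negates_nes(self, rng):
        genes = [f"g{i}" for i in range(100)]
        members = set(rng.choice(genes, 15, replace=False))
        rl_fwd = ranked(genes)
        rl_rev = ranked(genes[::-1])
        es_f, *_ = enrichment_score(rl_fwd, members)
        es_r, *_ = enrichment_score(rl_rev, members)
        null_f = sample_null(rl_fwd, 15, n_draws=1000, seed=9)
        # a symmetric null: use the mirrored draws for the reversed list
        null_r = NullDistribution(15, 1000, -null_f.null_es)
        assert normalized_es(es_r, null_r) == pytest.approx(
            -normalized_es(es_f, null_f), abs=1e-12
        )


def brute_force_gsea_fdr(nes_obs, nulls):
    """Double-counting oracle for the pooled-null FDR."""
    pooled = []
    for nd in nulls:
        es = nd.null_es
        pos_mean = np.abs(es[es > 0]).mean() if (es > 0).any() else None
        neg_mean = np.abs(es[es < 0]).mean() if (es < 0).any() else None
        for v in es:
            if v > 0:
                pooled.append(v / pos_mean)
            elif v < 0:
                pooled.append(v / neg_mean)
            else:
                pooled.append(0.0)
    pooled = np.array(pooled)
    raw = np.ones(len(nes_obs))
    for i, x in enumerate(nes_obs):
        if x == 0:
            continue
        side_null = pooled[pooled > 0] if x > 0 else pooled[pooled < 0]
        side_obs = np.array([y for y in nes_obs if y * np.sign(x) > 0])
        num = (np.abs(side_null) >= abs(x)).mean() if side_null.size else 0.0
        den = (np.abs(side_obs) >= abs(x)).mean()
        raw[i] = min(num / den, 1.0)
    # monotone within sign: take the best raw estimate among equally or less
    # extreme sets, so q never increases with |NES|
    q = raw.copy()
    for i, x in enumerate(nes_obs):
        if x == 0:
            continue
        for j, y in enumerate(nes_obs):
            if np.sign(y) == np.sign(x) and abs(y) <= abs(x):
                q[i] = min(q[i], raw[j])
    return q


class TestGseaFdr:
    def test_matches_brute_force_oracle(self, rng):
        nulls = [NullDistribution(10, 200, rng.normal(0, 0.3, 200))
                 for _ in range(5)]
        nes_obs = np.array([2.5, -1.8, 0.4, -0.2, 1.1])
        np.testing.assert_allclose(
            gsea_fdr(nes_obs, nulls),
            brute_force_gsea_fdr(nes_obs, nulls),
            atol=1e-12,
        )

    def test_extreme_nes_gets_zero_q(self, rng):
        nulls = [NullDistribution(10, 200, rng.normal(0, 0.3, 200))]
        q = gsea_fdr(np.array([50.0]), nulls)
        assert q[0] == 0.0

    def test_null_observations_have_large_median_q(self, rng):
        """NES drawn from the null itself should not look discovered."""
        medians = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            null_es = r.normal(0, 0.3, 500)
            nulls = [NullDistribution(10, 500, null_es)]
            pos_mean = np.abs(null_es[null_es > 0]).mean()
            neg_mean = np.abs(null_es[null_es < 0]).mean()
            obs_es = r.normal(0, 0.3, 20)
            nes = np.where(obs_es > 0, obs_es / pos_mean, obs_es / neg_mean)
            medians.append(np.median(gsea_fdr(nes, nulls)))
        assert np.median(medians) > 0.6


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(
        n_genes=800, n_per_cell=5, n_de_genes=0, noise_sd=0.5,
        planted_sets=[PlantedSet("PLANTED", 40, 1.5, "up")],
        n_background_sets=10, set_size_range=(15, 200), seed=13,
    )
    matrix, design, collection, _ = simulate_experiment(cfg)
    log2 = matrix.to_log2()
    filtered = filter_sets_by_size(collection, log2.gene_ids, 15, 500)
    return log2, design, filtered


class TestRunGsea:
    def test_planted_set_dominates(self, planted):
        log2, design, filtered = planted
        res = run_gsea(log2, design, "cerebellum", filtered,
                       n_draws=2000, seed=2)
        assert res["nes"].abs().idxmax() == "PLANTED"
        assert res.loc["PLANTED", "perm_p"] == 0.0005
        assert res.loc["PLANTED", "fdr_q"] <= 0.05

    def test_deterministic_given_seed(self, planted):
        log2, design, filtered = planted
        res1 = run_gsea(log2, design, "blood", filtered, n_draws=300, seed=4)
        res2 = run_gsea(log2, design, "blood", filtered, n_draws=300, seed=4)
        pd.testing.assert_frame_equal(res1, res2)

    def test_leading_edge_subset_of_members(self, planted):
        log2, design, filtered = planted
        res = run_gsea(log2, design, "cerebellum", filtered,
                       n_draws=200, seed=6)
        for name in res.index:
            le = [g for g in res.loc[name, "leading_edge"].split(",") if g]
            assert set(le) <= set(filtered.members(name))
            assert res.loc[name, "size"] == len(filtered.members(name))
            assert abs(res.loc[name, "es"]) <= 1.0
            assert np.sign(res.loc[name, "nes"]) == np.sign(res.loc[name, "es"])


class TestLeadingEdgeOverlap:
    def frame(self, le):
        return pd.DataFrame({"leading_edge": [",".join(le)]},
                            index=pd.Index(["S"], name="name"))

    def test_identical_results(self):
        res = self.frame(["g1", "g3"])
        assert leading_edge_overlap(res, res, "S") == ["g1", "g3"]

    def test_disjoint_and_ordered_intersection(self):
        a = self.frame(["g1", "g3", "g5"])
        b = self.frame(["g5", "g2", "g3"])
        assert leading_edge_overlap(a, b, "S") == ["g3", "g5"]
        assert leading_edge_overlap(a, self.frame(["g7"]), "S") == []

    def test_missing_set_rejected(self):
        a = self.frame(["g1"])
        with pytest.raises(KeyError, match="MISSING"):
            leading_edge_overlap(a, a, "MISSING")
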
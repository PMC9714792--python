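"""QC rules, normalization, marker statistics, scores, proportions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pavasc import sc_qc_stats
from pavasc.sc_qc_stats import (
    QCThresholds,
    cell_cycle_phase,
    find_markers,
    fisher_enrichment,
    log2fc,
    lognormalize,
    proportion_test,
    qc_filter,
    rank_sum_test,
    signature_score,
)
from conftest import make_norm_adata


def _counts_adata(rows, gene_names):
    import anndata

    X = np.asarray(rows, dtype=np.int32)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["mt"] = [g.startswith("MT-") for g in gene_names]
    return anndata.AnnData(X=X, obs=obs, var=var)


class TestQCFilter:
    def test_mito_rule_boundary(self):
        # 6% mito removed, 4% kept; plenty of detected genes so only the
        # mito rule can trigger
        genes = ["MT-a"] + [f"g{i}" for i in range(300)]
        rows = []
        for mito_pct in (4, 6, 4, 4, 4):
            mito = mito_pct
            rest = 100 - mito
            # spread `rest` counts over 300 genes: all genes detected once,
            # so detected-gene counts are equal across cells
            row = [mito] + [1] * (rest) + [0] * (300 - rest)
            rows.append(row)
        adata = _counts_adata(rows, genes)
        kept, report = qc_filter(adata, QCThresholds(min_genes=0))
        assert report.loc["c1", "removed"] and report.loc["c1", "reason"] == "mito"
        assert not report.loc["c0", "removed"]
        assert len(kept) == 4

    def test_low_gene_rule_boundary(self):
        genes = [f"g{i}" for i in range(300)]
        rows = [[1] * 199 + [0] * 101, [1] * 200 + [0] * 100,
                [1] * 250 + [0] * 50, [1] * 220 + [0] * 80]
        adata = _counts_adata(rows, genes)
        with pytest.warns(UserWarning, match="no mitochondrial genes"):
            kept, report = qc_filter(adata, QCThresholds(mad_multiplier=100))
        assert report.loc["c0", "reason"] == "low_genes"
        assert "c0" not in kept and len(kept) == 3

    def test_mad_upper_bound_hand_computed(self):
        # five cells each detecting 300 genes: median 300, MAD 0,
        # cutoff 300 + 3*0 = 300 -> none removed by the upper rule
        genes = [f"g{i}" for i in range(400)]
        rows = [[1] * 300 + [0] * 100] * 5
        adata = _counts_adata(rows, genes)
        with pytest.warns(UserWarning):
            kept, report = qc_filter(adata, QCThresholds(min_genes=0))
        assert (report["gene_upper_bound"] == 300).all()
        assert len(kept) == 5

    def test_near_idempotent_on_simulated_data(self, small_sim):
        # the mito and low-gene rules are exactly idempotent; the MAD upper
        # bound is recomputed on the kept cells, so a second pass may clip a
        # sliver of the new upper tail — it must stay below 1% of cells
        _, adata, _ = small_sim
        thr = QCThresholds(min_genes=50)
        kept, report = qc_filter(adata, thr, sample_key="sample")
        kept2, report2 = qc_filter(adata[kept].copy(), thr, sample_key="sample")
        assert set(kept2) <= set(kept)
        assert report2["removed"].sum() <= 0.01 * len(kept)
        assert not report2["reason"].str.contains("mito|low_genes").any()


class TestNormalize:
    def test_closed_forms(self):
        adata = _counts_adata([[1, 0, 9999]], [f"g{i}" for i in range(3)])
        norm = lognormalize(adata, scale=1e4)
        X = np.asarray(norm.X)
        assert X[0, 1] == 0.0
        assert np.isclose(X[0, 0], np.log(2.0))  # count 1, total == scale

    def test_cell_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, size=(4, 30))
        doubled = counts.copy()
        doubled[2] *= 2
        g = [f"g{i}" for i in range(30)]
        n1 = np.asarray(lognormalize(_counts_adata(counts, g)).X)
        n2 = np.asarray(lognormalize(_counts_adata(doubled, g)).X)
        assert np.allclose(n1[2], n2[2])

    def test_zero_cells_dropped_with_warning(self):
        adata = _counts_adata([[1, 2], [0, 0]], ["g0", "g1"])
        with pytest.warns(UserWarning, match="zero-count"):
            norm = lognormalize(adata)
        assert norm.n_obs == 1


class TestLog2FC:
    def test_identical_groups_zero(self):
        assert log2fc([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_closed_form(self):
        # de-logged means 3 and 1, pseudocount 1 -> log2(4/2) = 1
        a = np.log1p([3.0, 3.0])
        b = np.log1p([1.0, 1.0])
        assert np.isclose(log2fc(a, b, pseudocount=1.0), 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0, 6), min_size=2, max_size=8),
        st.lists(st.floats(0, 6), min_size=2, max_size=8),
    )
    def test_antisymmetry(self, a, b):
        assert np.isclose(log2fc(a, b), -log2fc(b, a), atol=1e-10)


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        count += abs(w - mu) >= abs(obs - mu) - 1e-12
        total += 1
    return count / total


class TestRankSum:
    def test_no_tie_exact_example(self):
        assert np.isclose(rank_sum_test([1, 2, 3], [4, 5, 6]), 0.1)

    def test_all_ties_p_one(self):
        assert rank_sum_test([5, 5, 5], [5, 5, 5]) == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 4), (4, 4), (3, 5)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert np.isclose(rank_sum_test(x, y), exact_ranksum_p(x, y))

    def test_vectorized_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, size=(60, 40)).astype(float)
        grp = np.zeros(60, dtype=bool)
        grp[:26] = True
        p_vec = sc_qc_stats._wilcoxon_vectorized(X, grp)
        for j in range(40):
            ref = stats.mannwhitneyu(
                X[grp, j], X[~grp, j], method="asymptotic", use_continuity=False
            ).pvalue
            assert np.isclose(p_vec[j], ref, atol=1e-12)


class TestFindMarkers:
    def test_recovers_planted_markers(self, small_sim, small_norm):
        _, _, truth = small_sim
        found = find_markers(small_norm, "pop00")
        sig = set(found.loc[found["significant"], "gene"])
        planted = set(truth.marker_genes["pop00"])
        assert len(planted & sig) / len(planted) >= 0.9

    def test_min_pct_excludes_rare_genes(self):
        rng = np.random.default_rng(0)
        X = np.zeros((40, 2))
        # gene 0 expressed in 10% of both groups; gene 1 everywhere
        X[::10, 0] = 5.0
        X[:, 1] = rng.uniform(1, 2, 40)
        labels = ["A"] * 20 + ["B"] * 20
        adata = make_norm_adata(X, labels=labels)
        out = find_markers(adata, "A", min_pct=0.25, lfc_min=0.0)
        assert "g0" not in set(out["gene"])

    def test_degenerate_group_errors(self):
        adata = make_norm_adata(np.ones((5, 3)), labels=["A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match=">= 3 cells"):
            find_markers(adata, "A")

    def test_bonferroni_and_ordering(self, small_norm):
        out = find_markers(small_norm, "pop01")
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        assert list(out["p_adj"]) == sorted(out["p_adj"])


class TestSignatureScore:
    def test_identical_expression_scores_zero(self):
        adata = make_norm_adata(np.full((10, 50), 2.0))
        s = signature_score(adata, ["g1", "g2", "g3"], seed=0)
        assert np.allclose(s, 0.0)

    def test_planted_shift_recovered(self):
        # 4 discrete expression levels, bins aligned with levels, so the
        # matched controls share the signature genes' baseline exactly
        rng = np.random.default_rng(0)
        n_cells, per_level = 200, 125
        means = np.repeat([1.0, 2.0, 3.0, 4.0], per_level)
        X = rng.normal(means, 0.1, size=(n_cells, 4 * per_level))
        sig = [f"g{j}" for j in (10, 140, 260, 390, 20, 150, 270, 395)]
        in_pop = np.zeros(n_cells, dtype=bool)
        in_pop[:40] = True
        delta = 0.5
        for g in sig:
            X[in_pop, int(g[1:])] += delta
        adata = make_norm_adata(X)
        s = signature_score(adata, sig, n_bins=4, seed=1)
        assert abs(s[in_pop].mean() - delta) < 0.05
        assert abs(s[~in_pop].mean()) < 0.05

    def test_seed_determinism_and_missing_gene_invariance(self, small_norm):
        sig = list(small_norm.var_names[:10])
        s1 = signature_score(small_norm, sig, seed=3)
        s2 = signature_score(small_norm, sig, seed=3)
        assert np.array_equal(s1, s2)
        with pytest.warns(UserWarning, match="not in matrix"):
            s3 = signature_score(small_norm, sig + ["NOT_A_GENE"], seed=3)
        assert np.array_equal(s1, s3)

    def test_empty_intersection_errors(self, small_norm):
        with pytest.raises(ValueError, match="missing"):
            signature_score(small_norm, ["NOPE1", "NOPE2"])


class TestCellCycle:
    def test_phase_rules(self):
        # engineered scores via two marker genes on flat background
        X = np.full((3, 40), 1.0)
        X[0, 0] = 0.0  # S gene low, G2M gene low -> G1
        X[0, 1] = 0.0
        X[1, 0] = 3.0  # S score larger -> S
        X[2, 1] = 3.0  # G2M larger -> G2M
        adata = make_norm_adata(X)
        out = cell_cycle_phase(adata, ["g0"], ["g1"], seed=0)
        assert list(out["phase"]) == ["G1", "S", "G2M"]

    def test_planted_s_population_called_s(self):
        # spread baseline means so expression bins hold many genes and the
        # control draw is not degenerate
        rng = np.random.default_rng(2)
        means = rng.uniform(0.5, 1.5, size=400)
        X = rng.normal(means, 0.1, size=(60, 400))
        s_genes = [f"g{j}" for j in range(5)]
        g2m_genes = [f"g{j}" for j in range(5, 10)]
        X[:30, :5] += 1.0  # S program on in first half
        adata = make_norm_adata(X)
        out = cell_cycle_phase(adata, s_genes, g2m_genes, seed=0)
        assert (out["phase"][:30] == "S").mean() > 0.5
        assert (out["phase"][30:] == "S").mean() < 0.1


class TestProportionTest:
    def _meta(self, props_a, props_b, n=100):
        rows = []
        for cond, props in (("donor", props_a), ("PAH", props_b)):
            for i, p in enumerate(props):
                k = int(round(p * n))
                for j in range(n):
                    rows.append(
                        (f"{cond}_{i}", cond, "target" if j < k else "other")
                    )
        return pd.DataFrame(rows, columns=["sample", "condition", "population"])

    def test_identical_proportions_give_t0_p1(self):
        meta = self._meta([0.2, 0.2], [0.2, 0.2])
        res = proportion_test(meta, "target")
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_closed_form_pooled_t(self):
        a = [0.10, 0.12, 0.11]
        b = [0.30, 0.28, 0.32]
        res = proportion_test(self._meta(a, b), "target")
        ta = np.arcsin(np.sqrt(a))
        tb = np.arcsin(np.sqrt(b))
        sp2 = (np.var(ta, ddof=1) * 2 + np.var(tb, ddof=1) * 2) / 4
        t_stat = (ta.mean() - tb.mean()) / math.sqrt(sp2 * (2 / 3))
        p_ref = 2 * stats.t.sf(abs(t_stat), df=4)
        assert np.isclose(res.t, t_stat)
        assert np.isclose(res.p, p_ref)

    def test_transform_endpoints(self):
        assert np.arcsin(np.sqrt(0.0)) == 0.0
        res = proportion_test(self._meta([1.0, 1.0], [0.0, 0.0]), "target")
        assert res.p < 1e-6  # pi/2 vs 0, zero within-group variance...

    def test_single_sample_condition_errors(self):
        meta = self._meta([0.1, 0.1], [0.3, 0.3])
        meta = meta[meta["sample"] != "PAH_1"]
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            proportion_test(meta, "target")

    def test_null_pvalues_approximately_uniform(self):
        # binomial sampling of per-sample proportions under equal truth
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            rows = []
            for cond in ("donor", "PAH"):
                for i in range(3):
                    k = rng.binomial(200, 0.25)
                    rows += [(f"{cond}_{i}", cond, "target")] * k
                    rows += [(f"{cond}_{i}", cond, "other")] * (200 - k)
            meta = pd.DataFrame(rows, columns=["sample", "condition", "population"])
            ps.append(proportion_test(meta, "target").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFisherEnrichment:
    def test_query_equal_to_set_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:10]
        out = fisher_enrichment(query, {"s": query}, universe)
        # oracle: hypergeometric point mass of drawing all 10 in 10 draws
        p_min = 1.0 / math.comb(20, 10)
        assert np.isclose(out.loc[0, "p"], p_min)

    def test_disjoint_query_not_significant(self):
        universe = [f"g{i}" for i in range(40)]
        out = fisher_enrichment(
            universe[:10], {"s1": universe[20:30], "s2": universe[30:40]}, universe
        )
        assert not out["significant"].any()

    def test_table_matches_hypergeometric_tail(self):
        # 2x2 table (5,5 / 5,85): universe 100, query 10, set 10, overlap 5
        universe = [f"g{i}" for i in range(100)]
        query = universe[:10]
        geneset = universe[5:15]  # overlap 5
        out = fisher_enrichment(query, {"s": geneset}, universe)
        tail = sum(
            math.comb(10, k) * math.comb(90, 10 - k) for k in range(5, 11)
        ) / math.comb(100, 10)
        assert np.isclose(out.loc[0, "p"], tail)

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment(["x"], {"s": ["a"]}, ["a", "b"])
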
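"""Variable genes, clustering, mixed-model DE, ssGSEA, classification."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chordomics.stats import bh_adjust
from chordomics.geomx_analysis import (
    ClusterAssignment,
    classify_samples,
    cluster_segments,
    compare_segment_features,
    differential_pathways,
    embed_umap,
    lmm_de,
    select_variable_genes,
    ssgsea,
)


def ssgsea_oracle(values, member_set, universe, alpha=0.25):
    """Literal running-sum evaluation of the ssGSEA score for one sample:
    walk the descending-ranked gene list, accumulating the weighted in-set
    ECDF minus the uniform out-of-set ECDF."""
    order = sorted(range(len(universe)), key=lambda i: (-values[i], i))
    n = len(universe)
    in_set = [universe[i] in member_set for i in order]
    rank_stat = list(range(n, 0, -1))
    denom = sum(abs(rank_stat[p]) ** alpha for p in range(n) if in_set[p])
    n_out = n - sum(in_set)
    score, pin, pout = 0.0, 0.0, 0.0
    for p in range(n):
        if in_set[p]:
            pin += abs(rank_stat[p]) ** alpha / denom
        else:
            pout += 1.0 / n_out
        score += pin - pout
    return score


class TestVariableGenes:
    def test_counts_and_bounds(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(50, 4)),
                            index=[f"g{i}" for i in range(50)])
        assert len(select_variable_genes(expr, 0.20)) == 10
        assert len(select_variable_genes(expr, 1.0)) == 50
        with pytest.raises(ValueError):
            select_variable_genes(expr, 0.0)

    def test_top2_matches_bruteforce_on_toy(self):
        expr = pd.DataFrame(
            [[0, 0, 0], [1, 5, 9], [2, 2, 3], [0, 9, 0], [4, 4, 4]],
            index=list("abcde"), dtype=float,
        )
        top2 = select_variable_genes(expr, 0.4)
        brute = sorted(expr.index, key=lambda g: -expr.loc[g].var(ddof=1))[:2]
        assert top2 == brute


class TestClusterSegments:
    @staticmethod
    def _two_blobs(n_per=12, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (20, n_per))
        b = rng.normal(sep, 1, (20, n_per))
        expr = pd.DataFrame(np.hstack([a, b]),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(2 * n_per)])
        truth = np.r_[np.zeros(n_per), np.ones(n_per)]
        return expr, truth

    def test_separated_blobs_recovered_exactly(self):
        expr, truth = self._two_blobs()
        ca = cluster_segments(expr, 2, seed=0, markers=["g0"])
        assert adjusted_rand_score(truth, ca.segment_cluster.values) == 1.0

    def test_marker_naming(self):
        expr, truth = self._two_blobs()
        ca = cluster_segments(expr, 2, seed=0, markers=["g0"])
        hot = ca.segment_label[truth == 1].unique()
        assert list(hot) == ["inflamed"]  # blob with higher g0 expression

    def test_duplicates_co_cluster(self):
        expr, _ = self._two_blobs(n_per=8)
        dup = pd.concat([expr, expr.add_suffix("_dup", axis=1)], axis=1)
        ca = cluster_segments(dup, 2, seed=1, markers=["g0"])
        for s in expr.columns:
            assert ca.segment_cluster[s] == ca.segment_cluster[s + "_dup"]

    def test_single_community_target(self):
        expr, _ = self._two_blobs(n_per=6)
        ca = cluster_segments(expr, 1, seed=0)
        assert ca.segment_cluster.nunique() == 1


class TestUmap:
    def test_deterministic_and_shaped(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(30, 12)),
                            columns=[f"s{i}" for i in range(12)])
        e1 = embed_umap(expr, seed=11)
        e2 = embed_umap(expr, seed=11)
        assert e1.shape == (12, 2) and np.isfinite(e1.values).all()
        pd.testing.assert_frame_equal(e1, e2)


def _lmm_sim(n_samples=10, seg_per=6, n_genes=50, effect=0.0, sample_sd=0.3,
             noise_sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    n = n_samples * seg_per
    sample = np.repeat([f"S{i}" for i in range(n_samples)], seg_per)
    group = np.tile(["A", "B"], n // 2)
    segs = [f"seg{i}" for i in range(n)]
    eff = rng.normal(0, sample_sd, n_samples)
    Y = (eff[np.repeat(np.arange(n_samples), seg_per)][None, :]
         + rng.normal(0, noise_sd, (n_genes, n))
         + effect * (group == "B")[None, :])
    expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)], columns=segs)
    return expr, pd.Series(group, index=segs), pd.Series(sample, index=segs)


class TestLmmDe:
    def test_constant_genes_are_null(self):
        expr, grp, smp = _lmm_sim(n_genes=3, noise_sd=0.0, sample_sd=0.0, seed=1)
        de = lmm_de(expr, grp, smp)
        assert (de.log2FC == 0).all() and (de.p == 1).all()

    def test_effect_recovery_within_tolerance(self):
        expr, grp, smp = _lmm_sim(n_genes=100, effect=1.0, seed=2)
        de = lmm_de(expr, grp, smp)
        assert de.log2FC.mean() == pytest.approx(1.0, abs=0.15)

    def test_reduces_to_pooled_ols_without_random_effect(self):
        import statsmodels.api as sm

        expr, grp, smp = _lmm_sim(n_genes=10, sample_sd=0.0, seed=3)
        de = lmm_de(expr, grp, smp).set_index("feature")
        x = sm.add_constant((grp == "B").astype(float).values)
        for g in expr.index:
            beta = sm.OLS(expr.loc[g].values, x).fit().params[1]
            assert de.loc[g, "log2FC"] == pytest.approx(beta, abs=1e-6)

    def test_agrees_with_lme4_reference_fit(self):
        """Independent cross-check of one fit against R lme4 (REML)."""
        expr, grp, smp = _lmm_sim(n_genes=1, effect=0.7, seed=4)
        de = lmm_de(expr, grp, smp)
        df = pd.DataFrame(dict(y=expr.iloc[0].values,
                               g=(grp == "B").astype(int).values,
                               s=smp.values))
        csv = df.to_csv(index=False)
        r_code = (
            "suppressMessages(library(lme4));"
            "d <- read.csv('stdin');"
            "m <- lmer(y ~ g + (1|s), data=d, REML=TRUE);"
            "cat(fixef(m)['g'], sqrt(vcov(m)['g','g']), sep=',')"
        )
        res = subprocess.run(["Rscript", "-e", r_code], input=csv,
                             capture_output=True, text=True, check=True)
        coef_r, se_r = map(float, res.stdout.strip().split(","))
        assert de.log2FC.iloc[0] == pytest.approx(coef_r, abs=1e-4)

    def test_bh_invariants(self):
        expr, grp, smp = _lmm_sim(n_genes=40, seed=5)
        de = lmm_de(expr, grp, smp)
        assert (de.q >= de.p - 1e-12).all() and (de.q <= 1).all()
        srt = de.sort_values("p")
        assert (np.diff(srt.q.values) >= -1e-12).all()


class TestSsgsea:
    def test_identical_segments_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=12)
        expr = pd.DataFrame({"s1": col, "s2": col},
                            index=[f"g{i}" for i in range(12)])
        sc = ssgsea(expr, {"pw": ["g1", "g5", "g9"]})
        assert sc["s1"].values == pytest.approx(sc["s2"].values)

    def test_toy_matches_running_sum_oracle(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame({"s": rng.normal(size=10)}, index=universe)
        members = ["g2", "g5", "g7"]
        sc = ssgsea(expr, {"pw": members})
        expect = ssgsea_oracle(expr["s"].values, set(members), universe)
        assert sc.loc["pw", "s"] == pytest.approx(expect, abs=1e-10)

    def test_exhaustive_three_gene_sets_over_eight_genes(self):
        """Exact agreement with the brute-force oracle for every 3-gene set
        over an 8-gene universe."""
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame({"s": rng.normal(size=8)}, index=universe)
        for combo in itertools.combinations(universe, 3):
            sc = ssgsea(expr, {"pw": list(combo)})
            expect = ssgsea_oracle(expr["s"].values, set(combo), universe)
            assert sc.loc["pw", "s"] == pytest.approx(expect, abs=1e-12)

    def test_raising_in_set_genes_never_lowers_score(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(15)]
        base = pd.Series(rng.normal(size=15), index=universe)
        members = ["g3", "g8", "g12"]
        lo = ssgsea(pd.DataFrame({"s": base}), {"pw": members}).loc["pw", "s"]
        boosted = base.copy()
        boosted[members] += 5.0
        hi = ssgsea(pd.DataFrame({"s": boosted}), {"pw": members}).loc["pw", "s"]
        assert hi >= lo

    def test_empty_intersection_dropped_with_warning(self):
        expr = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="dropped"):
            sc = ssgsea(expr, {"gone": ["x", "y"], "ok": ["a"]})
        assert list(sc.index) == ["ok"]


class TestDifferentialPathways:
    def test_top_fraction_count(self):
        expr, grp, smp = _lmm_sim(n_genes=30, seed=6)
        top = differential_pathways(expr, grp, smp, top_frac=0.10)
        assert len(top) == 3
        assert len(differential_pathways(expr, grp, smp, top_frac=1.0)) == 30

    def test_planted_active_pathways_rank_first(self):
        """5 pathway scores with a planted group shift among 50 null ones
        all land in the top 10 by adjusted p."""
        expr, grp, smp = _lmm_sim(n_genes=50, seed=8, noise_sd=0.3)
        active = [f"g{i}" for i in range(5)]
        expr.loc[active] += 1.5 * (grp == "B").astype(float).values[None, :]
        top = differential_pathways(expr, grp, smp, top_frac=0.2)
        assert set(active) <= set(top.feature)


class TestClassifySamples:
    @staticmethod
    def _assignment(labels):
        segs = [f"seg{i}" for i in range(len(labels))]
        cl = pd.Series([0 if l == "inflamed" else 1 for l in labels], index=segs)
        return ClusterAssignment(cl, {0: "inflamed", 1: "non-inflamed"}, 1.0), segs

    def test_majority_and_tie(self):
        ca, segs = self._assignment(["inflamed", "inflamed", "non-inflamed",
                                     "inflamed", "non-inflamed"])
        sample = pd.Series(["A", "A", "A", "B", "B"], index=segs)
        lab = classify_samples(ca, sample)
        assert lab["A"] == "inflamed" and lab["B"] == "tied"

    def test_homogeneous_samples(self):
        ca, segs = self._assignment(["non-inflamed"] * 4)
        sample = pd.Series(["A", "A", "B", "B"], index=segs)
        assert (classify_samples(ca, sample) == "non-inflamed").all()


class TestCompareSegmentFeatures:
    def test_identical_groups(self):
        vals = pd.Series([1.0, 2.0, 1.0, 2.0])
        grp = pd.Series(["a", "a", "b", "b"])
        t, p = compare_segment_features(vals, grp)
        assert t == 0.0 and p == 1.0

    def test_closed_form_oracle(self):
        """{1,2,3} vs {4,5,6}: pooled sd 1, t = -3/sqrt(2/3); p from the
        incomplete-beta form of the t distribution (df=4)."""
        from scipy.special import betainc

        vals = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        grp = pd.Series(list("aaabbb"))
        t, p = compare_segment_features(vals, grp)
        t_expect = -3.0 / np.sqrt(2.0 / 3.0)
        df = 4
        p_expect = betainc(df / 2, 0.5, df / (df + t_expect**2))
        assert t == pytest.approx(t_expect, abs=1e-10)
        assert p == pytest.approx(p_expect, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(size=12))
        grp = pd.Series(["a"] * 6 + ["b"] * 6)
        t1, _ = compare_segment_features(vals, grp)
        t2, _ = compare_segment_features(vals * 7.3, grp)
        assert t1 == pytest.approx(t2, abs=1e-12)


def test_bh_adjust_monotone_and_bounded():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=100)
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
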
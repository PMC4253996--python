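"""Tissue specificity, categorization, and correlation controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ricelnc.expression import (
    categorize,
    expression_summary,
    js_specificity,
    neighbor_correlation,
    specificity_table,
)


def manual_js_score(v):
    """Independent evaluation of 1 - sqrt(JSD(p, e_t)) maximized over t."""
    v = np.asarray(v, dtype=float)
    p = v / v.sum()

    def H(q):
        q = q[q > 0]
        return -(q * np.log2(q)).sum()

    best = -np.inf
    for t in range(len(p)):
        e = np.zeros(len(p))
        e[t] = 1.0
        m = (p + e) / 2
        jsd = H(m) - (H(p) + H(e)) / 2
        best = max(best, 1 - np.sqrt(max(jsd, 0.0)))
    return best


class TestJsSpecificity:
    def test_single_tissue_expression_scores_exactly_one(self):
        res = js_specificity([0, 5, 0], ["a", "b", "c"])
        assert res.js_score == 1.0
        assert res.tissue == "b"

    def test_two_tissue_uniform_value(self):
        # 1 - sqrt(JSD(uniform2, e_t)) = 0.4421 to 4 d.p.
        res = js_specificity([1.0, 1.0])
        assert res.js_score == pytest.approx(0.4421, abs=5e-5)

    def test_uniform_vector_symmetric_scores(self):
        res = js_specificity(np.ones(7))
        assert np.allclose(res.scores, res.scores[0])

    def test_scale_invariance(self, rng):
        for _ in range(50):
            v = rng.exponential(size=9) + 1e-9
            k = float(rng.uniform(0.1, 100))
            a = js_specificity(v)
            b = js_specificity(k * v)
            assert np.allclose(a.scores, b.scores, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        v = rng.exponential(size=8)
        perm = rng.permutation(8)
        a = js_specificity(v)
        b = js_specificity(v[perm])
        assert np.allclose(a.scores[perm], b.scores, atol=1e-12)

    def test_matches_independent_oracle_on_random_vectors(self, rng):
        for i in range(1000):
            T = int(rng.integers(2, 14))
            v = rng.exponential(size=T)
            if i % 3 == 0:  # sparse vectors exercise 0*log0
                v[rng.random(T) < 0.4] = 0.0
            if v.sum() == 0:
                continue
            got = js_specificity(v).js_score
            assert got == pytest.approx(manual_js_score(v), abs=1e-10)

    def test_scores_within_unit_interval(self, rng):
        for _ in range(200):
            v = rng.exponential(size=int(rng.integers(2, 10)))
            res = js_specificity(v)
            assert np.all(res.scores >= 0) and np.all(res.scores <= 1)

    def test_all_zero_vector_raises(self):
        with pytest.raises(ValueError):
            js_specificity([0.0, 0.0, 0.0])


class TestExpressionSummary:
    def make_fpkm(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2", "s3"]).astype(float)

    def test_identical_sets_equal_medians_p_near_one(self):
        fpkm = pd.DataFrame(
            np.abs(np.random.default_rng(0).normal(5, 1, size=(20, 4)))
        )
        fpkm.index = [f"t{i}" for i in range(20)]
        ids = list(fpkm.index)
        medians, tests = expression_summary({"a": ids, "b": ids}, fpkm)
        assert medians["a"] == medians["b"]
        assert tests["p_value"].iloc[0] > 0.9

    def test_shifted_sets_detected(self, rng):
        base = rng.lognormal(2, 0.5, size=(400, 5))
        fpkm = pd.DataFrame(
            np.vstack([base[:200], base[200:] * 2.0]),
            index=[f"t{i}" for i in range(400)],
        )
        a = [f"t{i}" for i in range(200)]
        b = [f"t{i}" for i in range(200, 400)]
        _, tests = expression_summary({"a": a, "b": b}, fpkm)
        assert tests["p_value"].iloc[0] < 0.01

    def test_median_of_three(self):
        fpkm = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]
        )
        medians, _ = expression_summary({"x": ["a", "b", "c"]}, fpkm)
        assert medians["x"] == 2.0

    def test_empty_set_raises(self):
        fpkm = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            expression_summary({"x": []}, fpkm)

    def test_ttest_flag(self, rng):
        fpkm = pd.DataFrame(
            rng.lognormal(1, 0.3, size=(60, 4)),
            index=[f"t{i}" for i in range(60)],
        )
        a = [f"t{i}" for i in range(30)]
        b = [f"t{i}" for i in range(30, 60)]
        _, tests = expression_summary({"a": a, "b": b}, fpkm, test="ttest")
        assert 0 <= tests["p_value"].iloc[0] <= 1


class TestCategorize:
    groups = {"reproductive": ["anther", "pistil"], "vegetative": ["leaf", "root"]}

    def make_fpkm(self, rows):
        return pd.DataFrame(
            rows, columns=["anther", "pistil", "leaf", "root", "extra"]
        ).astype(float)

    def test_anther_exclusive_is_reproductive(self):
        fpkm = self.make_fpkm({"t": [30, 0.1, 0.1, 0.1, 0.1]}.values())
        fpkm.index = ["t"]
        (c,) = categorize(["t"], fpkm, self.groups)
        assert (c.category, c.tissue) == ("reproductive", "anther")

    def test_uniform_expression_is_other(self):
        fpkm = self.make_fpkm([[5, 5, 5, 5, 5]])
        fpkm.index = ["t"]
        (c,) = categorize(["t"], fpkm, self.groups)
        assert c.category == "other"

    def test_sample_in_two_groups_raises(self):
        fpkm = self.make_fpkm([[1, 1, 1, 1, 1]])
        fpkm.index = ["t"]
        with pytest.raises(ValueError, match="two groups"):
            categorize(["t"], fpkm, {"a": ["anther"], "b": ["anther"]})

    def test_grouped_sample_missing_from_matrix_raises(self):
        fpkm = self.make_fpkm([[1, 1, 1, 1, 1]])
        fpkm.index = ["t"]
        with pytest.raises(KeyError):
            categorize(["t"], fpkm, {"a": ["nonexistent_tissue"]})

    def test_lowering_floor_moves_other_into_argmax_group_only(self):
        fpkm = self.make_fpkm([[3, 1, 1, 1, 0.1], [0.5, 0.4, 0.6, 0.5, 1]])
        fpkm.index = ["t1", "t2"]
        strict = {c.transcript_id: c for c in
                  categorize(["t1", "t2"], fpkm, self.groups, js_floor=0.5)}
        loose = {c.transcript_id: c for c in
                 categorize(["t1", "t2"], fpkm, self.groups, js_floor=0.0)}
        for tid in ("t1", "t2"):
            if strict[tid].category == "other":
                # moves exactly to its argmax tissue's group
                grp = ("reproductive"
                       if loose[tid].tissue in self.groups["reproductive"]
                       else "vegetative")
                assert loose[tid].category == grp
            else:
                assert loose[tid].category == strict[tid].category

    def test_planted_categories_recovered_exactly(self, bundle, identified):
        lnc, _ = identified
        cats = categorize(
            [t.id for t in lnc], bundle.fpkm, bundle.config.tissue_groups,
            bundle.config.js_floor,
        )
        for c in cats:
            assert c.category == bundle.truth.loc[c.transcript_id, "planted_category"]

    def test_planted_js_floor_holds_on_emitted_matrix(self, bundle):
        linc_ids = bundle.truth.index[
            bundle.truth.planted_role == "true_lincRNA"
        ]
        table = specificity_table(bundle.fpkm.loc[linc_ids])
        assert (table["js_score"] >= bundle.config.js_floor).all()


class TestNeighborCorrelation:
    def test_identical_and_reversed_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        assert stats.spearmanr(x, x).statistic == pytest.approx(1.0)
        assert stats.spearmanr(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_observed_within_three_sd_of_shuffle_control(
        self, bundle, lincs, mrnas
    ):
        corr = neighbor_correlation(
            lincs, mrnas, bundle.fpkm, bundle.chrom_lengths,
            n_shuffles=100, seed=7,
        )
        assert corr.n_pairs == len(lincs)
        assert abs(corr.mean_rho - corr.shuffle_mean) <= 3 * corr.shuffle_sd

    def test_deterministic_under_fixed_seed(self, bundle, lincs, mrnas):
        a = neighbor_correlation(
            lincs[:10], mrnas, bundle.fpkm, bundle.chrom_lengths,
            n_shuffles=20, seed=3,
        )
        b = neighbor_correlation(
            lincs[:10], mrnas, bundle.fpkm, bundle.chrom_lengths,
            n_shuffles=20, seed=3,
        )
        assert a.mean_rho == b.mean_rho
        assert np.array_equal(a.shuffle_means, b.shuffle_means)

    def test_constant_vector_pairs_excluded_and_counted(self, bundle, mrnas):
        from ricelnc.types import GenomicInterval, Transcript

        lnc = Transcript(
            "const_lnc", "const_lnc",
            (GenomicInterval("chr1", 5000, 5600, "+"),),
        )
        fpkm = bundle.fpkm.copy()
        fpkm.loc["const_lnc"] = 1.0  # constant across samples -> rho undefined
        corr = neighbor_correlation(
            [lnc], mrnas, fpkm, bundle.chrom_lengths, n_shuffles=2, seed=0
        )
        assert corr.n_excluded == 1
        assert corr.n_pairs == 0
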
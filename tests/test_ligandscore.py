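"""The RET-ligand outlier score and its cohort-level statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from retpoise.ligandscore import (
    ExpressionCohort,
    RetLigandScoreModel,
    average_timepoints,
    combined_score,
    high_expression_threshold,
    ligand_high_fraction,
    lower_tail_transform,
    responder_test,
)
from retpoise.synthdata import SimParams, gen_expression_cohort


def transform_oracle(x):
    """Plain-Python lower-tail transform, independent of the implementation."""
    xs = sorted(x)
    n = len(xs)
    if n % 2:
        med = xs[n // 2]
    else:
        med = (xs[n // 2 - 1] + xs[n // 2]) / 2
    lower = [v - med for v in x if v <= med]
    s = math.sqrt(sum(d * d for d in lower) / len(lower))
    return [(v - med) / s for v in x]


def ranksum_oracle(x, y):
    """Exact one-sided rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if sum(ranks[v] for v in combo) >= obs:
            count += 1
    return count / total


class TestLowerTailTransform:
    def test_hand_computed_example(self):
        # x = [1,2,3,4,100]: median 3, lower-tail deviations {-2,-1,0},
        # s = sqrt(5/3); the outlier scores 97/s
        scores = lower_tail_transform([1, 2, 3, 4, 100])
        s = math.sqrt(5 / 3)
        assert scores[-1] == pytest.approx(97 / s, abs=1e-9)
        assert scores[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 40))
            x = rng.lognormal(1, 1, n)
            np.testing.assert_allclose(
                lower_tail_transform(x), transform_oracle(x), atol=1e-12
            )

    def test_affine_invariance_exact(self, rng):
        x = rng.lognormal(0, 1, 25)
        base = lower_tail_transform(x)
        np.testing.assert_allclose(lower_tail_transform(3.5 * x + 11.0),
                                   base, atol=1e-9)

    def test_median_of_scores_is_zero_and_monotone(self, rng):
        x = rng.normal(0, 1, 31)
        scores = lower_tail_transform(x)
        assert np.median(scores) == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(scores[np.argsort(x)]) >= 0)

    def test_symmetric_sample_matches_lower_half_zscore(self):
        x = np.array([-3, -2, -1, 0, 1, 2, 3], dtype=float)
        scores = lower_tail_transform(x)
        dev = x[x <= 0]
        s = np.sqrt(np.mean(dev**2))
        np.testing.assert_allclose(scores, x / s)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            lower_tail_transform([1, 2, 3])
        with pytest.raises(ValueError, match="identical"):
            lower_tail_transform([2, 2, 2, 2, 2])
        with pytest.raises(ValueError, match="lower tail"):
            lower_tail_transform([3, 3, 3, 5, 9], gene="GDNF")

    def test_quartile_variant_normal_consistent(self, rng):
        x = rng.normal(10, 2, 20_001)
        scores = lower_tail_transform(x, method="quartile")
        assert np.std(scores) == pytest.approx(1.0, abs=0.05)


class TestCombinedScore:
    def test_sum_and_permutation_invariance(self):
        assert combined_score([1, 2, 0.5, -0.5]) == pytest.approx(3.0)
        assert combined_score([-0.5, 0.5, 2, 1]) == pytest.approx(3.0)
        assert combined_score([0, 0, 0, 0]) == 0.0

    def test_missing_ligand_rejected(self):
        with pytest.raises(ValueError):
            combined_score([1, 2, 3])
        with pytest.raises(ValueError):
            combined_score([1, 2, 3, np.nan])


class TestHighExpressionThreshold:
    def test_direct_formula(self):
        # [1,2,3,4,5]: Q25=2, Q50=3 -> threshold 3 + 2.5*1 = 5.5
        thr = high_expression_threshold([1, 2, 3, 4, 5])
        assert thr == pytest.approx(5.5)
        assert 6 > thr and not 5 > thr

    def test_normal_quantile_oracle(self, rng):
        x = rng.standard_normal(10_000)
        thr = high_expression_threshold(x)
        # 2.5 * (Q50 - Q25) of a unit normal = 2.5 * 0.674 = 1.686
        assert thr == pytest.approx(1.686, abs=0.08)
        frac = (x > thr).mean()
        assert 0.03 < frac < 0.06

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="Q50 == Q25"):
            thr = high_expression_threshold([4.0] * 10)
        assert thr == 4.0
        assert not (np.array([4.0] * 10) > thr).any()

    def test_anchor_options(self):
        x = [1, 2, 3, 4, 5]
        assert high_expression_threshold(x, anchor="q25") == pytest.approx(4.5)
        assert high_expression_threshold(x, anchor="zero") == pytest.approx(2.5)


class TestTimepointAveraging:
    def _cohort(self, rows):
        meta = pd.DataFrame(
            [{"sample_id": sid, "response": "NA", "er_status": "ER+",
              "timepoint": tp} for sid, tp, _ in rows]
        )
        expr = pd.DataFrame({"GDNF": [v for _, _, v in rows],
                             "NRTN": 1.0, "ARTN": 1.0, "PSPN": 1.0})
        return ExpressionCohort(meta=meta, expr=expr)

    def test_mean_of_three_timepoints(self):
        coh = self._cohort([("s1", 1, 2.0), ("s1", 2, 4.0), ("s1", 3, 6.0)])
        out = average_timepoints(coh)
        assert len(out.meta) == 1
        assert out.expr["GDNF"].iloc[0] == pytest.approx(4.0)

    def test_single_timepoint_identity(self):
        coh = self._cohort([("s1", 1, 3.0)])
        out = average_timepoints(coh)
        assert out.expr["GDNF"].iloc[0] == pytest.approx(3.0)

    def test_missing_timepoint_averages_present(self):
        coh = self._cohort([("s1", 1, 2.0), ("s1", 3, 6.0),
                            ("s2", 1, 1.0), ("s2", 2, 2.0), ("s2", 3, 3.0)])
        out = average_timepoints(coh)
        got = out.expr.set_index(out.meta["sample_id"])["GDNF"]
        assert got["s1"] == pytest.approx(4.0)
        assert got["s2"] == pytest.approx(2.0)


class TestResponderTest:
    def test_exact_small_sample(self):
        assert responder_test([4, 5, 6], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_identical_groups_null(self):
        p = responder_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p >= 0.5

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(10):
            x = rng.normal(0.5, 1, 10)
            y = rng.normal(0.0, 1, 10)  # pooled 20 -> exact branch
            assert responder_test(x, y) == pytest.approx(
                ranksum_oracle(x, y), abs=1e-12
            )

    def test_asymptotic_branch_close_to_enumeration(self, rng):
        x = rng.normal(0.3, 1, 12)
        y = rng.normal(0.0, 1, 12)  # pooled 24 > 20 -> asymptotic
        assert responder_test(x, y) == pytest.approx(ranksum_oracle(x, y),
                                                     abs=0.01)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            responder_test([1, 2], [3, 4, 5])


class TestCohortLevel:
    def test_fraction_counts_each_sample_once(self):
        n = 40
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                             "response": "NA", "er_status": "ER+",
                             "timepoint": 1})
        base = np.linspace(1, 2, n)
        expr = pd.DataFrame(
            {g: base.copy() for g in ["GDNF", "NRTN", "ARTN", "PSPN"]}
        )
        expr.iloc[0] = [50.0, 50.0, 50.0, 1.5]  # one sample high in 3 ligands
        coh = ExpressionCohort(meta=meta, expr=expr)
        out = ligand_high_fraction(coh)
        assert out["n_any_high"] == 1
        assert sum(out["per_ligand_high"].values()) == 3

    def test_no_high_samples_zero_fraction(self):
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)],
                             "response": "NA", "er_status": "ER+",
                             "timepoint": 1})
        expr = pd.DataFrame(
            {g: np.linspace(1, 1.2, 10) for g in ["GDNF", "NRTN", "ARTN", "PSPN"]}
        )
        coh = ExpressionCohort(meta=meta, expr=expr)
        assert ligand_high_fraction(coh)["fraction"] == 0.0

    def test_er_filter_can_empty_cohort(self):
        meta = pd.DataFrame({"sample_id": ["a"] * 5, "response": "NA",
                             "er_status": "ER-", "timepoint": 1})
        expr = pd.DataFrame(
            {g: np.arange(5.0) + 1 for g in ["GDNF", "NRTN", "ARTN", "PSPN"]}
        )
        coh = ExpressionCohort(meta=meta, expr=expr)
        with pytest.raises(ValueError, match="ER"):
            ligand_high_fraction(coh, er_positive_only=True)

    def test_model_output_invariant_to_sample_order(self):
        coh, _ = gen_expression_cohort(SimParams(seed=31), style="letrozole",
                                       n_timepoints=3)
        res = RetLigandScoreModel(coh).fit()
        perm = np.random.default_rng(1).permutation(len(coh.meta))
        coh2 = ExpressionCohort(
            meta=coh.meta.iloc[perm].reset_index(drop=True),
            expr=coh.expr.iloc[perm].reset_index(drop=True),
        )
        res2 = RetLigandScoreModel(coh2).fit()
        pd.testing.assert_series_equal(res.summed, res2.summed)
        assert res.group_p == res2.group_p

    def test_summed_score_is_exact_sum(self):
        coh, _ = gen_expression_cohort(SimParams(seed=32), style="tcga")
        res = RetLigandScoreModel(coh).fit()
        np.testing.assert_allclose(res.summed, res.scores.sum(axis=1),
                                   atol=1e-12)

    def test_summary_reports_fraction_and_p(self):
        coh, _ = gen_expression_cohort(SimParams(seed=33), style="letrozole",
                                       n_timepoints=3)
        text = RetLigandScoreModel(coh).fit().summary()
        assert "ligand high" in text or ">= 1 ligand high" in text
        assert "rank-sum" in text

    def test_score_boxplot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        coh, _ = gen_expression_cohort(SimParams(seed=35), style="letrozole")
        ax = RetLigandScoreModel(coh).fit().plot_scores()
        assert "outlier score" in ax.get_ylabel()

    def test_cohort_tsv_roundtrip(self, tmp_path):
        coh, _ = gen_expression_cohort(SimParams(seed=34), style="letrozole")
        path = tmp_path / "cohort.tsv"
        coh.to_tsv(path)
        back = ExpressionCohort.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.expr, coh.expr.reset_index(drop=True), check_dtype=False
        )
        assert list(back.meta["response"]) == list(coh.meta["response"])
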
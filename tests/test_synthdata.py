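"""Properties of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retpoise.synthdata import (
    PackingError,
    SimParams,
    background_windows,
    child_rng,
    gen_accessibility_truth,
    gen_count_table,
    gen_expression_cohort,
    gen_genome,
    gen_proseq_tracks,
    gen_tre_sequences,
)


class TestGenome:
    def test_deterministic_for_fixed_seed(self, small_params, small_genome):
        again = gen_genome(small_params)
        assert [g.start for g in again.genes] == [g.start for g in small_genome.genes]
        assert again.differential_truth == small_genome.differential_truth

    def test_features_within_bounds_and_disjoint_tres(self, small_genome):
        length = small_genome.chrom_sizes["chr1"]
        ivs = sorted(small_genome.tre_intervals(), key=lambda iv: iv.start)
        for iv in ivs:
            assert 0 <= iv.start < iv.end <= length
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a.end <= b.start

    def test_gene_length_floor(self, small_genome):
        assert all(g.length >= 2000 for g in small_genome.genes)

    def test_empty_gene_list_allowed(self):
        genome = gen_genome(SimParams(seed=1, n_genes=0, n_tres=5))
        assert genome.genes == []
        assert len(genome.true_tres) == 5

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            gen_genome(SimParams(seed=1, chrom_length=50_000, n_genes=40))

    def test_promoter_truth_inherits_gene_fold_change(self, small_genome):
        for t in small_genome.true_tres:
            if t["class"] == "promoter":
                assert (small_genome.differential_truth[t["interval"].id]
                        == small_genome.differential_truth[t["gene_id"]])


class TestProseqTracks:
    def test_deterministic_for_fixed_seed(self, small_genome, small_params,
                                          small_tracks):
        again = gen_proseq_tracks(small_genome, "A", small_params)
        np.testing.assert_array_equal(again.plus["chr1"],
                                      small_tracks.plus["chr1"])

    def test_unknown_condition_rejected(self, small_genome, small_params):
        with pytest.raises(ValueError, match="condition"):
            gen_proseq_tracks(small_genome, "C", small_params)

    def test_enhancers_transcribe_both_strands(self, small_genome, small_tracks):
        for t in small_genome.true_tres:
            if t["class"] != "enhancer":
                continue
            iv = t["interval"]
            lo, hi = iv.start - 100, iv.end + 100
            assert small_tracks.plus["chr1"][lo:hi].sum() > 0
            assert small_tracks.minus["chr1"][lo:hi].sum() > 0

    def test_planted_fold_change_recovered_in_body_counts(self):
        # planted +2 log2 units -> condition B bodies ~4x condition A
        params = SimParams(seed=3, n_genes=100, n_tres=0,
                           chrom_length=2_000_000, diff_fraction=0.5)
        genome = gen_genome(params)
        tr_a = gen_proseq_tracks(genome, "A", params)
        tr_b = gen_proseq_tracks(genome, "B", params)
        up = [g for g in genome.genes
              if genome.differential_truth[g.id] == params.planted_fc]
        assert len(up) >= 15
        a = sum(tr_a.plus["chr1"][g.start:g.end].sum()
                + tr_a.minus["chr1"][g.start:g.end].sum() for g in up)
        b = sum(tr_b.plus["chr1"][g.start:g.end].sum()
                + tr_b.minus["chr1"][g.start:g.end].sum() for g in up)
        # Poisson totals are large; ratio should sit within a few percent of 4
        assert b / a == pytest.approx(4.0, rel=0.1)

    def test_zero_rates_give_zero_tracks(self, small_genome):
        params = SimParams(seed=7, pause_height=0.0, body_density=0.0,
                           enhancer_height=0.0)
        tr = gen_proseq_tracks(small_genome, "A", params)
        assert tr.plus["chr1"].sum() == 0
        assert tr.minus["chr1"].sum() == 0

    def test_track_totals_scale_linearly_with_rates(self, small_genome):
        totals = []
        factors = (0.5, 1.0, 2.0)
        for f in factors:
            p = SimParams(seed=5, pause_height=2.0 * f, body_density=0.05 * f,
                          enhancer_height=1.0 * f)
            tr = gen_proseq_tracks(small_genome, "A", p)
            totals.append(tr.plus["chr1"].sum() + tr.minus["chr1"].sum())
        slope = np.polyfit(factors, totals, 1)[0]
        predicted = [slope * f for f in factors]
        for t, pr in zip(totals, predicted):
            assert t == pytest.approx(pr, rel=0.05)


class TestAccessibilityTruth:
    def test_maxima_at_tre_centers(self, small_genome, small_params):
        sig = gen_accessibility_truth(small_genome, small_params)["chr1"]
        for t in small_genome.true_tres[:5]:
            c = t["interval"].center
            window = sig[c - 200 : c + 200]
            assert abs(int(np.argmax(window)) + c - 200 - c) <= 2

    def test_no_active_tres_gives_zero_track(self, small_params):
        genome = gen_genome(small_params)
        for t in genome.true_tres:
            t["active"] = False
        sig = gen_accessibility_truth(genome, small_params)["chr1"]
        assert not sig.any()

    def test_two_separated_tres_two_local_maxima(self, small_genome, small_params):
        sig = gen_accessibility_truth(small_genome, small_params)["chr1"]
        ivs = sorted(small_genome.tre_intervals(), key=lambda iv: iv.start)
        far = [
            (a, b) for a, b in zip(ivs[:-1], ivs[1:]) if b.center - a.center > 5000
        ]
        a, b = far[0]
        assert sig[a.center] > 0 and sig[b.center] > 0
        mid = (a.center + b.center) // 2
        assert sig[mid] < min(sig[a.center], sig[b.center])


class TestCountTable:
    def test_nb_variance_exceeds_poisson(self):
        params = SimParams(seed=2, nb_dispersion=0.5)
        df, groups, _ = gen_count_table(params, 2000, 10, diff_fraction=0.0)
        sub = df.to_numpy()[:, :10]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        keep = mu > 50
        # MoM inversion across features recovers the planted dispersion scale
        alpha = np.median((var[keep] - mu[keep]) / mu[keep] ** 2)
        assert 0.25 < alpha < 1.0

    def test_planted_fold_change_mean_ratio(self):
        params = SimParams(seed=4)
        df, groups, truth = gen_count_table(params, 400, 6, diff_fraction=0.5)
        up = truth.index[(truth == params.planted_fc).to_numpy()]
        a = df.loc[up, groups == "A"].to_numpy().mean()
        b = df.loc[up, groups == "B"].to_numpy().mean()
        assert b / a == pytest.approx(4.0, rel=0.15)


class TestExpressionCohort:
    def test_deterministic_for_fixed_seed(self):
        p = SimParams(seed=9)
        c1, t1 = gen_expression_cohort(p)
        c2, t2 = gen_expression_cohort(p)
        pd.testing.assert_frame_equal(c1.expr, c2.expr)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_tail_fraction(self):
        fractions = [
            gen_expression_cohort(SimParams(seed=s))[1]["any_tail"].mean()
            for s in range(5)
        ]
        # binomial tolerance around 0.13 at n=925
        assert np.mean(fractions) == pytest.approx(0.13, abs=0.02)

    def test_receptor_esr1_spearman_near_target(self):
        rhos = []
        for s in (10, 11, 12):
            coh, _ = gen_expression_cohort(SimParams(seed=s))
            rhos.append(stats.spearmanr(coh.expr["RET"], coh.expr["ESR1"])[0])
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.06)

    def test_ligand_genes_fail_tail_symmetry_others_pass(self):
        coh, _ = gen_expression_cohort(SimParams(seed=13))
        logx = np.log(coh.expr.to_numpy())

        def asym(col):
            q10, q50, q90 = np.quantile(col, [0.1, 0.5, 0.9])
            return ((q90 - q50) - (q50 - q10)) / (q90 - q10)

        ligand_stats = [asym(np.log(coh.expr[g])) for g in coh.ligand_genes]
        other = [c for c in coh.expr.columns
                 if c not in coh.ligand_genes][:10]
        other_stats = [asym(np.log(coh.expr[g])) for g in other]
        assert min(np.abs(ligand_stats)) > max(np.abs(other_stats))

    def test_null_shift_keeps_labels_exchangeable(self):
        _, truth = gen_expression_cohort(
            SimParams(seed=21, responder_shift=0.0), style="letrozole"
        )
        by_group = truth.groupby("response")["any_tail"].mean()
        # membership independent of labels under the null construction
        assert abs(by_group.get("nonresponder", 0) - by_group.get("responder", 0)) < 0.5

    def test_nonresponder_membership_elevated_under_shift(self):
        counts = {"nonresponder": [], "responder": []}
        for s in range(10):
            _, truth = gen_expression_cohort(
                SimParams(seed=s, responder_shift=1.0), style="letrozole"
            )
            lig = truth[["GDNF", "NRTN", "ARTN", "PSPN"]].sum(axis=1)
            for grp in counts:
                counts[grp].append(lig[truth["response"] == grp].mean())
        excess = np.mean(counts["nonresponder"]) - np.mean(counts["responder"])
        assert excess == pytest.approx(1.0, abs=0.35)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="ligand"):
            gen_expression_cohort(SimParams(seed=1, n_cohort_genes=3))

    def test_timepoints_share_sample_mean(self):
        coh, _ = gen_expression_cohort(SimParams(seed=2), style="letrozole",
                                       n_timepoints=3)
        assert coh.meta["timepoint"].nunique() == 3
        wide = coh.expr.assign(sid=coh.meta["sample_id"].to_numpy())
        cv = wide.groupby("sid")["GDNF"].std() / wide.groupby("sid")["GDNF"].mean()
        assert cv.max() < 0.25  # repeated biopsies are tightly correlated


class TestSequencesAndWindows:
    def test_planted_motif_present_in_marked_sequences(self, rng):
        seqs, planted = gen_tre_sequences(40, 200, rng,
                                          motif_consensus="TGACGTCA",
                                          plant_fraction=0.5)
        for s, flag in zip(seqs, planted):
            assert ("TGACGTCA" in s) == flag or not flag

    def test_gc_content_tracks_request(self, rng):
        seqs, _ = gen_tre_sequences(50, 500, rng, gc_mean=0.6, gc_sd=0.01)
        gcs = [(s.count("G") + s.count("C")) / len(s) for s in seqs]
        assert np.mean(gcs) == pytest.approx(0.6, abs=0.03)

    def test_background_windows_avoid_features(self, small_genome, rng):
        wins = background_windows(small_genome, 10, 300, rng)
        for w in wins:
            for g in small_genome.genes:
                assert w.end <= g.start or w.start >= g.end
            for t in small_genome.true_tres:
                iv = t["interval"]
                assert w.end <= iv.start or w.start >= iv.end


def test_child_rng_streams_are_stable_and_distinct():
    a1 = child_rng(5, "x").integers(0, 1 << 30, 4)
    a2 = child_rng(5, "x").integers(0, 1 << 30, 4)
    b = child_rng(5, "y").integers(0, 1 << 30, 4)
    np.testing.assert_array_equal(a1, a2)
    assert not np.array_equal(a1, b)
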
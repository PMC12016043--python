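"""Disruption/allelic paired tests, group tests, correlations, padding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mprakit.design import reverse_complement
from mprakit.errors import InvalidParameterError
from mprakit.stats import (
    allelic_test,
    cross_tissue_correlation,
    group_activity_test,
    motif_disruption_test,
    pad_for_prediction,
    paired_t,
    prediction_correlation,
)


class TestPairedT:
    def test_matches_closed_form_on_worked_vector(self):
        x = np.array([2.1, 3.0, 1.8, 2.6])
        y = np.array([1.0, 1.2, 1.5, 0.9])
        t, p = paired_t(x, y)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df=len(d) - 1))

    def test_identical_pairs_no_effect(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_needs_two_pairs(self):
        with pytest.raises(InvalidParameterError):
            paired_t([1.0], [2.0])


class TestMotifDisruption:
    def test_active_baselines_significant_inactive_not(self, sim, scored):
        """Shuffling removes the motif's activity: active baselines come out
        significant at FDR 0.05 while inactive ones do not."""
        res = motif_disruption_test(scored, sim["design"])
        assert not res.empty
        # all MEF2 baselines are active in the default simulation
        assert (res["p_adjusted"] < 0.05).mean() > 0.5
        assert (res["effect"] > 0).all()

    def test_null_scores_give_large_p(self, sim):
        meta = sim["design"].enhancers
        rows = []
        rng = np.random.default_rng(5)
        for grp in ("s1", "s2", "s3", "s4"):
            for eid in meta["enhancer_id"]:
                rows.append({"enhancer_id": eid, "group": grp,
                             "tissue": "cortex",
                             "mad_score": rng.normal()})
        table = pd.DataFrame(rows)
        res = motif_disruption_test(table, sim["design"], tissues=["cortex"])
        assert (res["p_raw"] < 0.05).mean() <= 0.3  # small-n sanity, not power

    def test_typeI_error_controlled_over_200_replicates(self, design60):
        """Null simulations (no disruption effect): ≤7% of units reach
        p_raw < 0.05 across 200 replicates."""
        rng = np.random.default_rng(17)
        meta = design60.enhancers
        eids = meta["enhancer_id"]
        hits = trials = 0
        for _ in range(200):
            rows = []
            for grp in ("s1", "s2", "s3", "s4", "s5", "s6"):
                scores = rng.normal(size=len(eids))
                rows.append(pd.DataFrame({
                    "enhancer_id": eids, "group": grp, "tissue": "cortex",
                    "mad_score": scores}))
            res = motif_disruption_test(
                pd.concat(rows, ignore_index=True), design60,
                tissues=["cortex"])
            hits += (res["p_raw"] < 0.05).sum()
            trials += len(res)
        assert trials >= 200
        assert hits / trials <= 0.07

    def test_bh_is_monotone_in_raw_p(self, sim, scored):
        res = motif_disruption_test(scored, sim["design"])
        srt = res.sort_values("p_raw")
        assert (srt["p_adjusted"].diff().dropna() >= -1e-12).all()
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()


class TestAllelic:
    def test_gain_of_function_allele_brain_not_liver(self, sim, scored):
        """Alt alleles boosted in brain/HMC3 only: significant with liver
        excluded, not in a liver-only analysis."""
        res = allelic_test(scored, sim["design"])
        alt = res[res["comparison"] == "alt"].set_index("unit")
        # effect loci are the low-numbered SNPs in the default model
        eff = [u for u in alt.index if int(u.split("_")[1]) < 8]
        assert eff and (alt.loc[eff, "p_raw"] < 0.05).all()
        assert (alt.loc[eff, "effect"] < 0).all()  # alt > ref
        liver_only = allelic_test(scored, sim["design"],
                                  exclude_tissues=(), tissues=["liver"])
        lalt = liver_only[liver_only["comparison"] == "alt"].set_index("unit")
        assert (lalt.loc[[u for u in eff if u in lalt.index], "p_raw"]
                > 0.05).all()

    def test_label_swap_flips_effect_sign(self):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.2, size=6)
        b = rng.normal(0.2, 0.2, size=6)
        t1, p1 = paired_t(a, b)
        t2, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_region_disrupt_family_present(self, sim, scored):
        res = allelic_test(scored, sim["design"])
        assert set(res["comparison"]) <= {"alt", "region_disrupt"}
        assert (res["comparison"] == "region_disrupt").any()


class TestGroupTest:
    def test_null_uniform_over_replicates(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            g = rng.normal(size=20)
            n = rng.normal(size=20)
            ps.append(group_activity_test(g, n))
        _, ks_p = sps.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_power_at_three_robust_sd_shift(self):
        rng = np.random.default_rng(6)
        n = rng.normal(size=20)
        g = rng.normal(loc=3.0, size=20)
        assert group_activity_test(g, n) < 0.001

    def test_liver_controls_active_in_liver_not_brain(self, sim, scored):
        from mprakit.activity import aggregate_activity
        agg = aggregate_activity(scored, sim["design"], grouping="tissue_type")
        meta = sim["design"].enhancers.set_index("enhancer_id")
        liver_pos = meta[(meta["category"] == "positive_control")
                         & (meta["target_tissue"] == "liver")].index
        neg = meta[meta["category"].isin(
            ["negative_control", "random_negative"])].index
        by_grp = {g: s.set_index("enhancer_id")["mad_score"]
                  for g, s in agg.groupby("group")}
        p_liver = group_activity_test(
            by_grp["liver"].loc[liver_pos], by_grp["liver"].loc[neg])
        p_brain = group_activity_test(
            by_grp["brain"].loc[liver_pos], by_grp["brain"].loc[neg])
        assert p_liver < 0.05 < p_brain

    def test_degenerate_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            group_activity_test([1.0, 1.0], [2.0, 2.0])


class TestCrossTissueCorrelation:
    def test_identical_vectors_give_rho_one(self):
        act = pd.DataFrame({
            "enhancer_id": list("abcdefghijkl") * 2,
            "group": ["t1"] * 12 + ["t2"] * 12,
            "alpha": list(range(12)) * 2,
        })
        cm = cross_tissue_correlation(act)
        assert cm.rho.loc["t1", "t2"] == pytest.approx(1.0)
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert cm.rho.equals(cm.rho.T)

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0, 4.0, 5.0])
        act = pd.DataFrame({
            "enhancer_id": [f"e{i}" for i in range(12)] * 2,
            "group": ["t1"] * 12 + ["t2"] * 12,
            "alpha": np.concatenate([x, y]),
        })
        cm = cross_tissue_correlation(act)
        rho_oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert cm.rho.loc["t1", "t2"] == pytest.approx(rho_oracle)

    def test_too_few_shared_enhancers_flagged_na(self):
        act = pd.DataFrame({
            "enhancer_id": list("abcde") * 2,
            "group": ["t1"] * 5 + ["t2"] * 5,
            "alpha": range(10),
        })
        cm = cross_tissue_correlation(act, min_shared=10)
        assert np.isnan(cm.rho.loc["t1", "t2"])

    def test_brain_brain_exceeds_brain_liver(self, sim, scored):
        from mprakit.activity import aggregate_activity
        agg = aggregate_activity(scored, sim["design"], grouping="tissue")
        cm = cross_tissue_correlation(agg)
        assert cm.rho.loc["M1", "cortex"] > cm.rho.loc["M1", "liver"]
        assert cm.rho.loc["cortex", "striatum"] > cm.rho.loc["cortex", "liver"]


class TestPrediction:
    def test_padding_geometry(self):
        seq = "A" * 120
        padded = pad_for_prediction(seq, 500)
        assert len(padded.forward) == 500
        assert padded.forward == "N" * 190 + seq + "N" * 190

    def test_identity_when_already_target_length(self):
        seq = "ACGT" * 10
        assert pad_for_prediction(seq, 40).forward == seq

    def test_odd_padding_extra_n_on_left(self):
        padded = pad_for_prediction("ACG", 6)
        assert padded.forward == "NNACGN"

    def test_revcomp_commutes_with_padding(self):
        # symmetric (even) padding: padding and reverse-complement commute
        seq = "ACGTTGCAAC"
        a = pad_for_prediction(seq, 22).reverse
        b = pad_for_prediction(reverse_complement(seq), 22).forward
        assert a == b

    def test_target_shorter_than_sequence_raises(self):
        with pytest.raises(InvalidParameterError):
            pad_for_prediction("ACGTACGT", 4)

    def test_perfect_scores_give_rho_one(self):
        act = pd.DataFrame({"enhancer_id": [f"e{i}" for i in range(20)],
                            "alpha": np.arange(20, dtype=float)})
        scores = pd.DataFrame({
            "enhancer_id": act["enhancer_id"],
            "score_fwd": act["alpha"] * 1.1,
            "score_rev": act["alpha"] * 0.9,
        })
        rho, p, n = prediction_correlation(act, scores)
        assert rho == pytest.approx(1.0)
        assert n == 20

    def test_permuted_scores_near_zero(self):
        rng = np.random.default_rng(8)
        rhos = []
        for _ in range(20):
            act = pd.DataFrame({"enhancer_id": [f"e{i}" for i in range(50)],
                                "alpha": rng.normal(size=50)})
            perm = rng.permutation(act["alpha"].to_numpy())
            scores = pd.DataFrame({"enhancer_id": act["enhancer_id"],
                                   "score_fwd": perm, "score_rev": perm})
            rho, _, _ = prediction_correlation(act, scores)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_monotone_transform_beats_shuffled_scores(self, sim, scored):
        """Scores that are a monotone transform of alpha_true correlate with
        measured activity far better than shuffled scores (margin > 0.3)."""
        truth = sim["truth"].alpha_true["cortex"]
        act = scored[scored["group"] == "animal1_cortex_RNA"][
            ["enhancer_id", "alpha"]]
        s = np.log1p(truth.loc[act["enhancer_id"]]).to_numpy()
        scores = pd.DataFrame({"enhancer_id": act["enhancer_id"],
                               "score_fwd": s, "score_rev": s})
        rho_true, _, _ = prediction_correlation(act, scores)
        rng = np.random.default_rng(9)
        shuf = scores.assign(score_fwd=rng.permutation(s),
                             score_rev=rng.permutation(s))
        rho_shuf, _, _ = prediction_correlation(act, shuf)
        assert rho_true - rho_shuf > 0.3
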
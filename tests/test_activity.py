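"""Activity estimation (alpha), MAD scoring and empirical p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mprakit.activity import (
    aggregate_activity,
    empirical_pvalue,
    estimate_alpha,
    mad_score,
    score_activity,
)
from mprakit.design import EnhancerCandidate, assign_barcodes, random_dna
from mprakit.errors import DegenerateNullError, InvalidParameterError, PairingError
from mprakit.quant import CountMatrix
from mprakit.simulate import ExpressionModel, make_sample_sheet, simulate_counts


def _null_design(n_neg=100, n_cand=100, k=4, seed=0):
    """Design dominated by negative controls, for null-calibration checks."""
    rng = np.random.default_rng(seed)
    cands = [EnhancerCandidate(f"neg_{i:03d}", random_dna(120, rng),
                               "random_negative", "none")
             for i in range(n_neg)]
    cands += [EnhancerCandidate(f"cand_{i:03d}", random_dna(120, rng),
                                "cortical", "brain")
              for i in range(n_cand)]
    return assign_barcodes(cands, k=k, seed=seed + 1)


class TestEstimateAlpha:
    def test_identity_ratio(self, design60):
        counts = pd.DataFrame(
            {"animal1_cortex_DNA": 10}, index=design60.barcodes)
        dna = CountMatrix(df=counts, molecule="DNA")
        rna = CountMatrix(df=counts.rename(
            columns={"animal1_cortex_DNA": "animal1_cortex_RNA"}), molecule="RNA")
        samples = make_sample_sheet(("cortex",), n_animals=1)
        table = estimate_alpha(rna, dna, design60, samples)
        assert np.allclose(table["alpha"], 1.0)

    def test_zero_rna_stays_positive_below_one(self, design60):
        dna = CountMatrix(df=pd.DataFrame(
            {"animal1_cortex_DNA": 10}, index=design60.barcodes), molecule="DNA")
        rna = CountMatrix(df=pd.DataFrame(
            {"animal1_cortex_RNA": 0}, index=design60.barcodes), molecule="RNA")
        samples = make_sample_sheet(("cortex",), n_animals=1)
        table = estimate_alpha(rna, dna, design60, samples)
        assert (table["alpha"] > 0).all()
        assert (table["alpha"] < 1).all()

    def test_missing_dna_sample_raises(self, design60):
        rna = CountMatrix(df=pd.DataFrame(
            {"animal1_cortex_RNA": 1}, index=design60.barcodes), molecule="RNA")
        dna = CountMatrix(df=pd.DataFrame(
            {"animal2_cortex_DNA": 1}, index=design60.barcodes), molecule="DNA")
        samples = make_sample_sheet(("cortex",), n_animals=1)
        samples.loc[samples["molecule"] == "DNA", "animal"] = "animal2"
        samples.loc[samples["molecule"] == "DNA", "sample_id"] = \
            "animal2_cortex_DNA"
        with pytest.raises(PairingError):
            estimate_alpha(rna, dna, design60, samples)

    def test_scale_invariance_of_alpha(self, sim):
        """Multiplying all RNA counts in a sample by a constant cancels in
        the library-size normalization."""
        t1 = estimate_alpha(sim["rna"], sim["dna"], sim["design"], sim["samples"])
        scaled = CountMatrix(df=sim["rna"].df * 7, molecule="RNA")
        t2 = estimate_alpha(scaled, sim["dna"], sim["design"], sim["samples"])
        assert np.allclose(t1["alpha"], t2["alpha"], rtol=1e-4)

    def test_rank_recovery_of_true_activity(self, design60):
        """alpha_true spanning {1,2,4,8}: estimated alpha recovers the
        ranking (Spearman > 0.9) at depth 2×10^5."""
        eids = design60.enhancers["enhancer_id"]
        truth = np.array([2 ** (i % 4) for i in range(len(eids))], dtype=float)
        alpha = pd.DataFrame({"cortex": truth}, index=eids)
        model = ExpressionModel(alpha=alpha, dna_depth=2e5, rna_depth=2e5,
                                transduction={"cortex": 1.0})
        samples = make_sample_sheet(("cortex",), n_animals=1)
        dna, rna, _ = simulate_counts(design60, model, samples, seed=13)
        table = estimate_alpha(rna, dna, design60, samples)
        est = table.set_index("enhancer_id").loc[eids, "alpha"]
        rho, _ = sps.spearmanr(est, truth)
        assert rho > 0.9


class TestMadScore:
    def test_centering_at_negative_median(self):
        neg = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert mad_score(np.array([2.0]), neg)[0] == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        neg = rng.normal(size=20)
        shifted = mad_score(vals + 5.0, neg + 5.0)
        assert np.allclose(shifted, mad_score(vals, neg))

    def test_consistency_with_normal_sd(self):
        rng = np.random.default_rng(1)
        neg = rng.normal(0, 2.0, size=20000)
        scores = mad_score(np.array([2.0]), neg)
        assert scores[0] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_null_raises(self):
        with pytest.raises(DegenerateNullError):
            mad_score(np.array([1.0]), np.full(10, 3.0))

    def test_too_few_negatives_raises(self):
        with pytest.raises(InvalidParameterError):
            mad_score(np.array([1.0]), np.array([1.0, 2.0, 3.0, 4.0]))


class TestEmpiricalPvalue:
    def test_extreme_rank(self):
        neg = np.arange(39, dtype=float)
        assert empirical_pvalue(100.0, neg) == pytest.approx(1 / 40)

    def test_score_at_null_minimum_gives_one(self):
        neg = np.arange(1, 40, dtype=float)
        assert empirical_pvalue(1.0, neg) == 1.0

    def test_null_pvalues_uniform(self):
        """Candidates exchangeable with the null give ~Uniform(0,1] p-values."""
        rng = np.random.default_rng(2)
        neg = rng.normal(size=200)
        cand = rng.normal(size=200)
        p = empirical_pvalue(cand, neg)
        _, ks_p = sps.kstest(p, "uniform")
        assert ks_p > 0.01

    def test_empty_null_raises(self):
        with pytest.raises(InvalidParameterError):
            empirical_pvalue(1.0, np.array([]))


class TestTypeIError:
    def test_null_simulation_fpr_below_7pct(self):
        """Constant activity everywhere: ≤7% of candidate enhancers reach
        p_empirical < 0.05."""
        design = _null_design()
        alpha = pd.DataFrame(
            1.0, index=design.enhancers["enhancer_id"],
            columns=["cortex", "liver"])
        model = ExpressionModel(alpha=alpha, dna_depth=1e5, rna_depth=1e5)
        samples = make_sample_sheet(("cortex", "liver"), n_animals=1)
        dna, rna, _ = simulate_counts(design, model, samples, seed=21)
        table = score_activity(
            estimate_alpha(rna, dna, design, samples), design)
        cands = table[table["enhancer_id"].str.startswith("cand")]
        fpr = (cands["p_empirical"] < 0.05).mean()
        assert fpr <= 0.07


class TestAggregation:
    def test_single_sample_is_identity(self, sim, scored):
        one = scored[scored["group"] == "animal1_cortex_RNA"]
        agg = aggregate_activity(one, sim["design"], grouping="tissue")
        merged = one.merge(agg, on="enhancer_id", suffixes=("_s", "_a"))
        assert np.allclose(merged["log_alpha_s"], merged["log_alpha_a"])
        assert np.allclose(merged["mad_score_s"], merged["mad_score_a"])

    def test_aggregate_bounded_by_per_sample_range(self, sim, scored):
        agg = aggregate_activity(scored, sim["design"], grouping="tissue")
        per = scored.groupby(["enhancer_id", "tissue"])["log_alpha"]
        lo, hi = per.min(), per.max()
        merged = agg.set_index(["enhancer_id", "tissue"])
        for key, row in merged.iterrows():
            assert lo[key] - 1e-9 <= row["log_alpha"] <= hi[key] + 1e-9

    def test_two_identical_samples_equal_either(self, sim, scored):
        one = scored[scored["group"] == "animal1_cortex_RNA"].copy()
        two = one.copy()
        two["group"] = "animal2_cortex_RNA"
        two["animal"] = "animal2"
        both = pd.concat([one, two], ignore_index=True)
        agg = aggregate_activity(both, sim["design"], grouping="tissue")
        merged = one.merge(agg, on="enhancer_id", suffixes=("_s", "_a"))
        assert np.allclose(merged["log_alpha_s"], merged["log_alpha_a"])
        assert agg["consistent"].all()

    def test_tissue_type_grouping(self, sim, scored):
        agg = aggregate_activity(scored, sim["design"], grouping="tissue_type")
        assert set(agg["group"]) == {"brain", "liver", "HMC3"}

    def test_unknown_grouping_rejected(self, sim, scored):
        from mprakit.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            aggregate_activity(scored, sim["design"], grouping="animal")


class TestDirectionalStructure:
    def test_mef2_scores_higher_in_brain_than_liver(self, sim, scored):
        """MEF2-class active enhancers score higher in brain samples than in
        liver samples under the strong-effect simulation."""
        meta = sim["design"].enhancers.set_index("enhancer_id")
        mef2 = meta[(meta["category"] == "MEF2")
                    & (meta["variant_kind"] == "baseline")].index
        sub = scored[scored["enhancer_id"].isin(mef2)]
        brain = sub[sub["tissue"].isin(["M1", "cortex", "striatum"])]
        liver = sub[sub["tissue"] == "liver"]
        assert brain["mad_score"].median() > liver["mad_score"].median()

    def test_active_pvalues_pile_near_zero(self, sim, scored):
        meta = sim["design"].enhancers.set_index("enhancer_id")
        active = meta[(meta["category"] == "cortical")].index
        neg = meta[meta["category"].isin(
            ["negative_control", "random_negative"])].index
        brain = scored[scored["tissue"] == "cortex"]
        p_active = brain[brain["enhancer_id"].isin(active)]["p_empirical"]
        p_neg = brain[brain["enhancer_id"].isin(neg)]["p_empirical"]
        assert p_active.median() < 0.1
        assert p_neg.median() > 0.2
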
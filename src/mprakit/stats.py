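"""Statistical comparisons on scored enhancer activities.

Covers the perturbation analyses of a variant-bearing MPRA library: paired
t-tests of baseline vs motif-shuffled enhancers (disruption), paired ref vs
alt allele tests (SNPs), one-sided Welch tests of a candidate group against
the negative controls, Spearman correlation of activities between tissues,
and the padding/averaging interface used to compare measured activity with
external open-chromatin predictor scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mprakit.design import DesignTable, reverse_complement
from mprakit.errors import InvalidParameterError

logger = logging.getLogger(__name__)

#: Brain samples used for motif-disruption testing.
DISRUPTION_TISSUES = ("M1", "cortex", "striatum")


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired t-test returning (statistic, p).

    The degenerate all-equal case (every difference zero) is defined as
    t = 0, p = 1 — no evidence of an effect rather than an undefined
    statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidParameterError("paired test needs >= 2 complete pairs")
    diff = x - y
    if np.allclose(diff, 0):
        return 0.0, 1.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def _bh(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        df["p_adjusted"] = pd.Series(dtype=float)
        return df
    df = df.copy()
    df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def _pivot_scores(activity: pd.DataFrame, tissues: Sequence[str] | None,
                  exclude: Sequence[str] = ()) -> pd.DataFrame:
    if "mad_score" not in activity.columns:
        raise InvalidParameterError(
            "activity table has no mad_score column; run score_activity first")
    t = activity
    if tissues is not None:
        t = t[t["tissue"].isin(tissues)]
    if exclude:
        t = t[~t["tissue"].isin(exclude)]
    return t.pivot_table(index="enhancer_id", columns="group",
                         values="mad_score")


def motif_disruption_test(activity: pd.DataFrame, design: DesignTable,
                          tissues: Sequence[str] | None = DISRUPTION_TISSUES,
                          ) -> pd.DataFrame:
    """Paired test of each baseline enhancer against its shuffled versions.

    For every baseline with motif-shuffled variants, each sample contributes
    the pair (baseline MAD score, mean MAD score over the shuffled versions);
    a paired t-test runs across samples and Benjamini–Hochberg adjustment
    across all baselines tested.  The effect is the mean score difference
    (baseline − shuffled), positive when shuffling lowers activity.
    """
    scores = _pivot_scores(activity, tissues)
    meta = design.enhancers
    shuffled = meta[meta["variant_kind"].isin(
        ["motif_shuffled", "motif_flank_shuffled"])]
    rows = []
    for baseline, grp in shuffled.groupby("variant_of"):
        if baseline not in scores.index:
            logger.info("disruption unit %s skipped: no baseline scores", baseline)
            continue
        variant_ids = [v for v in grp["enhancer_id"] if v in scores.index]
        if not variant_ids:
            logger.info("disruption unit %s skipped: no variant scores", baseline)
            continue
        base = scores.loc[baseline]
        var_mean = scores.loc[variant_ids].mean(axis=0)
        ok = base.notna() & var_mean.notna()
        if ok.sum() < 2:
            logger.info("disruption unit %s skipped: <2 complete pairs", baseline)
            continue
        t, p = paired_t(base[ok], var_mean[ok])
        rows.append({
            "unit": baseline, "statistic": t, "p_raw": p,
            "effect": float((base[ok] - var_mean[ok]).mean()),
            "baseline_score": float(base[ok].mean()),
            "n_pairs": int(ok.sum()), "n_variants": len(variant_ids),
            "tissues": ",".join(tissues) if tissues else "all",
        })
    return _bh(pd.DataFrame(rows))


def allelic_test(activity: pd.DataFrame, design: DesignTable,
                 exclude_tissues: Sequence[str] = ("liver",),
                 tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Paired ref vs alt (and ref vs region-disrupt) tests per SNP locus.

    Liver samples are excluded by default; pass ``tissues`` to restrict to an
    explicit subset instead.  The effect is mean(ref − alt) of MAD scores,
    so a negative effect marks a gain-of-activity alternative allele.
    Benjamini–Hochberg adjustment runs across SNPs within each comparison
    family (alt, region_disrupt).
    """
    scores = _pivot_scores(activity, tissues, exclude=exclude_tissues
                           if tissues is None else ())
    meta = design.enhancers
    variants = meta[meta["variant_kind"].isin(["alt_allele", "region_disrupt"])]
    rows = []
    for ref_id, grp in variants.groupby("variant_of"):
        if ref_id not in scores.index:
            logger.info("allelic unit %s skipped: no ref scores", ref_id)
            continue
        ref = scores.loc[ref_id]
        for v in grp.itertuples():
            if v.enhancer_id not in scores.index:
                logger.info("allele %s skipped: missing scores", v.enhancer_id)
                continue
            other = scores.loc[v.enhancer_id]
            ok = ref.notna() & other.notna()
            if ok.sum() < 2:
                logger.info("allelic unit %s/%s skipped: <2 pairs",
                            ref_id, v.enhancer_id)
                continue
            t, p = paired_t(ref[ok], other[ok])
            rows.append({
                "unit": ref_id, "comparison":
                    "alt" if v.variant_kind == "alt_allele" else "region_disrupt",
                "statistic": t, "p_raw": p,
                "effect": float((ref[ok] - other[ok]).mean()),
                "n_pairs": int(ok.sum()),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_adjusted"] = pd.Series(dtype=float)
        return df
    # BH within each comparison family (all alt tests; all region_disrupt tests)
    return pd.concat([_bh(g) for _, g in df.groupby("comparison")],
                     ignore_index=True)


def group_activity_test(group_scores: Sequence[float],
                        negative_scores: Sequence[float],
                        side: str = "greater") -> float:
    """One-sided Welch t-test that a group's mean score exceeds the negatives."""
    g = np.asarray(group_scores, dtype=float)
    n = np.asarray(negative_scores, dtype=float)
    if g.size < 2 or n.size < 2:
        raise InvalidParameterError("both groups need >= 2 values")
    if np.var(g) == 0 and np.var(n) == 0:
        raise InvalidParameterError("degenerate variance in both groups")
    _, p = sps.ttest_ind(g, n, equal_var=False, alternative=side)
    return float(p)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlation of enhancer activities between groups."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rho.rename_axis("group").to_csv(path, sep="\t")


def cross_tissue_correlation(activity: pd.DataFrame,
                             value: str = "alpha",
                             min_shared: int = 10) -> CorrelationMatrix:
    """Spearman rho over paired enhancer activities for every group pair.

    Enhancers missing (or non-finite) in either group are dropped pairwise;
    cells with fewer than ``min_shared`` shared enhancers are flagged NaN.
    """
    wide = activity.pivot_table(index="enhancer_id", columns="group",
                                values=value)
    groups = list(wide.columns)
    k = len(groups)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        nmat[i, i] = int(np.isfinite(wide[groups[i]]).sum())
        for j in range(i + 1, k):
            pair = wide[[groups[i], groups[j]]].replace(
                [np.inf, -np.inf], np.nan).dropna()
            nmat[i, j] = nmat[j, i] = len(pair)
            if len(pair) < min_shared:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(groups, name="group")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=groups),
        p=pd.DataFrame(pval, index=idx, columns=groups),
        n=pd.DataFrame(nmat, index=idx, columns=groups),
    )


class PaddedSequence(NamedTuple):
    forward: str
    reverse: str


def pad_for_prediction(sequence: str, target_length: int = 500) -> PaddedSequence:
    """Center a sequence in Ns up to ``target_length``, for predictor input.

    A 120-nt enhancer padded to 500 nt receives 190 Ns on each side.  When
    the padding is odd, the extra N goes on the 5' (left) side.  The reverse
    field is the reverse complement of the padded sequence.
    """
    if target_length < len(sequence):
        raise InvalidParameterError(
            f"target_length {target_length} < sequence length {len(sequence)}")
    pad = target_length - len(sequence)
    left = pad - pad // 2
    right = pad // 2
    fwd = "N" * left + sequence + "N" * right
    return PaddedSequence(forward=fwd, reverse=reverse_complement(fwd))


def prediction_correlation(activity: pd.DataFrame, scores: pd.DataFrame,
                           value: str = "alpha") -> tuple[float, float, int]:
    """Spearman rho between measured activity and predictor scores.

    ``scores`` carries enhancer_id, score_fwd, score_rev; forward and
    reverse-complement predictions are averaged before correlating.
    Unmatched enhancer ids are reported and dropped.  Returns (rho, p, n).
    """
    required = {"enhancer_id", "score_fwd", "score_rev"}
    if not required <= set(scores.columns):
        raise InvalidParameterError(
            f"scores table missing columns {required - set(scores.columns)}")
    s = scores.copy()
    s["score"] = (s["score_fwd"] + s["score_rev"]) / 2
    act = activity[["enhancer_id", value]].dropna()
    merged = act.merge(s[["enhancer_id", "score"]], on="enhancer_id")
    dropped = set(act["enhancer_id"]).symmetric_difference(s["enhancer_id"])
    if dropped:
        logger.info("prediction_correlation: %d unmatched enhancer ids dropped",
                    len(dropped))
    if len(merged) < 3:
        raise InvalidParameterError("fewer than 3 matched enhancers")
    rho, p = sps.spearmanr(merged[value], merged["score"])
    return float(rho), float(p), len(merged)
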
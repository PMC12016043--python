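"""Enhancer activity estimation and robust scoring against negative controls.

Activity (alpha) is a library-size-normalized RNA:DNA ratio summed over an
enhancer's barcodes.  Raw activities are standardized into a *MAD score* — a
robust z-score of log(alpha) against the negative-control distribution
(median / 1.4826·MAD) — and an add-one empirical p-value against the same
null.  Scoring operates per sample and can be aggregated per tissue or per
tissue type (brain / liver / HMC3 / other) by averaging log-activities across
animals, flagging enhancers whose per-sample scores disagree in sign.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from mprakit.design import DesignTable
from mprakit.errors import (
    ConfigurationError,
    DegenerateNullError,
    InvalidParameterError,
    PairingError,
)
from mprakit.quant import CountMatrix
from mprakit.simulate import BRAIN_TISSUES

NEGATIVE_CATEGORIES = ("negative_control", "random_negative")

#: Robust-scale constant making the MAD consistent with a normal SD.
MAD_CONSISTENCY = 1.4826


def tissue_type_of(tissue: str) -> str:
    if tissue in BRAIN_TISSUES:
        return "brain"
    if tissue in ("liver", "HMC3"):
        return tissue
    return "other"


def estimate_alpha(rna: CountMatrix, dna: CountMatrix, design: DesignTable,
                   samples: pd.DataFrame, pseudocount: float = 1e-6,
                   dna_floor: int = 1) -> pd.DataFrame:
    """Per-sample, per-enhancer activity from paired RNA/DNA counts.

    For enhancer *e* in RNA sample *s* paired (same animal and tissue) with
    DNA sample *d*:

        alpha = (Σ_b RNA_eb / R_s + ε) / (Σ_b DNA_eb / D_d + ε)

    where the sums run over barcodes of *e* whose DNA count is at least
    ``dna_floor`` and R, D are the samples' accepted-read totals.  Returns a
    table with one row per (enhancer, RNA sample): columns enhancer_id,
    group, animal, tissue, alpha, log_alpha, n_barcodes_used.
    """
    if pseudocount <= 0:
        raise InvalidParameterError("pseudocount must be positive")
    meta = samples.set_index("sample_id")
    dna_by_unit = {
        (r.animal, r.tissue): r.sample_id
        for r in samples[samples["molecule"] == "DNA"].itertuples()
    }
    rna_samples = samples[samples["molecule"] == "RNA"]

    bc_index = pd.Index(rna.barcodes)
    if list(dna.barcodes) != list(bc_index):
        dna_df = dna.df.reindex(bc_index, fill_value=0)
    else:
        dna_df = dna.df
    enhancer_of = pd.Series(design.barcode_to_enhancer).reindex(bc_index)

    rows = []
    for r in rna_samples.itertuples():
        unit = (r.animal, r.tissue)
        if unit not in dna_by_unit:
            raise PairingError(
                f"no DNA sample matches RNA sample {r.sample_id} "
                f"(animal={r.animal}, tissue={r.tissue})")
        d_id = dna_by_unit[unit]
        R = rna.accepted_total(r.sample_id) or 1
        D = dna.accepted_total(d_id) or 1
        rna_col = rna.df[r.sample_id].to_numpy(dtype=float)
        dna_col = dna_df[d_id].to_numpy(dtype=float)
        use = dna_col >= dna_floor
        grp = pd.DataFrame({
            "enhancer_id": enhancer_of.to_numpy(),
            "rna": np.where(use, rna_col, 0.0),
            "dna": np.where(use, dna_col, 0.0),
            "used": use.astype(int),
        }).groupby("enhancer_id", sort=False).sum()
        grp = grp.reindex(design.enhancers["enhancer_id"], fill_value=0.0)
        alpha = (grp["rna"] / R + pseudocount) / (grp["dna"] / D + pseudocount)
        rows.append(pd.DataFrame({
            "enhancer_id": grp.index,
            "group": r.sample_id,
            "animal": r.animal,
            "tissue": r.tissue,
            "alpha": alpha.to_numpy(),
            "log_alpha": np.log(alpha.to_numpy()),
            "n_barcodes_used": grp["used"].astype(int).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def mad_score(log_alpha: np.ndarray | pd.Series,
              negative_log_alpha: np.ndarray | pd.Series) -> np.ndarray:
    """Robust z-score of log-activities against the negative-control null.

    score = (log_alpha − median(neg)) / (1.4826 × MAD(neg)).  Requires at
    least 5 finite negative-control values and a non-degenerate MAD.
    """
    neg = np.asarray(negative_log_alpha, dtype=float)
    neg = neg[np.isfinite(neg)]
    if neg.size < 5:
        raise InvalidParameterError(
            f"need >= 5 finite negative-control values, got {neg.size}")
    scale = MAD_CONSISTENCY * median_abs_deviation(neg)
    if scale == 0:
        raise DegenerateNullError("negative-control MAD is zero")
    return (np.asarray(log_alpha, dtype=float) - np.median(neg)) / scale


def empirical_pvalue(score: float | np.ndarray,
                     negative_scores: np.ndarray | pd.Series) -> np.ndarray:
    """One-sided add-one empirical p-value against negative-control scores.

    p = (1 + #{neg ≥ score}) / (1 + N); ties count against the candidate.
    """
    neg = np.asarray(negative_scores, dtype=float)
    if neg.size == 0:
        raise InvalidParameterError("empty negative-control null")
    if neg.size < 20:
        warnings.warn(
            f"only {neg.size} negative-control scores; empirical p-values "
            "are coarse", stacklevel=2)
    s = np.atleast_1d(np.asarray(score, dtype=float))
    p = (1 + (neg[None, :] >= s[:, None]).sum(axis=1)) / (1 + neg.size)
    return p if np.ndim(score) else float(p[0])


def score_activity(table: pd.DataFrame, design: DesignTable) -> pd.DataFrame:
    """Add mad_score and p_empirical columns, per group, to an activity table.

    Negative controls (categories negative_control and random_negative) form
    the null within each group; they are themselves scored against the full
    negative set.
    """
    cat = design.enhancers.set_index("enhancer_id")["category"]
    out = table.copy()
    out["category"] = out["enhancer_id"].map(cat)
    is_neg = out["category"].isin(NEGATIVE_CATEGORIES)
    scores = np.full(len(out), np.nan)
    pvals = np.full(len(out), np.nan)
    for _, idx in out.groupby("group").groups.items():
        sub = out.loc[idx]
        neg_la = sub.loc[is_neg.loc[idx], "log_alpha"]
        s = mad_score(sub["log_alpha"], neg_la)
        neg_scores = s[is_neg.loc[idx].to_numpy()]
        scores[out.index.get_indexer(idx)] = s
        pvals[out.index.get_indexer(idx)] = empirical_pvalue(s, neg_scores)
    out["mad_score"] = scores
    out["p_empirical"] = pvals
    return out.drop(columns="category")


def aggregate_activity(table: pd.DataFrame, design: DesignTable,
                       grouping: str = "tissue") -> pd.DataFrame:
    """Aggregate per-sample activities across animals.

    ``grouping`` is ``"tissue"`` or ``"tissue_type"``.  The aggregated
    log_alpha is the mean of per-sample log_alpha; MAD scores and empirical
    p-values are recomputed on the aggregated values.  ``consistent`` flags
    enhancers whose per-sample MAD scores share one sign across all samples
    of the group (flag only, nothing is filtered).
    """
    if grouping not in ("tissue", "tissue_type"):
        raise ConfigurationError(f"unknown grouping {grouping!r}")
    t = table.copy()
    if "mad_score" not in t.columns:
        t = score_activity(t, design)
    t["_g"] = (t["tissue"] if grouping == "tissue"
               else t["tissue"].map(tissue_type_of))
    agg = (t.groupby(["enhancer_id", "_g"], sort=False)
           .agg(log_alpha=("log_alpha", "mean"),
                n_barcodes_used=("n_barcodes_used", "mean"),
                n_samples=("group", "nunique"),
                sign_min=("mad_score", lambda s: np.sign(s).min()),
                sign_max=("mad_score", lambda s: np.sign(s).max()))
           .reset_index()
           .rename(columns={"_g": "group"}))
    agg["alpha"] = np.exp(agg["log_alpha"])
    agg["consistent"] = agg["sign_min"] == agg["sign_max"]
    agg = agg.drop(columns=["sign_min", "sign_max"])
    agg["tissue"] = agg["group"]
    agg["animal"] = "aggregate"
    return score_activity(agg, design)
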
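"""Estimate enhancer activity (alpha) and score it against negative controls.

Alpha is the library-size-normalized RNA:DNA ratio per enhancer; the MAD
score standardizes log(alpha) by the median and scaled median absolute
deviation of the negative controls, and an add-one empirical p-value ranks
each enhancer inside the negative-control null.
"""

from mprakit import (
    CloningModel,
    aggregate_activity,
    build_default_library,
    default_expression_model,
    estimate_alpha,
    make_sample_sheet,
    score_activity,
    simulate_cloning,
    simulate_counts,
)

design = build_default_library(seed=42, total=120, k=20)
surviving, _ = simulate_cloning(design, CloningModel(0.43), seed=1)
tissues = ("M1", "cortex", "striatum", "liver", "HMC3")
model = default_expression_model(design, tissues=tissues,
                                 dna_depth=5e4, rna_depth=5e4)
samples = make_sample_sheet(tissues, n_animals=2)
dna, rna, truth = simulate_counts(surviving, model, samples, seed=2)

per_sample = score_activity(
    estimate_alpha(rna, dna, design, samples), design)
by_tissue = aggregate_activity(per_sample, design, grouping="tissue")

meta = design.enhancers.set_index("enhancer_id")
label = meta["category"].where(
    meta["category"] != "MEF2",
    meta["variant_kind"].map(lambda k: "MEF2 (baseline)" if k == "baseline"
                             else "MEF2 (shuffled)"))
by_tissue["class"] = by_tissue["enhancer_id"].map(label)
summary = (by_tissue[by_tissue["group"].isin(["cortex", "liver"])]
           .groupby(["group", "class"])["mad_score"].median().unstack(0)
           .round(2))
print("median MAD score by enhancer class and tissue:")
print(summary)
# Brain-class enhancers (cortical, MEF2 baselines) score high in cortex and
# near zero in liver; shuffling the MEF2 motif abolishes the signal, and
# negative controls sit at ~0 everywhere by construction.
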
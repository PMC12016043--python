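"""Simulate cloning dropout and an in-vivo expression experiment.

Each designed barcode survives library cloning with probability 0.43 (the
complexity loss a real plasmid library shows), then tissue-specific
transduction and activity-driven expression generate overdispersed DNA/RNA
counts with full ground truth.
"""

import numpy as np

from mprakit import (
    CloningModel,
    build_default_library,
    default_expression_model,
    make_sample_sheet,
    simulate_cloning,
    simulate_counts,
)

design = build_default_library(seed=42, total=120, k=20)
surviving, truth = simulate_cloning(design, CloningModel(0.43), seed=1)

per_enh = [len(v) for v in surviving.enhancer_to_barcodes.values()]
print(f"designed barcodes: {len(design.barcodes)}, "
      f"surviving: {len(surviving.barcodes)} "
      f"({100 * len(surviving.barcodes) / len(design.barcodes):.1f}%)")
print(f"barcodes/enhancer: mean {np.mean(per_enh):.1f}, "
      f"range {min(per_enh)}-{max(per_enh)} "
      f"(expected mean 20 x 0.43 = 8.6)")

tissues = ("M1", "cortex", "liver", "HMC3")
model = default_expression_model(design, tissues=tissues,
                                 dna_depth=5e4, rna_depth=5e4)
samples = make_sample_sheet(tissues, n_animals=2)
dna, rna, truth = simulate_counts(surviving, model, samples, seed=2)

print(f"samples: {len(samples)} ({len(dna.samples)} DNA + {len(rna.samples)} RNA)")
print("DNA depth per sample ~", int(dna.df.sum(axis=0).mean()))
# RNA counts scale with each enhancer's tissue-specific activity, so active
# enhancers are over-represented in RNA relative to DNA.
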
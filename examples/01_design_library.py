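"""Design a barcoded enhancer library with variants and controls.

Builds a scaled-down version of the default 461-member library: GC-stratified
random negatives, MEF2-motif enhancers with shuffled versions, SNP ref/alt
pairs — each enhancer tagged by unique 16-nt barcodes behind a 27-nt linker.
"""

from collections import Counter

from mprakit import build_default_library

design = build_default_library(seed=42, total=120, k=10)

print(f"enhancers: {design.n_enhancers}, barcodes: {len(design.barcodes)}")
print("categories:", dict(Counter(design.enhancers["category"])))
print("variant kinds:", dict(Counter(design.enhancers["variant_kind"])))

oligo = design.oligos()[0]
parts = oligo.parts()
print(f"first oligo ({len(oligo.oligo)} nt): "
      f"adapter5[{len(parts['adapter5'])}] + enhancer[{len(parts['enhancer'])}] "
      f"+ linker[{len(parts['linker'])}] + barcode[{len(parts['barcode'])}] "
      f"+ adapter3[{len(parts['adapter3'])}]")
# Every barcode is ≥3 substitutions from every other, so one sequencing error
# can never turn one designed barcode into another.
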
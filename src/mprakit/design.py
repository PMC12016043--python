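"""In-silico construction of a barcoded MPRA enhancer library.

The library couples candidate enhancer sequences (120 nt by default) to short
unique DNA barcodes (16 nt) through a fixed 27-nt linker, so that sequencing
the barcode reports on the activity of the enhancer it tags.  Besides the
baseline candidates, the design carries variant lineages used for perturbation
analyses: transcription-factor motif shuffles (with or without flanking
context) and reference/alternative SNP allele pairs.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mprakit.errors import (
    AlleleMismatchError,
    BoundsError,
    CapacityError,
    InvalidParameterError,
    StructureError,
)

DNA_ALPHABET = "ACGT"
BARCODE_LENGTH = 16
LINKER_LENGTH = 27
ENHANCER_LENGTH = 120
BARCODES_PER_ENHANCER = 20
MOTIF_FLANK = 5  # nt of context shuffled together with a motif

CATEGORIES = frozenset({
    "positive_control", "negative_control", "random_negative",
    "cortical", "MEF2", "SNP", "cross_tissue",
})
VARIANT_KINDS = frozenset({
    "baseline", "motif_shuffled", "motif_flank_shuffled",
    "ref_allele", "alt_allele", "region_disrupt",
})

# Restriction site used as the extraction anchor (AscI recognition sequence);
# barcodes are screened against containing it so that anchored extraction is
# unambiguous.
RESTRICTION_SITE = "GGCGCGCC"

# Default oligo scaffold.  The linker carries the restriction site plus the
# bases adjacent to the barcode that the quality filter checks.
DEFAULT_ADAPTER5 = "ACTGGCCGCTTCACTGAGTA"
DEFAULT_LINKER = "TCGACTGCAGAC" + RESTRICTION_SITE + "AGTC" + "ACT"
DEFAULT_ADAPTER3 = "AGATCGGAAGAGCGTCGTGT"

assert len(DEFAULT_LINKER) == LINKER_LENGTH

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Return the reverse complement of a DNA string (N preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_dna(sequence: str, *, what: str = "sequence") -> None:
    if not set(sequence) <= set(DNA_ALPHABET):
        bad = sorted(set(sequence) - set(DNA_ALPHABET))
        raise InvalidParameterError(f"{what} contains non-ACGT symbols: {bad}")


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


@dataclass
class EnhancerCandidate:
    """A candidate enhancer sequence and its lineage metadata.

    ``variant_of`` points at the baseline (or reference-allele) enhancer this
    sequence was derived from; it is ``None`` exactly when ``variant_kind`` is
    ``baseline`` or ``ref_allele``.
    """

    enhancer_id: str
    sequence: str
    category: str
    target_tissue: str = ""
    variant_of: str | None = None
    variant_kind: str = "baseline"

    def __post_init__(self) -> None:
        _check_dna(self.sequence, what=f"enhancer {self.enhancer_id}")
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"unknown category {self.category!r}")
        if self.variant_kind not in VARIANT_KINDS:
            raise InvalidParameterError(f"unknown variant_kind {self.variant_kind!r}")
        is_root = self.variant_kind in ("baseline", "ref_allele")
        if is_root != (self.variant_of is None):
            raise InvalidParameterError(
                f"{self.enhancer_id}: variant_of must be null iff variant_kind "
                f"is baseline/ref_allele (got kind={self.variant_kind}, "
                f"variant_of={self.variant_of})"
            )


@dataclass(frozen=True)
class OligoRecord:
    """A fully assembled synthesis oligo: adapter5 ∥ enhancer ∥ linker ∥ barcode ∥ adapter3."""

    enhancer_id: str
    barcode: str
    oligo: str
    adapter5_len: int
    enhancer_len: int

    def parts(self, linker_len: int = LINKER_LENGTH,
              barcode_len: int = BARCODE_LENGTH) -> dict[str, str]:
        """Decompose the oligo back into its parts by fixed offsets."""
        o = self.oligo
        a5, e = self.adapter5_len, self.enhancer_len
        return {
            "adapter5": o[:a5],
            "enhancer": o[a5:a5 + e],
            "linker": o[a5 + e:a5 + e + linker_len],
            "barcode": o[a5 + e + linker_len:a5 + e + linker_len + barcode_len],
            "adapter3": o[a5 + e + linker_len + barcode_len:],
        }


class DesignTable:
    """Catalogue of enhancer↔barcode assignments with lineage metadata.

    Holds one metadata row per enhancer (so enhancers that lose every barcode
    to cloning dropout remain represented with an empty barcode set) and one
    row per (enhancer, barcode) pair.  Barcodes are globally unique.
    """

    def __init__(self, enhancers: pd.DataFrame, pairs: pd.DataFrame):
        required = {"enhancer_id", "category", "target_tissue", "variant_of",
                    "variant_kind", "sequence"}
        missing = required - set(enhancers.columns)
        if missing:
            raise InvalidParameterError(f"enhancer table missing columns {missing}")
        if enhancers["enhancer_id"].duplicated().any():
            raise InvalidParameterError("duplicate enhancer_id in design")
        if not pairs.empty:
            if pairs["barcode"].duplicated().any():
                dup = pairs.loc[pairs["barcode"].duplicated(), "barcode"].iloc[0]
                raise InvalidParameterError(f"barcode {dup} assigned twice")
            unknown = set(pairs["enhancer_id"]) - set(enhancers["enhancer_id"])
            if unknown:
                raise InvalidParameterError(f"pairs reference unknown enhancers {unknown}")
        self.enhancers = enhancers.reset_index(drop=True)
        self.pairs = pairs.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def n_enhancers(self) -> int:
        return len(self.enhancers)

    @property
    def barcodes(self) -> list[str]:
        """All barcodes, in stable design order (the whitelist)."""
        return self.pairs["barcode"].tolist()

    @property
    def barcode_to_enhancer(self) -> dict[str, str]:
        return dict(zip(self.pairs["barcode"], self.pairs["enhancer_id"]))

    @property
    def enhancer_to_barcodes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {e: [] for e in self.enhancers["enhancer_id"]}
        for e, b in zip(self.pairs["enhancer_id"], self.pairs["barcode"]):
            out[e].append(b)
        return out

    def sequence_of(self, enhancer_id: str) -> str:
        row = self.enhancers.loc[self.enhancers["enhancer_id"] == enhancer_id]
        if row.empty:
            raise KeyError(enhancer_id)
        return row["sequence"].iloc[0]

    def subset_barcodes(self, keep: Iterable[str]) -> "DesignTable":
        """Restrict to a barcode subset; enhancers with no surviving barcode stay."""
        keep = set(keep)
        pairs = self.pairs[self.pairs["barcode"].isin(keep)]
        return DesignTable(self.enhancers.copy(), pairs.copy())

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-pair view (barcode-less enhancers get one empty row)."""
        meta = self.enhancers.set_index("enhancer_id")
        rows = []
        e2b = self.enhancer_to_barcodes
        for eid in self.enhancers["enhancer_id"]:
            m = meta.loc[eid]
            bcs = e2b[eid] or [""]
            for bc in bcs:
                rows.append({
                    "enhancer_id": eid, "category": m["category"],
                    "target_tissue": m["target_tissue"],
                    "variant_of": m["variant_of"] if pd.notna(m["variant_of"]) else "",
                    "variant_kind": m["variant_kind"],
                    "sequence": m["sequence"], "barcode": bc,
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DesignTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        meta_cols = ["enhancer_id", "category", "target_tissue", "variant_of",
                     "variant_kind", "sequence"]
        enhancers = df[meta_cols].drop_duplicates("enhancer_id").copy()
        enhancers["variant_of"] = enhancers["variant_of"].replace("", None)
        pairs = df.loc[df["barcode"] != "", ["enhancer_id", "barcode"]].copy()
        return cls(enhancers, pairs)

    @classmethod
    def from_candidates(cls, candidates: Sequence[EnhancerCandidate],
                        pairs: pd.DataFrame) -> "DesignTable":
        enhancers = pd.DataFrame([{
            "enhancer_id": c.enhancer_id, "category": c.category,
            "target_tissue": c.target_tissue, "variant_of": c.variant_of,
            "variant_kind": c.variant_kind, "sequence": c.sequence,
        } for c in candidates])
        return cls(enhancers, pairs)

    def oligos(self, adapter5: str = DEFAULT_ADAPTER5,
               linker: str = DEFAULT_LINKER,
               adapter3: str = DEFAULT_ADAPTER3) -> list[OligoRecord]:
        cand = {
            r.enhancer_id: EnhancerCandidate(
                enhancer_id=r.enhancer_id, sequence=r.sequence,
                category=r.category, target_tissue=r.target_tissue,
                variant_of=r.variant_of if pd.notna(r.variant_of) else None,
                variant_kind=r.variant_kind)
            for r in self.enhancers.itertuples()
        }
        return [
            assemble_oligo(cand[eid], bc, adapter5, linker, adapter3)
            for eid, bc in zip(self.pairs["enhancer_id"], self.pairs["barcode"])
        ]

    def to_fasta(self, path: str | Path, **kwargs) -> None:
        """Write the assembled oligo library as FASTA (id = enhancer_id|barcode)."""
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(o.oligo), id=f"{o.enhancer_id}|{o.barcode}", description="")
            for o in self.oligos(**kwargs)
        ]
        seqio_write(records, str(path), "fasta")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DesignTable):
            return NotImplemented
        return (self.enhancers.equals(other.enhancers)
                and self.pairs.equals(other.pairs))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_negative_controls(count_per_level: int,
                               gc_levels: Sequence[float],
                               length: int = ENHANCER_LENGTH,
                               seed: int = 0) -> list[EnhancerCandidate]:
    """Random-sequence negative controls stratified by GC content.

    Each sequence carries exactly ``round(gc_level * length)`` G+C bases, with
    G/C and A/T chosen uniformly and positions placed uniformly at random.
    Returns ``count_per_level × len(gc_levels)`` candidates, deterministically
    for a fixed seed.
    """
    if length <= 0:
        raise InvalidParameterError("length must be positive")
    if count_per_level < 0:
        raise InvalidParameterError("count_per_level must be >= 0")
    for gc in gc_levels:
        if not 0.0 < gc < 1.0:
            raise InvalidParameterError(f"gc_level {gc} outside (0, 1)")
    rng = np.random.default_rng(seed)
    out: list[EnhancerCandidate] = []
    for gc in gc_levels:
        n_gc = round(gc * length)
        for i in range(count_per_level):
            positions = rng.permutation(length)
            bases = [""] * length
            for p in positions[:n_gc]:
                bases[p] = "GC"[rng.integers(0, 2)]
            for p in positions[n_gc:]:
                bases[p] = "AT"[rng.integers(0, 2)]
            out.append(EnhancerCandidate(
                enhancer_id=f"neg_gc{int(round(gc * 100))}_{i:02d}",
                sequence="".join(bases),
                category="random_negative",
                target_tissue="none",
            ))
    return out


def shuffle_interval(sequence: str, start: int, end: int,
                     flank: int = 0, seed: int = 0) -> str:
    """Shuffle the bases of ``[start-flank, end+flank)`` in place.

    Used to disrupt a transcription-factor binding motif while preserving the
    local base composition.  The permutation is a seeded Fisher–Yates shuffle;
    if it reproduces the input over a non-monomorphic window it is redrawn
    (at most 10 attempts) so the disruption is real.
    """
    lo, hi = start - flank, end + flank
    if not (0 <= lo and hi <= len(sequence) and start <= end):
        raise BoundsError(
            f"interval [{lo}, {hi}) outside sequence of length {len(sequence)}")
    window = list(sequence[lo:hi])
    if len(set(window)) <= 1:
        return sequence  # monomorphic window is a fixed point
    rng = np.random.default_rng(seed)
    for _ in range(10):
        perm = rng.permutation(len(window))
        shuffled = [window[i] for i in perm]
        if shuffled != window:
            break
    return sequence[:lo] + "".join(shuffled) + sequence[hi:]


def make_allele_pair(sequence: str, position: int,
                     ref_base: str, alt_base: str) -> tuple[str, str]:
    """Return (reference, alternative) sequences differing only at ``position``."""
    if not 0 <= position < len(sequence):
        raise BoundsError(f"position {position} outside sequence")
    if sequence[position] != ref_base:
        raise AlleleMismatchError(
            f"sequence has {sequence[position]!r} at {position}, "
            f"expected ref allele {ref_base!r}")
    alt = sequence[:position] + alt_base + sequence[position + 1:]
    return sequence, alt


def assign_barcodes(enhancers: Sequence[EnhancerCandidate],
                    k: int = BARCODES_PER_ENHANCER,
                    barcode_length: int = BARCODE_LENGTH,
                    min_hamming: int = 3,
                    seed: int = 0,
                    forbidden: Sequence[str] = (RESTRICTION_SITE,)) -> DesignTable:
    """Assign ``k`` globally unique barcodes to every enhancer.

    Barcodes are drawn by rejection sampling so that every pair is at Hamming
    distance ≥ ``min_hamming`` and no barcode contains a forbidden subsequence
    (by default the extraction-anchor restriction site).  Deterministic per
    seed.
    """
    if min_hamming < 1:
        raise InvalidParameterError("min_hamming must be >= 1")
    need = k * len(enhancers)
    if need == 0:
        return DesignTable.from_candidates(
            list(enhancers), pd.DataFrame(columns=["enhancer_id", "barcode"]))
    if 4 ** barcode_length < 4 * need:
        raise CapacityError(
            f"4^{barcode_length} barcodes cannot host {need} with headroom")
    rng = np.random.default_rng(seed)
    accepted = np.empty((need, barcode_length), dtype=np.uint8)
    n_acc = 0
    tried = 0
    max_tries = 60 * need
    forb = [f for f in forbidden if f]
    while n_acc < need:
        batch = rng.integers(0, 4, size=(4096, barcode_length), dtype=np.uint8)
        for cand in batch:
            tried += 1
            if tried > max_tries:
                raise CapacityError(
                    f"could not place {need} barcodes under min_hamming="
                    f"{min_hamming} within {max_tries} draws")
            if n_acc:
                d = (accepted[:n_acc] != cand).sum(axis=1).min()
                if d < min_hamming:
                    continue
            s = "".join(DNA_ALPHABET[i] for i in cand)
            if any(f in s for f in forb):
                continue
            accepted[n_acc] = cand
            n_acc += 1
            if n_acc == need:
                break
    barcodes = ["".join(DNA_ALPHABET[i] for i in row) for row in accepted]
    pairs = pd.DataFrame({
        "enhancer_id": np.repeat([c.enhancer_id for c in enhancers], k),
        "barcode": barcodes,
    })
    return DesignTable.from_candidates(list(enhancers), pairs)


def assemble_oligo(enhancer: EnhancerCandidate, barcode: str,
                   adapter5: str = DEFAULT_ADAPTER5,
                   linker: str = DEFAULT_LINKER,
                   adapter3: str = DEFAULT_ADAPTER3) -> OligoRecord:
    """Concatenate adapter5 ∥ enhancer ∥ linker ∥ barcode ∥ adapter3."""
    if len(linker) != LINKER_LENGTH:
        raise StructureError(f"linker must be {LINKER_LENGTH} nt, got {len(linker)}")
    if len(barcode) != BARCODE_LENGTH:
        raise StructureError(f"barcode must be {BARCODE_LENGTH} nt, got {len(barcode)}")
    _check_dna(barcode, what="barcode")
    oligo = adapter5 + enhancer.sequence + linker + barcode + adapter3
    return OligoRecord(
        enhancer_id=enhancer.enhancer_id, barcode=barcode, oligo=oligo,
        adapter5_len=len(adapter5), enhancer_len=len(enhancer.sequence),
    )


# ---------------------------------------------------------------------------
# Default library composition
# ---------------------------------------------------------------------------

# MEF2 family consensus core (YTAWWWWTAR); planted at the enhancer center in
# the synthetic MEF2 candidates.
MEF2_MOTIF = "CTATTTTTAG"

DEFAULT_COMPOSITION = {
    "cross_tissue": 3,
    "positive_per_tissue": 10,   # ×3 tissues (brain, liver, immune)
    "published_negatives": 10,
    "random_negatives_per_level": 10,
    "gc_levels": (0.30, 0.50, 0.70),
    "cortical": 144,
    "mef2_loci": 28,             # each with 2 shuffled versions
    "snp_loci": 27,              # each ref+alt; some with region_disrupt
    "snp_region_disrupt": 8,
    "total": 461,
}


def scaled_composition(total: int) -> dict:
    """Shrink the default category counts proportionally to a smaller total.

    Keeps every category represented (floors keep the MEF2/SNP lineages and
    the negative-control null usable) so scaled-down libraries still exercise
    the full analysis surface.
    """
    full = DEFAULT_COMPOSITION
    if total >= full["total"]:
        return dict(full, total=total)
    f = total / full["total"]
    comp = dict(full)
    comp["total"] = total
    comp["positive_per_tissue"] = max(2, round(full["positive_per_tissue"] * f))
    comp["published_negatives"] = max(2, round(full["published_negatives"] * f))
    comp["random_negatives_per_level"] = max(
        4, round(full["random_negatives_per_level"] * f))
    comp["cortical"] = max(4, round(full["cortical"] * f))
    comp["mef2_loci"] = max(3, round(full["mef2_loci"] * f))
    comp["snp_loci"] = max(3, round(full["snp_loci"] * f))
    comp["snp_region_disrupt"] = min(
        comp["snp_loci"], max(1, round(full["snp_region_disrupt"] * f)))
    # category floors can overshoot a small total; absorb in cortical slots
    members = (comp["cross_tissue"] + 3 * comp["positive_per_tissue"]
               + comp["published_negatives"]
               + comp["random_negatives_per_level"] * len(comp["gc_levels"])
               + comp["cortical"] + 3 * comp["mef2_loci"]
               + 2 * comp["snp_loci"] + comp["snp_region_disrupt"])
    overshoot = members - total
    if overshoot > 0:
        comp["cortical"] -= overshoot
        if comp["cortical"] < 0:
            raise InvalidParameterError(
                f"total {total} too small for a representative library "
                f"(minimum ≈ {members - comp['cortical'] - overshoot})")
    return comp


def build_default_library(seed: int = 0,
                          k: int = BARCODES_PER_ENHANCER,
                          min_hamming: int = 3,
                          length: int = ENHANCER_LENGTH,
                          total: int | None = None) -> DesignTable:
    """Generate the full default 461-member library with barcodes assigned.

    Composition: 3 cross-tissue viral controls, 30 tissue positive controls,
    10 published + 30 GC-stratified random negatives, 144 cortical/striatal
    candidates, 28 MEF2-motif loci each in baseline / motif-shuffled /
    motif+flank-shuffled versions, 27 SNP loci as ref/alt pairs (8 of which
    also carry a local region-disrupt version), and labelled placeholder
    candidates filling the remaining slots.
    """
    total = DEFAULT_COMPOSITION["total"] if total is None else total
    comp = scaled_composition(total)
    rng = np.random.default_rng(seed)
    cands: list[EnhancerCandidate] = []

    for i in range(comp["cross_tissue"]):
        cands.append(EnhancerCandidate(
            f"ct_{i}", random_dna(length, rng), "cross_tissue", "all"))
    for tissue in ("brain", "liver", "immune"):
        for i in range(comp["positive_per_tissue"]):
            cands.append(EnhancerCandidate(
                f"pos_{tissue}_{i:02d}", random_dna(length, rng),
                "positive_control", tissue))
    for i in range(comp["published_negatives"]):
        cands.append(EnhancerCandidate(
            f"neg_pub_{i:02d}", random_dna(length, rng),
            "negative_control", "none"))
    cands.extend(generate_negative_controls(
        comp["random_negatives_per_level"], list(comp["gc_levels"]),
        length=length, seed=int(rng.integers(2 ** 31))))
    for i in range(comp["cortical"]):
        cands.append(EnhancerCandidate(
            f"cort_{i:03d}", random_dna(length, rng), "cortical", "brain"))

    # MEF2 loci: plant the motif at the center, derive two shuffled versions.
    motif_len = len(MEF2_MOTIF)
    m_start = (length - motif_len) // 2
    m_end = m_start + motif_len
    for i in range(comp["mef2_loci"]):
        base = random_dna(length, rng)
        base = base[:m_start] + MEF2_MOTIF + base[m_end:]
        bid = f"mef2_{i:02d}"
        cands.append(EnhancerCandidate(bid, base, "MEF2", "brain"))
        cands.append(EnhancerCandidate(
            f"{bid}_shuf", shuffle_interval(base, m_start, m_end, flank=0,
                                            seed=int(rng.integers(2 ** 31))),
            "MEF2", "brain", variant_of=bid, variant_kind="motif_shuffled"))
        cands.append(EnhancerCandidate(
            f"{bid}_flankshuf",
            shuffle_interval(base, m_start, m_end, flank=MOTIF_FLANK,
                             seed=int(rng.integers(2 ** 31))),
            "MEF2", "brain", variant_of=bid, variant_kind="motif_flank_shuffled"))

    # SNP loci: center position ref/alt pair; first few also region-disrupted.
    pos = length // 2
    for i in range(comp["snp_loci"]):
        seq = random_dna(length, rng)
        ref_base = seq[pos]
        alt_base = rng.choice([b for b in DNA_ALPHABET if b != ref_base])
        ref_seq, alt_seq = make_allele_pair(seq, pos, ref_base, str(alt_base))
        sid = f"snp_{i:02d}"
        cands.append(EnhancerCandidate(
            f"{sid}_ref", ref_seq, "SNP", "brain", variant_kind="ref_allele"))
        cands.append(EnhancerCandidate(
            f"{sid}_alt", alt_seq, "SNP", "brain",
            variant_of=f"{sid}_ref", variant_kind="alt_allele"))
        if i < comp["snp_region_disrupt"]:
            cands.append(EnhancerCandidate(
                f"{sid}_disrupt",
                shuffle_interval(ref_seq, pos, pos + 1, flank=MOTIF_FLANK,
                                 seed=int(rng.integers(2 ** 31))),
                "SNP", "brain", variant_of=f"{sid}_ref",
                variant_kind="region_disrupt"))

    # Placeholder candidates fill the library to its designed size.
    n_fill = total - len(cands)
    if n_fill < 0:
        raise InvalidParameterError(
            f"composition exceeds total ({len(cands)} > {total})")
    for i in range(n_fill):
        cands.append(EnhancerCandidate(
            f"placeholder_{i:03d}", random_dna(length, rng), "cortical", "brain"))

    return assign_barcodes(cands, k=k, min_hamming=min_hamming,
                           seed=int(rng.integers(2 ** 31)))
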
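"""Anchor-filtered barcode extraction and count-matrix construction.

Amplicon reads carry a fixed layout: a restriction-site anchor, a few bases
adjacent to the barcode, the 16-nt barcode itself, then downstream adapter
sequence.  A read is counted only if the anchor matches, the adjacent bases
match, and the extracted 16-mer resolves uniquely against the design
whitelist — the "high-quality barcode read" rule.  By default all three
matches are exact; mismatch tolerances are configurable.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from mprakit.design import (
    BARCODE_LENGTH,
    DEFAULT_ADAPTER3,
    DEFAULT_LINKER,
    DNA_ALPHABET,
    DesignTable,
)
from mprakit.errors import ConfigurationError, InvalidParameterError

REJECTION_REASONS = (
    "too_short", "anchor_fail", "flank_fail",
    "barcode_unmatched", "barcode_ambiguous",
)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AnchorSpec:
    """Read-layout contract for barcode extraction.

    The read starts with ``anchor_sequence`` (the designed restriction-enzyme
    site plus context), followed by ``left_flank`` (the bases adjacent to the
    barcode on its 5' side), the barcode, and ``right_flank`` on its 3' side.
    """

    anchor_sequence: str = DEFAULT_LINKER[12:24]
    left_flank: str = DEFAULT_LINKER[24:27]
    right_flank: str = DEFAULT_ADAPTER3[:3]
    barcode_length: int = BARCODE_LENGTH
    max_anchor_mismatches: int = 0
    max_barcode_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_anchor_mismatches < 0 or self.max_barcode_mismatches < 0:
            raise InvalidParameterError("mismatch allowances must be >= 0")

    @property
    def barcode_offset(self) -> int:
        return len(self.anchor_sequence) + len(self.left_flank)

    @property
    def span(self) -> int:
        """Minimum read length required for extraction."""
        return self.barcode_offset + self.barcode_length + len(self.right_flank)

    def read_prefix(self) -> str:
        return self.anchor_sequence + self.left_flank


class Whitelist:
    """Design barcodes with exact and Hamming-tolerant lookup."""

    def __init__(self, barcodes: Sequence[str]):
        self.barcodes = list(barcodes)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InvalidParameterError("whitelist contains duplicate barcodes")
        self._exact = {b: b for b in self.barcodes}
        self._encoded: np.ndarray | None = None
        self._cache: dict[tuple[str, int], tuple[str | None, str]] = {}

    def __len__(self) -> int:
        return len(self.barcodes)

    def _ensure_encoded(self) -> np.ndarray:
        if self._encoded is None:
            lut = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate(DNA_ALPHABET):
                lut[ord(b)] = i
            self._encoded = np.vstack([
                lut[np.frombuffer(b.encode(), dtype=np.uint8)]
                for b in self.barcodes
            ])
        return self._encoded

    def match(self, seq: str, max_mismatches: int = 0) -> tuple[str | None, str]:
        """Resolve a 16-mer to a whitelist barcode.

        Returns ``(barcode, "ok")`` on a unique match within the allowance,
        else ``(None, reason)`` with reason ``barcode_unmatched`` or
        ``barcode_ambiguous`` (two whitelist barcodes tied at minimum
        distance).
        """
        hit = self._exact.get(seq)
        if hit is not None:
            return hit, "ok"
        if max_mismatches == 0:
            return None, "barcode_unmatched"
        key = (seq, max_mismatches)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        enc = self._ensure_encoded()
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(DNA_ALPHABET):
            lut[ord(b)] = i
        q = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        dists = (enc != q).sum(axis=1)
        d = int(dists.min())
        if d > max_mismatches:
            result: tuple[str | None, str] = (None, "barcode_unmatched")
        elif int((dists == d).sum()) > 1:
            result = (None, "barcode_ambiguous")
        else:
            result = (self.barcodes[int(dists.argmin())], "ok")
        self._cache[key] = result
        return result


def extract_barcode(read: str, spec: AnchorSpec,
                    whitelist: Whitelist | Sequence[str]) -> str:
    """Extract and resolve the barcode from one read.

    Returns the whitelist barcode on success, otherwise one of the rejection
    reasons ``too_short``, ``anchor_fail``, ``flank_fail``,
    ``barcode_unmatched`` or ``barcode_ambiguous``.
    """
    if not isinstance(whitelist, Whitelist):
        whitelist = Whitelist(whitelist)
    if len(read) < spec.span:
        return "too_short"
    anc = spec.anchor_sequence
    if _hamming(read[:len(anc)], anc) > spec.max_anchor_mismatches:
        return "anchor_fail"
    off = spec.barcode_offset
    left = read[len(anc):off]
    right = read[off + spec.barcode_length:
                 off + spec.barcode_length + len(spec.right_flank)]
    if (_hamming(left, spec.left_flank) > spec.max_anchor_mismatches
            or _hamming(right, spec.right_flank) > spec.max_anchor_mismatches):
        return "flank_fail"
    bc = read[off:off + spec.barcode_length]
    hit, reason = whitelist.match(bc, spec.max_barcode_mismatches)
    return hit if hit is not None else reason


@dataclass
class CountMatrix:
    """Per-sample barcode counts for one molecule type (DNA or RNA).

    ``df`` is barcodes (whitelist order) × samples; ``tallies`` records, per
    sample, accepted reads and per-reason rejections so that column sums can
    be audited against total input reads.
    """

    df: pd.DataFrame
    molecule: str
    tallies: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        if self.molecule not in ("DNA", "RNA"):
            raise InvalidParameterError("molecule must be DNA or RNA")

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.df.index)

    def accepted_total(self, sample: str) -> int:
        """Accepted reads for a sample (tally if present, else column sum)."""
        if not self.tallies.empty and sample in self.tallies.index:
            return int(self.tallies.loc[sample, "accepted"])
        return int(self.df[sample].sum())

    @classmethod
    def from_barcode_sets(cls, sets: Mapping[str, Iterable[str]],
                          whitelist: Sequence[str],
                          molecule: str = "DNA") -> "CountMatrix":
        """Presence/absence matrix (count 1) from per-sample barcode sets."""
        df = pd.DataFrame(0, index=list(whitelist), columns=list(sets), dtype=int)
        for sample, bcs in sets.items():
            df.loc[list(set(bcs) & set(whitelist)), sample] = 1
        return cls(df=df, molecule=molecule)

    def to_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("barcode").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, molecule: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="barcode")
        return cls(df=df, molecule=molecule)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_barcodes(sample_sheet: pd.DataFrame | str | Path,
                   spec: AnchorSpec,
                   whitelist: Whitelist | Sequence[str],
                   fastq_root: str | Path | None = None,
                   ) -> dict[str, CountMatrix]:
    """Count whitelist barcodes per sample from FASTQ files.

    ``sample_sheet`` needs columns sample_id, animal, tissue, molecule
    (DNA|RNA) and fastq_path; returns one :class:`CountMatrix` per molecule
    type present, with per-sample acceptance/rejection tallies.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = pd.read_csv(sample_sheet, sep="\t", dtype=str)
    if not isinstance(whitelist, Whitelist):
        whitelist = Whitelist(whitelist)
    required = {"sample_id", "molecule", "fastq_path"}
    if not required <= set(sample_sheet.columns):
        raise ConfigurationError(
            f"sample sheet missing columns {required - set(sample_sheet.columns)}")

    index = {b: i for i, b in enumerate(whitelist.barcodes)}
    per_molecule: dict[str, dict[str, np.ndarray]] = {}
    tallies: dict[str, dict[str, dict[str, int]]] = {}
    for row in sample_sheet.itertuples():
        path = Path(row.fastq_path)
        if fastq_root is not None and not path.is_absolute():
            path = Path(fastq_root) / path
        if not path.exists():
            raise FileNotFoundError(
                f"sample {row.sample_id}: FASTQ not found at {path}")
        counts = np.zeros(len(whitelist), dtype=np.int64)
        tally = {r: 0 for r in REJECTION_REASONS}
        tally.update(accepted=0, total=0)
        with _open_text(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                tally["total"] += 1
                result = extract_barcode(seq, spec, whitelist)
                if result in REJECTION_REASONS:
                    tally[result] += 1
                else:
                    counts[index[result]] += 1
                    tally["accepted"] += 1
        per_molecule.setdefault(row.molecule, {})[row.sample_id] = counts
        tallies.setdefault(row.molecule, {})[row.sample_id] = tally

    out: dict[str, CountMatrix] = {}
    for mol, cols in per_molecule.items():
        df = pd.DataFrame(cols, index=whitelist.barcodes)
        tl = pd.DataFrame(tallies[mol]).T
        out[mol] = CountMatrix(df=df, molecule=mol, tallies=tl)
    return out


def detected_from_proportion(proportion: float, union_size: int) -> int:
    """Detected-barcode count implied by a detection proportion of the union."""
    return math.floor(proportion * union_size)


@dataclass
class ComplexityReport:
    """Library complexity, coverage and transduction summary."""

    per_sample: pd.DataFrame            # sample, detected, proportion
    union_size: int                     # high-quality barcode union across samples
    n_designed: int
    complexity: float                   # union_size / n_designed
    per_enhancer_detected: pd.Series    # detected barcodes per enhancer
    barcode_stats: dict                 # min / mean / max over enhancers with >=1
    enhancer_coverage: float            # fraction of enhancers with >=1 detected
    effective_barcodes_per_enhancer: float
    transduction_rate: float
    detection_threshold: int

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "union_size": self.union_size,
            "n_designed": self.n_designed,
            "complexity": self.complexity,
            "barcode_stats": self.barcode_stats,
            "enhancer_coverage": self.enhancer_coverage,
            "effective_barcodes_per_enhancer": self.effective_barcodes_per_enhancer,
            "transduction_rate": self.transduction_rate,
            "detection_threshold": self.detection_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def complexity_metrics(dna: CountMatrix, design: DesignTable,
                       effective_barcodes_per_enhancer: float | None = None,
                       detection_threshold: int = 1) -> ComplexityReport:
    """Summarize barcode complexity and transduction from DNA counts.

    A barcode is *detected* in a sample when its count reaches
    ``detection_threshold``.  The high-quality union is the set of barcodes
    detected in at least one sample; per-sample proportions are taken relative
    to that union.  The transduction rate follows the convention
    union / (n_enhancers × effective barcodes per enhancer), where the
    effective number defaults to the rounded observed mean per enhancer.
    """
    if design.n_enhancers == 0 or not design.barcodes:
        raise InvalidParameterError("design has no enhancers or no barcodes")
    counts = dna.df
    detected_mask = counts >= detection_threshold
    union_mask = detected_mask.any(axis=1)
    union_size = int(union_mask.sum())
    per_sample = pd.DataFrame({
        "sample": counts.columns,
        "detected": detected_mask.sum(axis=0).to_numpy(),
    })
    per_sample["proportion"] = (
        per_sample["detected"] / union_size if union_size else 0.0)

    b2e = design.barcode_to_enhancer
    detected_barcodes = set(counts.index[union_mask])
    per_enhancer = pd.Series(
        0, index=design.enhancers["enhancer_id"], dtype=int)
    for bc in detected_barcodes:
        eid = b2e.get(bc)
        if eid is not None:
            per_enhancer[eid] += 1
    covered = per_enhancer[per_enhancer > 0]
    stats = {
        "min": int(covered.min()) if len(covered) else 0,
        "mean": float(per_enhancer.mean()),
        "max": int(covered.max()) if len(covered) else 0,
    }
    coverage = float((per_enhancer > 0).mean())
    if effective_barcodes_per_enhancer is None:
        effective_barcodes_per_enhancer = round(union_size / design.n_enhancers)
    denom = design.n_enhancers * effective_barcodes_per_enhancer
    transduction = union_size / denom if denom else 0.0
    return ComplexityReport(
        per_sample=per_sample,
        union_size=union_size,
        n_designed=len(design.barcodes),
        complexity=union_size / len(design.barcodes),
        per_enhancer_detected=per_enhancer,
        barcode_stats=stats,
        enhancer_coverage=coverage,
        effective_barcodes_per_enhancer=float(effective_barcodes_per_enhancer),
        transduction_rate=float(transduction),
        detection_threshold=detection_threshold,
    )
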
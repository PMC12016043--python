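"""Generative model of a systemic MPRA experiment with ground truth.

The simulator reproduces the stages that shape real reporter data:

1. *Cloning dropout* — each designed barcode survives library assembly
   independently with probability ``survival_prob`` (default 0.43, i.e. a 57%
   dropout), so a 20-barcode enhancer retains on average 8.6 barcodes.
2. *Transduction* — in each animal × tissue, only a tissue-specific fraction
   of surviving barcodes is delivered (muscle and heart are deliberately
   handicapped to mimic poor viral delivery).
3. *Expression* — DNA counts are overdispersed (gamma–Poisson) around an even
   share of the sample's sequencing depth; RNA counts share the DNA mean
   scaled by the enhancer's tissue-specific activity alpha.  RNA depends on
   DNA only through its mean (conditional independence).
4. *Amplicon reads* — each counted barcode molecule is emitted as a read with
   the anchored layout expected by the extraction step, with independent
   per-base substitution errors.

Every stage records its ground truth so downstream estimates can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mprakit.design import DNA_ALPHABET, DesignTable
from mprakit.errors import ConfigurationError, InvalidParameterError
from mprakit.quant import AnchorSpec, CountMatrix

#: Default tissue panel: five brain regions, five peripheral tissues, and a
#: cultured microglia-like cell line.
DEFAULT_TISSUES = (
    "M1", "cortex", "striatum", "hippocampus", "hypothalamus",
    "liver", "kidney", "lung", "muscle", "heart", "HMC3",
)
BRAIN_TISSUES = frozenset({"M1", "cortex", "striatum", "hippocampus", "hypothalamus"})

#: Tissues with deliberately reduced viral delivery in the default model.
LOW_TRANSDUCTION = {"muscle": 0.5, "heart": 0.5}
DEFAULT_TRANSDUCTION = 0.95


@dataclass(frozen=True)
class CloningModel:
    """Independent per-barcode survival through library cloning."""

    survival_prob: float = 0.43

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_prob <= 1.0:
            raise InvalidParameterError("survival_prob must be in (0, 1]")


@dataclass
class ExpressionModel:
    """Tissue-structured activity and count-generation parameters.

    ``alpha`` is an enhancers × tissues table of true activities, with
    inactive enhancers at ``baseline_alpha``.  ``dispersion`` is the
    gamma–Poisson shape parameter (larger = closer to Poisson).  Expected RNA
    count per barcode is (expected DNA count) × alpha / baseline_alpha scaled
    to ``rna_depth``.
    """

    alpha: pd.DataFrame
    dispersion: float = 10.0
    dna_depth: float = 2e5
    rna_depth: float = 2e5
    transduction: Mapping[str, float] = field(default_factory=dict)
    baseline_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be positive")
        if (self.alpha.to_numpy() < 0).any():
            raise InvalidParameterError("activities must be non-negative")

    @property
    def tissues(self) -> list[str]:
        return list(self.alpha.columns)

    def transduction_of(self, tissue: str) -> float:
        return float(self.transduction.get(tissue, DEFAULT_TRANSDUCTION))


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator for validation."""

    designed: set[str] = field(default_factory=set)
    surviving: set[str] = field(default_factory=set)
    transduced: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    alpha_true: pd.DataFrame | None = None
    seed: int | None = None

    def validate_containment(self) -> None:
        assert self.surviving <= self.designed
        for bcs in self.transduced.values():
            assert bcs <= self.surviving


def default_expression_model(design: DesignTable,
                             tissues: Sequence[str] = DEFAULT_TISSUES,
                             active_fold: float = 10.0,
                             snp_alt_fold: float = 4.0,
                             n_snp_effect_loci: int = 8,
                             **kwargs) -> ExpressionModel:
    """Build the default strong-effect activity structure from a design.

    Brain-class candidates (cortical, MEF2 baselines, brain positive
    controls) are active at ``active_fold`` × baseline in brain tissues and
    HMC3; liver positives in liver; immune positives in HMC3 (plus weakly in
    liver); motif-shuffled variants fall back to baseline (the motif carries
    the activity); the first ``n_snp_effect_loci`` SNP alt alleles gain
    ``snp_alt_fold`` × the ref activity in brain and HMC3 but not liver.
    Everything else sits at baseline.
    """
    base = kwargs.get("baseline_alpha", 1.0)
    alpha = pd.DataFrame(
        base, index=design.enhancers["enhancer_id"], columns=list(tissues),
        dtype=float)
    brain_cols = [t for t in tissues if t in BRAIN_TISSUES]
    meta = design.enhancers
    for row in meta.itertuples():
        eid, cat, kind, tt = (row.enhancer_id, row.category,
                              row.variant_kind, row.target_tissue)
        if cat == "cross_tissue":
            alpha.loc[eid, :] = active_fold * base
        elif cat == "positive_control":
            if tt == "brain":
                alpha.loc[eid, brain_cols] = active_fold * base
                if "HMC3" in tissues:
                    alpha.loc[eid, "HMC3"] = active_fold * base
            elif tt == "liver" and "liver" in tissues:
                alpha.loc[eid, "liver"] = active_fold * base
            elif tt == "immune" and "HMC3" in tissues:
                alpha.loc[eid, "HMC3"] = active_fold * base
                if "liver" in tissues:
                    alpha.loc[eid, "liver"] = 0.5 * active_fold * base
        elif cat == "cortical" and not eid.startswith("placeholder"):
            alpha.loc[eid, brain_cols] = active_fold * base
        elif cat == "MEF2":
            if kind == "baseline":
                alpha.loc[eid, brain_cols] = active_fold * base
                if "HMC3" in tissues:
                    alpha.loc[eid, "HMC3"] = 0.5 * active_fold * base
            # shuffled versions stay at baseline: the motif carries the signal
        elif cat == "SNP":
            locus = int(eid.split("_")[1]) if "_" in eid else 0
            if kind == "alt_allele" and locus < n_snp_effect_loci:
                cols = brain_cols + (["HMC3"] if "HMC3" in tissues else [])
                alpha.loc[eid, cols] = snp_alt_fold * base
    transduction = dict(LOW_TRANSDUCTION)
    transduction.update(kwargs.get("transduction", {}))
    return ExpressionModel(
        alpha=alpha,
        dispersion=kwargs.get("dispersion", 10.0),
        dna_depth=kwargs.get("dna_depth", 2e5),
        rna_depth=kwargs.get("rna_depth", 2e5),
        transduction=transduction,
        baseline_alpha=base,
    )


def make_sample_sheet(tissues: Sequence[str] = DEFAULT_TISSUES,
                      n_animals: int = 2,
                      molecules: Sequence[str] = ("DNA", "RNA"),
                      fastq_dir: str | Path | None = None) -> pd.DataFrame:
    """Sample sheet with one DNA and one RNA sample per animal × tissue."""
    rows = []
    for a in range(1, n_animals + 1):
        animal = f"animal{a}"
        for tissue in tissues:
            for mol in molecules:
                sid = f"{animal}_{tissue}_{mol}"
                rows.append({
                    "sample_id": sid, "animal": animal, "tissue": tissue,
                    "molecule": mol,
                    "fastq_path": (str(Path(fastq_dir) / f"{sid}.fastq")
                                   if fastq_dir is not None else f"{sid}.fastq"),
                })
    return pd.DataFrame(rows)


def simulate_cloning(design: DesignTable, model: CloningModel = CloningModel(),
                     seed: int = 0) -> tuple[DesignTable, SimulationTruth]:
    """Drop each barcode independently with probability 1 − survival_prob."""
    rng = np.random.default_rng(seed)
    barcodes = design.barcodes
    keep_mask = rng.random(len(barcodes)) < model.survival_prob
    surviving = {b for b, k in zip(barcodes, keep_mask) if k}
    truth = SimulationTruth(
        designed=set(barcodes), surviving=surviving, seed=seed)
    return design.subset_barcodes(surviving), truth


def _gamma_poisson(rng: np.random.Generator, mean: np.ndarray,
                   dispersion: float) -> np.ndarray:
    """Overdispersed counts: Poisson with gamma-distributed rate."""
    mean = np.asarray(mean, dtype=float)
    rates = np.zeros_like(mean)
    pos = mean > 0
    rates[pos] = rng.gamma(shape=dispersion, scale=mean[pos] / dispersion)
    return rng.poisson(rates)


def expected_rna_mean(model: ExpressionModel, alpha_value: float,
                      n_transduced: int) -> float:
    """Analytic expected RNA count per transduced barcode."""
    if n_transduced == 0:
        return 0.0
    return (model.rna_depth / n_transduced) * alpha_value / model.baseline_alpha


def simulate_counts(surviving: DesignTable, model: ExpressionModel,
                    samples: pd.DataFrame, seed: int = 0,
                    ) -> tuple[CountMatrix, CountMatrix, SimulationTruth]:
    """Generate DNA and RNA count matrices over the sample sheet.

    Transduction draws one barcode subset per (animal, tissue); the DNA and
    RNA samples of that pair share it.  DNA counts are gamma–Poisson around
    dna_depth / n_transduced; RNA counts are gamma–Poisson around the DNA
    mean × alpha / baseline scaled to rna_depth.
    """
    for tissue in samples["tissue"].unique():
        if tissue not in model.tissues:
            raise ConfigurationError(f"tissue {tissue!r} not in expression model")
    rng = np.random.default_rng(seed)
    barcodes = surviving.barcodes
    n_bc = len(barcodes)
    b2e = surviving.barcode_to_enhancer
    enhancer_of = np.array([b2e[b] for b in barcodes])
    alpha_of = {t: model.alpha[t].to_dict() for t in model.tissues}

    truth = SimulationTruth(
        designed=set(barcodes), surviving=set(barcodes),
        alpha_true=model.alpha.copy(), seed=seed)
    transduced_mask: dict[tuple[str, str], np.ndarray] = {}
    for key in samples[["animal", "tissue"]].drop_duplicates().itertuples(index=False):
        animal, tissue = key
        frac = model.transduction_of(tissue)
        n_trans = int(round(frac * n_bc))
        mask = np.zeros(n_bc, dtype=bool)
        if n_trans:
            mask[rng.choice(n_bc, size=n_trans, replace=False)] = True
        transduced_mask[(animal, tissue)] = mask
        truth.transduced[(animal, tissue)] = {
            b for b, m in zip(barcodes, mask) if m}

    dna_cols: dict[str, np.ndarray] = {}
    rna_cols: dict[str, np.ndarray] = {}
    for row in samples.itertuples():
        mask = transduced_mask[(row.animal, row.tissue)]
        n_trans = int(mask.sum())
        mean = np.zeros(n_bc)
        if n_trans:
            mean[mask] = model.dna_depth / n_trans
        if row.molecule == "DNA":
            dna_cols[row.sample_id] = _gamma_poisson(rng, mean, model.dispersion)
        elif row.molecule == "RNA":
            a = np.array([alpha_of[row.tissue][e] for e in enhancer_of])
            rna_mean = (mean / model.dna_depth * model.rna_depth
                        * a / model.baseline_alpha)
            rna_cols[row.sample_id] = _gamma_poisson(rng, rna_mean, model.dispersion)
        else:
            raise ConfigurationError(f"unknown molecule {row.molecule!r}")

    def _matrix(cols: dict[str, np.ndarray], mol: str) -> CountMatrix:
        df = pd.DataFrame(cols, index=barcodes, dtype=int)
        tallies = pd.DataFrame({
            "total": df.sum(axis=0), "accepted": df.sum(axis=0),
        })
        for reason in ("too_short", "anchor_fail", "flank_fail",
                       "barcode_unmatched", "barcode_ambiguous"):
            tallies[reason] = 0
        return CountMatrix(df=df, molecule=mol, tallies=tallies)

    return _matrix(dna_cols, "DNA"), _matrix(rna_cols, "RNA"), truth


def _mutate_reads(reads: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply independent per-base substitutions to an array of encoded reads."""
    if error_rate <= 0:
        return reads
    hit = rng.random(reads.shape) < error_rate
    # substitute with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
    out = reads.copy()
    out[hit] = (out[hit] + shift[hit]) % 4
    return out


def emit_amplicon_reads(counts: CountMatrix, design: DesignTable,
                        spec: AnchorSpec, outdir: str | Path,
                        error_rate: float = 0.0, seed: int = 0,
                        read_tail: str | None = None,
                        quality_char: str = "I") -> dict[str, Path]:
    """Write per-sample FASTQ files realizing a count matrix.

    Each barcode contributes exactly its count in reads laid out as
    anchor ∥ left flank ∥ barcode ∥ right flank ∥ tail, with independent
    per-base substitution errors at ``error_rate``.  Deterministic per seed.
    Returns {sample_id: fastq path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(DNA_ALPHABET):
        lut[ord(b)] = i
    if read_tail is None:
        # default tail continues into downstream adapter sequence
        from mprakit.design import DEFAULT_ADAPTER3
        read_tail = DEFAULT_ADAPTER3[len(spec.right_flank):]
    prefix = spec.read_prefix()
    suffix = spec.right_flank + read_tail
    templates = {
        bc: lut[np.frombuffer((prefix + bc + suffix).encode(), dtype=np.uint8)]
        for bc in counts.barcodes
    }
    read_len = len(prefix) + spec.barcode_length + len(suffix)
    qual = quality_char * read_len
    base_arr = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)

    paths: dict[str, Path] = {}
    for sample in counts.samples:
        col = counts.df[sample]
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for bc_idx, (bc, n) in enumerate(col.items()):
                n = int(n)
                if n == 0:
                    continue
                block = np.tile(templates[bc], (n, 1))
                block = _mutate_reads(block, error_rate, rng)
                chars = base_arr[block]
                for j in range(n):
                    seq = chars[j].tobytes().decode()
                    fh.write(f"@{sample}:{bc_idx}:{j}\n{seq}\n+\n{qual}\n")
        paths[sample] = path
    return paths
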
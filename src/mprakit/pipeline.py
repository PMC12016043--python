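"""End-to-end orchestration: design → simulate → count → score → test.

All randomness flows from one master seed; rerunning with an identical
config produces byte-identical outputs.  Every stage writes plain-text
artifacts (TSV/JSON/FASTQ) under the configured output directory and the run
manifest records versions, the config hash and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mprakit
from mprakit.activity import aggregate_activity, estimate_alpha, score_activity
from mprakit.design import DesignTable, build_default_library
from mprakit.errors import ConfigurationError
from mprakit.quant import (
    AnchorSpec,
    CountMatrix,
    Whitelist,
    complexity_metrics,
    count_barcodes,
)
from mprakit.simulate import (
    DEFAULT_TISSUES,
    CloningModel,
    default_expression_model,
    emit_amplicon_reads,
    make_sample_sheet,
    simulate_cloning,
    simulate_counts,
)
from mprakit.stats import (
    allelic_test,
    cross_tissue_correlation,
    group_activity_test,
    motif_disruption_test,
)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic run."""

    outdir: str = "mprakit_run"
    seed: int = 0
    # library design
    total_enhancers: int = 461
    barcodes_per_enhancer: int = 20
    min_hamming: int = 3
    # simulation
    survival_prob: float = 0.43
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    n_animals: int = 2
    dna_depth: float = 2e5
    rna_depth: float = 2e5
    dispersion: float = 10.0
    active_fold: float = 10.0
    error_rate: float = 0.001
    # quantification / scoring
    max_anchor_mismatches: int = 0
    max_barcode_mismatches: int = 0
    detection_threshold: int = 1
    pseudocount: float = 1e-6
    dna_floor: int = 1
    fdr_level: float = 0.05
    mad_flag_level: float = 1.3
    grouping: str = "tissue"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def anchor_spec(self) -> AnchorSpec:
        return AnchorSpec(max_anchor_mismatches=self.max_anchor_mismatches,
                          max_barcode_mismatches=self.max_barcode_mismatches)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31, size=n)]


def stage_design(cfg: PipelineConfig, outdir: Path, seed: int) -> DesignTable:
    design = build_default_library(
        seed=seed, k=cfg.barcodes_per_enhancer, min_hamming=cfg.min_hamming,
        total=cfg.total_enhancers)
    design.to_tsv(outdir / "design.tsv")
    return design


def stage_simulate(cfg: PipelineConfig, outdir: Path, design: DesignTable,
                   seeds: list[int]) -> pd.DataFrame:
    surviving, clone_truth = simulate_cloning(
        design, CloningModel(cfg.survival_prob), seed=seeds[0])
    surviving.to_tsv(outdir / "surviving_design.tsv")
    model = default_expression_model(
        design, tissues=cfg.tissues, active_fold=cfg.active_fold,
        dispersion=cfg.dispersion, dna_depth=cfg.dna_depth,
        rna_depth=cfg.rna_depth)
    fastq_dir = outdir / "fastq"
    samples = make_sample_sheet(cfg.tissues, cfg.n_animals, fastq_dir=fastq_dir)
    samples.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    dna, rna, truth = simulate_counts(surviving, model, samples, seed=seeds[1])
    model.alpha.rename_axis("enhancer_id").to_csv(
        outdir / "truth_alpha.tsv", sep="\t")
    pd.Series(sorted(clone_truth.surviving), name="barcode").to_csv(
        outdir / "truth_surviving_barcodes.tsv", sep="\t", index=False)
    spec = cfg.anchor_spec()
    emit_amplicon_reads(dna, surviving, spec, fastq_dir,
                        error_rate=cfg.error_rate, seed=seeds[2])
    emit_amplicon_reads(rna, surviving, spec, fastq_dir,
                        error_rate=cfg.error_rate, seed=seeds[3])
    dna.to_tsv(outdir / "sim_counts_dna.tsv")
    rna.to_tsv(outdir / "sim_counts_rna.tsv")
    return samples


def stage_count(cfg: PipelineConfig, outdir: Path, design: DesignTable,
                samples: pd.DataFrame) -> dict[str, CountMatrix]:
    matrices = count_barcodes(samples, cfg.anchor_spec(),
                              Whitelist(design.barcodes))
    for mol, cm in matrices.items():
        cm.to_tsv(outdir / f"counts_{mol.lower()}.tsv")
        cm.tallies.rename_axis("sample").to_csv(
            outdir / f"tallies_{mol.lower()}.tsv", sep="\t")
    report = complexity_metrics(matrices["DNA"], design,
                                detection_threshold=cfg.detection_threshold)
    report.to_json(outdir / "complexity.json")
    return matrices


def stage_activity(cfg: PipelineConfig, outdir: Path, design: DesignTable,
                   samples: pd.DataFrame,
                   matrices: dict[str, CountMatrix]) -> dict[str, pd.DataFrame]:
    per_sample = estimate_alpha(matrices["RNA"], matrices["DNA"], design,
                                samples, pseudocount=cfg.pseudocount,
                                dna_floor=cfg.dna_floor)
    per_sample = score_activity(per_sample, design)
    by_tissue = aggregate_activity(per_sample, design, grouping="tissue")
    by_type = aggregate_activity(per_sample, design, grouping="tissue_type")
    per_sample.to_csv(outdir / "activity_per_sample.tsv", sep="\t", index=False)
    by_tissue.to_csv(outdir / "activity_by_tissue.tsv", sep="\t", index=False)
    by_type.to_csv(outdir / "activity_by_tissue_type.tsv", sep="\t", index=False)
    return {"per_sample": per_sample, "by_tissue": by_tissue, "by_type": by_type}


def stage_test(cfg: PipelineConfig, outdir: Path, design: DesignTable,
               tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    per_sample = tables["per_sample"]
    disruption_tissues = [t for t in ("M1", "cortex", "striatum")
                          if t in cfg.tissues] or None
    disruption = motif_disruption_test(per_sample, design,
                                       tissues=disruption_tissues)
    allelic = allelic_test(per_sample, design)
    disruption.to_csv(outdir / "disruption_tests.tsv", sep="\t", index=False)
    allelic.to_csv(outdir / "allelic_tests.tsv", sep="\t", index=False)

    # one-sided group tests: each positive-control class vs the negatives,
    # within each aggregated tissue-type group
    by_type = tables["by_type"]
    cat = design.enhancers.set_index("enhancer_id")["category"]
    tt = design.enhancers.set_index("enhancer_id")["target_tissue"]
    rows = []
    for group, sub in by_type.groupby("group"):
        sub = sub.set_index("enhancer_id")
        neg = sub.loc[cat.reindex(sub.index).isin(
            ["negative_control", "random_negative"]), "mad_score"].dropna()
        for label, mask in {
            "positive_brain": (cat == "positive_control") & (tt == "brain"),
            "positive_liver": (cat == "positive_control") & (tt == "liver"),
            "positive_immune": (cat == "positive_control") & (tt == "immune"),
            "MEF2_baseline": (cat == "MEF2")
                & (design.enhancers.set_index("enhancer_id")["variant_kind"]
                   == "baseline"),
        }.items():
            ids = mask[mask].index.intersection(sub.index)
            vals = sub.loc[ids, "mad_score"].dropna()
            if len(vals) < 2 or len(neg) < 2:
                continue
            rows.append({
                "group": group, "enhancer_class": label, "n": len(vals),
                "p": group_activity_test(vals, neg),
            })
    group_tests = pd.DataFrame(rows)
    group_tests.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)

    corr = cross_tissue_correlation(tables["by_tissue"])
    corr.to_tsv(outdir / "correlation_by_tissue.tsv")
    return {"disruption": disruption, "allelic": allelic,
            "group_tests": group_tests, "correlation": corr}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the output bundle plus a run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    design = stage_design(cfg, outdir, seeds[4])
    samples = stage_simulate(cfg, outdir, design, seeds)
    matrices = stage_count(cfg, outdir, design, samples)
    tables = stage_activity(cfg, outdir, design, samples, matrices)
    results = stage_test(cfg, outdir, design, tables)

    accepted = {
        mol: {s: cm.accepted_total(s) for s in cm.samples}
        for mol, cm in matrices.items()
    }
    manifest = {
        "mprakit_version": mprakit.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "records": {
            "n_enhancers": design.n_enhancers,
            "n_barcodes_designed": len(design.barcodes),
            "n_activity_rows": len(tables["per_sample"]),
            "n_disruption_units": len(results["disruption"]),
            "n_allelic_units": len(results["allelic"]),
        },
        "accepted_reads": accepted,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"design": design, "samples": samples, "matrices": matrices,
            "tables": tables, "results": results, "manifest": manifest}
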
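"""Shared fixtures: a scaled-down library and one simulated experiment.

Session-scoped because library design and count simulation are the expensive
steps; tests must not mutate these objects.
"""

import pandas as pd
import pytest

from mprakit import (
    CloningModel,
    build_default_library,
    default_expression_model,
    make_sample_sheet,
    simulate_cloning,
    simulate_counts,
    score_activity,
    estimate_alpha,
)
from mprakit.quant import AnchorSpec

SIM_TISSUES = ("M1", "cortex", "striatum", "liver", "HMC3")


@pytest.fixture(scope="session")
def design60():
    """Scaled 60-enhancer library with 5 barcodes each."""
    return build_default_library(seed=11, total=60, k=5)


@pytest.fixture(scope="session")
def design_full():
    """The full 461-enhancer, 20-barcodes-per-enhancer library."""
    return build_default_library(seed=2024)


@pytest.fixture(scope="session")
def spec():
    return AnchorSpec()


@pytest.fixture(scope="session")
def sim(design60):
    """Strong-effect simulated experiment on the small library."""
    model = default_expression_model(
        design60, tissues=SIM_TISSUES, dna_depth=5e4, rna_depth=5e4)
    samples = make_sample_sheet(SIM_TISSUES, n_animals=2)
    surviving, clone_truth = simulate_cloning(design60, CloningModel(0.7), seed=5)
    dna, rna, truth = simulate_counts(surviving, model, samples, seed=7)
    return {
        "design": design60, "model": model, "samples": samples,
        "surviving": surviving, "clone_truth": clone_truth,
        "dna": dna, "rna": rna, "truth": truth,
    }


@pytest.fixture(scope="session")
def scored(sim):
    """Per-sample activity table with MAD scores and empirical p-values."""
    table = estimate_alpha(sim["rna"], sim["dna"], sim["design"], sim["samples"])
    with pd.option_context("mode.chained_assignment", None):
        return score_activity(table, sim["design"])
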
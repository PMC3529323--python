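"""Shared fixtures: small synthetic compendia generated at test time."""

import numpy as np
import pandas as pd
import pytest

import retromap as rm
from retromap.simulate import SyntheticConfig, generate_compendium


@pytest.fixture(scope="session")
def small_compendium():
    """A quick 400-gene, 3+3-experiment compendium with strong effects."""
    cfg = SyntheticConfig(
        n_genes=400,
        n_mito_experiments=3,
        n_chloro_experiments=3,
        n_replicates=3,
        frac_shared=0.1,
        frac_mito_specific=0.1,
        frac_chloro_specific=0.1,
        respond_prob=1.0,
        effect_size_log2=2.0,
        noise_sd_log2=0.25,
        absent_prob=0.02,
        seed=11,
    )
    return generate_compendium(cfg)


@pytest.fixture(scope="session")
def small_calls(small_compendium):
    """Differential calls and recurrence counts for the small compendium."""
    comp = small_compendium
    de = rm.call_compendium(comp.expression, comp.presence)
    calls, classes = rm.response_matrix(de, comp.truth.experiment_classes)
    counts = rm.recurrence_counts(calls, classes)
    return de, calls, classes, counts


@pytest.fixture(scope="session")
def benchmark_compendium():
    """The full-scale benchmark world: 14 mito + 13 chloro experiments,
    2000 genes, planted effect 2 log2-units over noise sd 0.25, three
    replicates, respond probability 0.7."""
    cfg = SyntheticConfig(
        n_genes=2000,
        n_mito_experiments=14,
        n_chloro_experiments=13,
        n_replicates=3,
        effect_size_log2=2.0,
        noise_sd_log2=0.25,
        respond_prob=0.7,
        seed=20,
    )
    return generate_compendium(cfg)


@pytest.fixture(scope="session")
def benchmark_counts(benchmark_compendium):
    comp = benchmark_compendium
    de = rm.call_compendium(comp.expression, comp.presence)
    calls, classes = rm.response_matrix(de, comp.truth.experiment_classes)
    counts = rm.recurrence_counts(calls, classes)
    return de, calls, classes, counts
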
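import numpy as np
import pytest

from clonotrace.simulate import (CNVEvent, SampleSpec, SimulationConfig,
                                 build_genome, default_marker_config,
                                 plant_clonal_architecture, simulate_counts)


@pytest.fixture(scope="session")
def small_genome():
    return build_genome(n_chromosomes=4, genes_per_chromosome=60, seed=0)


@pytest.fixture(scope="session")
def small_experiment(small_genome):
    """Two-sample experiment with two subclones and clear planted events.

    Clone P is truncal-only apart from a deletion; clone Q adds a private
    amplification.  Q expands from 10% at diagnosis to 80% at relapse.
    """
    g = small_genome.genes
    chr2 = g[g["chromosome"] == "chr2"]
    chr3 = g[g["chromosome"] == "chr3"]
    events_p = [CNVEvent("chr2", int(chr2.iloc[5]["start"]), int(chr2.iloc[45]["end"]), 1)]
    events_q = [CNVEvent("chr3", int(chr3.iloc[10]["start"]), int(chr3.iloc[50]["end"]), 4)]
    subclones = plant_clonal_architecture(small_genome, [
        ("P", None, events_p, {"Dg": 0.9, "Rel": 0.2}),
        ("Q", "P", events_q, {"Dg": 0.1, "Rel": 0.8}),
    ])
    config = SimulationConfig(
        samples={
            "Dg": SampleSpec("diagnosis", {"B": 60, "CD8T": 40, "malignant": 250}),
            "Rel": SampleSpec("relapse", {"B": 60, "CD8T": 40, "malignant": 250}),
        },
        seed=11,
    )
    return simulate_counts(small_genome, subclones, config)


@pytest.fixture(scope="session")
def small_norm(small_experiment):
    from clonotrace.preprocess import log_normalize

    return log_normalize(small_experiment.counts)
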
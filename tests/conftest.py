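import numpy as np
import pytest

from netosc.synthgen import (ExperimentDesign, GeneModel, SynchronyModel,
                             build_gene_models, simulate_experiment)

ALL_CONTINUE = {c: "continue" for c in
                ("WT", "CDK_ON", "CDK_OFF", "REP_CHECKPOINT",
                 "SPINDLE_CHECKPOINT", "REP_CHECKPOINT_RAD53OFF")}


@pytest.fixture
def sync_perfect():
    """Zero-dispersion population: bulk trace equals the single-cell profile."""
    return SynchronyModel(initial_phase=0.0, initial_sd=0.0, period=120.0,
                          dispersion_rate=0.0, bud_phase=0.25)


@pytest.fixture
def sync_default():
    return SynchronyModel(initial_phase=0.05, initial_sd=0.03, period=100.0,
                          dispersion_rate=0.05, bud_phase=0.3)


@pytest.fixture
def gene_periodic():
    return GeneModel(gene_id="gP", baseline=1.0, amplitude=8.0, peak_phase=0.5,
                     concentration=5.0, regulon="SFF", programs=dict(ALL_CONTINUE))


@pytest.fixture
def gene_flat():
    return GeneModel(gene_id="gF", baseline=2.0, amplitude=0.0, peak_phase=0.0,
                     concentration=0.0, regulon="OTHER", programs=dict(ALL_CONTINUE))


@pytest.fixture
def small_matrix(sync_default, gene_periodic, gene_flat):
    """One periodic plus a few flat genes, noiseless, 19 points."""
    extra = [GeneModel(gene_id=f"gF{i}", baseline=0.5 + i, amplitude=0.0,
                       peak_phase=0.0, concentration=0.0, regulon="OTHER",
                       programs=dict(ALL_CONTINUE)) for i in range(3)]
    design = ExperimentDesign(condition="WT", dt=20.0, total_time=360.0,
                              noise_cv=0.0, seed=0)
    return simulate_experiment([gene_periodic, gene_flat] + extra,
                               sync_default, design)
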
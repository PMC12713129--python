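"""Shared fixtures: simulated datasets are generated once per session.

Fixture parameters are pinned here; tests assert against them, so changing
a parameter means re-deriving the frozen expectations in the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from scrhythm.hurdle import rhythm_call, timepoint_shift_contrasts
from scrhythm.io import PipelineConfig
from scrhythm.pseudobulk import de_between_timepoints
from scrhythm.simulate import SimConfig, simulate_cell_counts

# the standard rhythm-recovery fixture: 4 timepoints x 3 replicates x 400
# cells/sample, 10% rhythmic genes, peak-to-trough log2FC 0.7 (>= 0.6)
STANDARD_CONFIG = SimConfig(
    n_genes=300,
    n_cell_types=1,
    rhythmic_fraction=0.1,
    amplitude_log2=0.35,
    cells_per_sample_per_type=(400, 400),
    baseline_log_mean=0.7,
    baseline_log_sd=0.8,
    dropout_midpoint=-1.0,
    nb_dispersion=0.3,
    seed=7,
)

# null fixtures: realistic low per-cell expression keeps the pseudobulk
# Wald test in its Poisson-dominated, well-calibrated regime
NULL_PB_CONFIG = SimConfig(
    n_genes=2000,
    n_cell_types=1,
    rhythmic_fraction=0.0,
    cells_per_sample_per_type=(150, 150),
    baseline_log_mean=-0.7,
    baseline_log_sd=1.0,
    dropout_midpoint=-2.0,
    nb_dispersion=0.3,
    seed=11,
)

NULL_HURDLE_CONFIG = SimConfig(
    n_genes=2000,
    n_cell_types=1,
    rhythmic_fraction=0.0,
    cells_per_sample_per_type=(100, 100),
    baseline_log_mean=-0.7,
    baseline_log_sd=1.0,
    dropout_midpoint=-2.0,
    nb_dispersion=0.3,
    seed=11,
)


@pytest.fixture(scope="session")
def standard_sim():
    return simulate_cell_counts(STANDARD_CONFIG)


@pytest.fixture(scope="session")
def standard_calls(standard_sim):
    ccm, _ = standard_sim
    return rhythm_call(ccm, PipelineConfig())


@pytest.fixture(scope="session")
def null_pb_de():
    ccm, _ = simulate_cell_counts(NULL_PB_CONFIG)
    return de_between_timepoints(ccm, 0.0, 12.0)


@pytest.fixture(scope="session")
def null_hurdle_contrasts():
    ccm, _ = simulate_cell_counts(NULL_HURDLE_CONFIG)
    return timepoint_shift_contrasts(ccm, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
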
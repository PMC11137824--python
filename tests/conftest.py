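"""Shared fixtures.

The expensive end-to-end artifacts (relaxed toy clusters, the desk-scale
protocol report) are session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest

from espec import (ForceFieldParams, ProtocolConfig, WaterTopology,
                   run_paper_protocol, toy_cluster)


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def water2(ff):
    """Relaxed two-water cluster (hydrogen-bonded dimer)."""
    return toy_cluster(2, seed=7, ff=ff)


@pytest.fixture(scope="session")
def water8(ff):
    return toy_cluster(8, seed=1, ff=ff)


@pytest.fixture(scope="session")
def desk_report():
    """One desk-scale run of the full protocol (simulate -> GSTA -> spectra).

    Several physics-direction tests read different slices of this report;
    running the pipeline once keeps the suite fast.
    """
    cfg = ProtocolConfig(seed=1, scale_factors=(0.9, 1.1))
    return run_paper_protocol(cfg)
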
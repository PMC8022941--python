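import pytest

from gapweaver.gap_filler import GapFillConfig, run_gapfill
from gapweaver.genome_model import find_gaps
from gapweaver.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_bundle():
    """Error-free desk-scale fixture (no anomalies)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def anomaly_bundle():
    """One of each planted anomaly."""
    return simulate(
        SimulationConfig(
            seed=7, translocated_fills=1, nonlinear_contigs=1, uncovered_fills=1
        )
    )


@pytest.fixture(scope="session")
def default_gapfill(default_bundle):
    b = default_bundle
    gaps = find_gaps(b.reference)
    return gaps, run_gapfill(b.reference, gaps, b.donors, b.donor_paf, GapFillConfig())


@pytest.fixture(scope="session")
def anomaly_gapfill(anomaly_bundle):
    b = anomaly_bundle
    gaps = find_gaps(b.reference)
    return gaps, run_gapfill(b.reference, gaps, b.donors, b.donor_paf, GapFillConfig())
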
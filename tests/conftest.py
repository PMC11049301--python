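import numpy as np
import pytest

from commutakit import (MeterModel, ReplicateTable, SimulationConfig,
                        StabilitySeries)


@pytest.fixture
def textbook_table() -> ReplicateTable:
    """Three vials x two replicates with hand-checkable sums of squares."""
    return ReplicateTable("B1", [("v1", [98, 100]), ("v2", [101, 103]),
                                 ("v3", [97, 99])])


@pytest.fixture
def duplicate_table_factory():
    """Balanced duplicate tables with prescribed per-vial variances.

    A duplicate pair (m - d/2, m + d/2) has variance d^2/2, so the
    factory realises any variance vector exactly.
    """

    def make(variances, mean=100.0):
        rows = []
        for i, v in enumerate(variances):
            d = float(np.sqrt(2.0 * v))
            rows.append((f"v{i+1}", [mean - d / 2, mean + d / 2]))
        return ReplicateTable("B1", rows)

    return make


@pytest.fixture
def default_design_series() -> StabilitySeries:
    """Zero-drift series on the standard checkpoint grid (5 vials/day)."""
    cfg = SimulationConfig(seed=7, drift_slope=0.0)
    from commutakit import gen_stability
    return gen_stability(cfg, 120.0)


@pytest.fixture
def identity_meter() -> MeterModel:
    return MeterModel("identity", slope=1.0, intercept=0.0,
                      cv_prop=0.0, sd_const=0.0)
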
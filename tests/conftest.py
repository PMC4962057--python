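"""Shared fixtures: one simulated selection experiment reused across the suite.

The simulated N20U experiment (40k control reads, 20k selected per stage) is
session-scoped because the 30SIC stage folds every unique construct; computing
it once keeps the whole suite fast while giving every planted-signal test the
same ground-truth data.
"""

import pytest

import riboselect as rb
from riboselect import simulate

CONTROL_N = 40_000
SELECTED_N = 20_000
SEED = 101


@pytest.fixture(scope="session")
def n20u() -> rb.LibraryDesign:
    return rb.get_design("N20U")


@pytest.fixture(scope="session")
def n20d() -> rb.LibraryDesign:
    return rb.get_design("N20D")


@pytest.fixture(scope="session")
def control_n20u() -> rb.ReadSet:
    return simulate.make_control_library("N20U", CONTROL_N, seed=SEED)


@pytest.fixture(scope="session")
def selected_30s(control_n20u) -> rb.ReadSet:
    return simulate.select_reads(
        control_n20u, rb.SelectionModel.preset("30S"), SELECTED_N, seed=SEED + 1
    )


@pytest.fixture(scope="session")
def selected_30sic(control_n20u) -> rb.ReadSet:
    return simulate.select_reads(
        control_n20u, rb.SelectionModel.preset("30SIC"), SELECTED_N, seed=SEED + 2
    )
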
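"""Shared fixtures: printed substitution tables and small simulated cohorts."""

import logging

import pytest

from cystivar.variant_core import ClassCrossTab

logging.getLogger("cystivar").setLevel(logging.ERROR)

# Published 4x4 substitution counts (rows: wild-type class hydrophobic/
# polar/positive/negative; columns: mutant class, same order).
B0AT_CROSSTAB_CELLS = (
    (20, 10, 12, 3),
    (5, 0, 1, 1),
    (2, 1, 1, 1),
    (0, 0, 0, 1),
)
RBAT_CROSSTAB_CELLS = (
    (17, 15, 13, 4),
    (10, 2, 6, 2),
    (10, 5, 2, 0),
    (3, 1, 4, 0),
)


@pytest.fixture(scope="session")
def b0at_crosstab() -> ClassCrossTab:
    """58 b(0+)AT point mutations cross-tabulated by amino-acid class."""
    return ClassCrossTab.from_array(B0AT_CROSSTAB_CELLS)


@pytest.fixture(scope="session")
def rbat_crosstab() -> ClassCrossTab:
    """94 rBAT point mutations cross-tabulated by amino-acid class."""
    return ClassCrossTab.from_array(RBAT_CROSSTAB_CELLS)


@pytest.fixture(scope="session")
def default_simulation():
    """One default-config simulation shared by read-only tests."""
    from cystivar.synthetic_data import SimulationConfig, simulate

    config = SimulationConfig(seed=42)
    variants, patients = simulate(config)
    return config, variants, patients
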
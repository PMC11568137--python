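"""Shared fixtures. Expensive synthetic artifacts are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from mpoct.geometry import OCTGeometry
from mpoct.quantify.table import assemble_table
from mpoct.synthgen.cohort import simulate_cohort


@pytest.fixture(scope="session")
def geometry() -> OCTGeometry:
    return OCTGeometry()


@pytest.fixture(scope="session")
def iso10_geometry() -> OCTGeometry:
    """Isotropic 10 um pixel spacing (201 x 201 over ~6.94 deg)."""
    side_deg = 2000.0 / 288.0
    return OCTGeometry(n_bscans=201, n_ascans=201,
                       field_deg=(side_deg, side_deg), um_per_deg=288.0)


@pytest.fixture(scope="session")
def cohort20():
    """Default direct-mode 20-patient cohort (the calibrated setting)."""
    return simulate_cohort(20, seed=1)


@pytest.fixture(scope="session")
def table20(cohort20):
    return assemble_table(cohort20)


@pytest.fixture(scope="session")
def rendered_patient():
    """One patient with fundus images rendered, for registration tests."""
    cohort = simulate_cohort(1, seed=3, render_fundus=True)
    return cohort.patients[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
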
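"""Shared fixtures: apparatus geometry and a fitted conversion model.

Everything is generated programmatically; the conversion model is fitted
once per session because several modules consume it.
"""

import numpy as np
import pytest

import seedfall as sf


@pytest.fixture(scope="session")
def geometry():
    return sf.ApparatusGeometry()


@pytest.fixture(scope="session")
def calibration_table(geometry):
    return sf.generate_calibration(geometry)


@pytest.fixture(scope="session")
def conversion_model(calibration_table):
    return sf.fit_conversion(calibration_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
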
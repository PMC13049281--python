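"""Shared fixtures: the six-waveform study protocol is expensive to build
(spectral analysis per waveform), so it is session-scoped."""

import numpy as np
import pytest

import ogsekit as ok

#: Printed protocol table: label -> (total time ms, peak frequency Hz, G mT/m)
PRINTED = {
    "90Hz-N3": (80.0, 88.3, 465.0),
    "65Hz-N2": (79.9, 62.5, 326.0),
    "30Hz-N1": (77.3, 23.2, 137.0),
    "40Hz-N1": (84.1, 34.0, 213.0),
    "50Hz-N1": (67.9, 42.2, 303.0),
    "60Hz-N1": (56.9, 51.6, 405.0),
}


@pytest.fixture(scope="session")
def protocol():
    return ok.study_protocol()


@pytest.fixture(scope="session")
def operator(protocol):
    return ok.ForwardOperator(protocol)


@pytest.fixture(scope="session")
def gm_median():
    return ok.PRESETS["GM_median"].params


@pytest.fixture(scope="session")
def wm_median():
    return ok.PRESETS["WM_median"].params
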
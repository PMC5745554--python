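"""Shared fixtures: model specs and expensive session-scoped results."""

import pytest
from hypothesis import settings

import templig as tl

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def chirality_spec():
    return tl.chirality_model()


@pytest.fixture(scope="session")
def regio_spec():
    return tl.regioselectivity_model()


@pytest.fixture(scope="session")
def chirality_kc():
    """Critical k_lig of the chirality model at the study conditions.

    Session-scoped: shared between the transition-location check and the
    maximum-length ordering check.
    """
    from templig.scans import find_critical
    res = find_critical(tl.chirality_model(), bracket=(1.0, 10.0), tol=0.05)
    return res.value
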
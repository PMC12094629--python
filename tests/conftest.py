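"""Shared fixtures: synthetic cohorts reused across test modules.

Cohort generation and the connectivity pipeline dominate test runtime, so
the two expensive cohorts (a null cohort and a strongly separable one) are
built once per session via the package's experiment builders.
"""

from __future__ import annotations

import logging

import pytest
from hypothesis import settings

from eegsync.experiments import make_null_cohort, make_separable_cohort

logging.getLogger("eegsync").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def null_cohort():
    """20 IA + 20 HC with no couplings: no true group difference anywhere."""
    config, tensors, labels = make_null_cohort(seed=11)
    return {"config": config, "tensors": tensors, "labels": labels}


@pytest.fixture(scope="session")
def separable_cohort():
    """Full-size cohort (42 IA + 50 HC) with strength-ratio-4 couplings."""
    config, tensors, labels = make_separable_cohort(seed=5)
    return {"config": config, "tensors": tensors, "labels": labels}
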
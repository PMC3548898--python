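"""Shared fixtures: one large calibrated synthetic cohort and derived models.

The 20,000-candidate cohort is the workhorse for parameter-recovery,
discrimination-ordering, and calibration tests; building it once per session
keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from meldkit.cohort import outcomes_at_horizon
from meldkit.derive import SplitSpec, derive_extension, split_cohort
from meldkit.scores import default_models, score_frame
from meldkit.simulate import SimParams, simulate_cohort

COHORT_SEED = 42
SPLIT_SEED = 7


@pytest.fixture(scope="session")
def sim_params() -> SimParams:
    return SimParams(n=20_000, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort20k(sim_params):
    return simulate_cohort(sim_params)


@pytest.fixture(scope="session")
def split20k(cohort20k):
    return split_cohort(cohort20k, SplitSpec(seed=SPLIT_SEED))


@pytest.fixture(scope="session")
def derived_models(split20k):
    """Albumin extensions derived from the derivation half (with their fits)."""
    der, _ = split20k
    m5, f5 = derive_extension(der, base="meldna")
    ma, fa = derive_extension(der, base="meld")
    return {"5v": (m5, f5), "meld_albumin": (ma, fa)}


@pytest.fixture(scope="session")
def validation_scores(split20k, derived_models):
    """Integer scores of all four models plus outcomes on the validation half."""
    _, val = split20k
    models = default_models()
    oh = outcomes_at_horizon(val, 90.0)
    out = {
        "meld": score_frame(val, models["meld"])["score"].to_numpy(),
        "meldna": score_frame(val, models["meldna"])["score"].to_numpy(),
        "5v": score_frame(val, derived_models["5v"][0])["score"].to_numpy(),
        "meld_albumin": score_frame(val, derived_models["meld_albumin"][0])["score"].to_numpy(),
        "time": oh["time"].to_numpy(),
        "event": oh["event"].to_numpy(),
    }
    assert all(np.isfinite(out[k]).all() for k in ("meld", "meldna", "5v"))
    return out
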
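"""Shared fixtures: hand-built small cohorts and session-scoped presets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from promkit import OHS, PairedCohort, generate_cohort, preset
from promkit.cohort import COMORBIDITIES, TRANSITION_LEVELS
from promkit.instruments import InstrumentSpec


def make_cohort(
    pre,
    post,
    transition=None,
    instrument: InstrumentSpec = OHS,
    joint: str = "hip",
    period=None,
    **extra_columns,
) -> PairedCohort:
    """Build a PairedCohort directly from score vectors (test helper)."""
    n = len(pre)
    if transition is None:
        transition = ["much better"] * n
    if period is None:
        period = ["2009-2011"] * n
    df = pd.DataFrame(
        {
            "patient_id": [f"T{i + 1:04d}" for i in range(n)],
            "joint": joint,
            "instrument": instrument.name,
            "pre_score": np.asarray(pre, float),
            "post_score": np.asarray(post, float),
            "transition": list(transition),
            "age": extra_columns.pop("age", [65.0] * n),
            "gender": extra_columns.pop("gender", ["female"] * n),
            **{c: extra_columns.pop(c, [0] * n) for c in COMORBIDITIES},
            "period": list(period),
        }
    )
    return PairedCohort(df, instrument, joint)


def random_cohort(rng: np.random.Generator, n: int = 40) -> PairedCohort:
    """A random but valid OHS cohort covering all transition levels."""
    pre = rng.integers(2, 35, n).astype(float)
    post = np.clip(pre + rng.normal(15, 9, n).round(), 0, 48)
    transition = list(rng.choice(TRANSITION_LEVELS, n, p=[0.5, 0.2, 0.1, 0.1, 0.1]))
    # guarantee every level appears (RI/SES need the anchor strata)
    for i, level in enumerate(TRANSITION_LEVELS):
        transition[i] = level
        transition[i + 5] = level
    period = list(rng.choice(["2009-2011", "2012-2015"], n))
    return make_cohort(pre, post, transition, period=period)


@pytest.fixture(scope="session")
def hip_ohs_50k() -> PairedCohort:
    return generate_cohort(preset("hip-ohs", n=50_000, seed=1))


@pytest.fixture(scope="session")
def knee_oks_50k() -> PairedCohort:
    return generate_cohort(preset("knee-oks", n=50_000, seed=1))


@pytest.fixture(scope="session")
def hip_eq5d_50k() -> PairedCohort:
    return generate_cohort(preset("hip-eq5d", n=50_000, seed=1))


@pytest.fixture
def small_cohort() -> PairedCohort:
    return random_cohort(np.random.default_rng(42), n=40)


def boxcox_regression_cohort(theta: float, n: int, seed: int) -> PairedCohort:
    """Cohort whose post-score follows a known Box-Cox regression.

    T(post + 1; theta) = b0 + b1 * pre + N(0, sigma^2), with scales chosen
    per theta so the response stays in a realistic score range.
    """
    from scipy.special import inv_boxcox

    params = {
        1.0: dict(beta=(1.0, 0.25), sigma=0.4),
        0.5: dict(beta=(1.0, 0.25), sigma=0.4),
        0.0: dict(beta=(0.3, 0.075), sigma=0.12),
    }[theta]
    rng = np.random.default_rng(seed)
    pre = rng.uniform(5, 40, n)
    eta = params["beta"][0] + params["beta"][1] * pre
    eta = eta + params["sigma"] * rng.standard_normal(n)
    y = np.exp(eta) if theta == 0 else inv_boxcox(eta, theta)
    return make_cohort(pre, y - 1.0)
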
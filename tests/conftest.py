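"""Shared fixtures.

The heavy cross-validation studies (cohort generation + CNN training) are
session-scoped so the acceptance tests can share one computation per study.
Study seeds are fixed constants.
"""

from __future__ import annotations

import numpy as np
import pytest

from ripplelearn.studies import (
    ad_null_cohort,
    run_study,
    signature_only_cohort,
    wt_shift_cohort,
    wt_signature_cohort,
)

#: fixed study seeds (one per replicate)
AD_SEED = 101
WT_SEEDS = (201, 202, 203)
SIG_SEEDS = (301, 302, 303)
SIGONLY_SEEDS = (401, 402, 403)


@pytest.fixture(scope="session")
def ad_study():
    """AD-like null: identical condition distributions, 10 sessions."""
    cohort = ad_null_cohort(seed=AD_SEED)
    return run_study(cohort, ("full",), n_sessions=10, master_seed=AD_SEED)["full"]


@pytest.fixture(scope="session")
def wt_studies():
    """WT-like (10-Hz shift) replicates: full windows + ripple-zeroed windows."""
    return [
        run_study(
            wt_shift_cohort(seed=s),
            ("full", "surround_only"),
            n_sessions=3,
            master_seed=s,
        )
        for s in WT_SEEDS
    ]


@pytest.fixture(scope="session")
def signature_studies():
    """Shift + peri-signature replicates: full vs frequency-equalized training."""
    return [
        run_study(
            wt_signature_cohort(seed=s),
            ("full", "equalized_freq"),
            n_sessions=3,
            master_seed=s,
        )
        for s in SIG_SEEDS
    ]


@pytest.fixture(scope="session")
def signature_only_studies():
    """No frequency shift; class information only in the head/tail signature."""
    return [
        run_study(
            signature_only_cohort(seed=s),
            ("full", "swr_only"),
            n_sessions=3,
            master_seed=s,
        )
        for s in SIGONLY_SEEDS
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
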
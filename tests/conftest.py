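"""Shared fixtures: small synthetic objects reused across test modules.

Everything is generated programmatically with fixed seeds; the heavier
cohort fixtures are session-scoped so their cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegcrit.banding import Envelope
from eegcrit.simulate import (
    BistableProfile,
    CohortSpec,
    CoupledProfile,
    FractionalProfile,
    gen_cohort,
    gen_envelope_series,
    gen_subject,
)

SEG_SECONDS = (49.4, 60.0, 60.0, 60.0, 49.4)


@pytest.fixture(scope="session")
def fractional_envelope():
    """One 278.8-s five-segment envelope with Hurst 0.75."""
    return gen_envelope_series(FractionalProfile(hurst=0.75), fs=100.0, rng=101)


@pytest.fixture(scope="session")
def coupled_envelope_zero():
    """Decoupled (rho = 0) envelope passing the DFA gate."""
    return gen_envelope_series(CoupledProfile(rho=0.0), fs=100.0, rng=202)


@pytest.fixture(scope="session")
def bistable_envelope():
    """Strongly bimodal envelope (mode separation 100x, w_hi = 0.4)."""
    profile = BistableProfile(mu_lo=1.0, mu_hi=100.0, w_hi=0.4, dwell=0.4)
    return gen_envelope_series(profile, fs=100.0, rng=303)


def envelope_from_array(arr: np.ndarray, fs: float = 100.0, band=(8.0, 13.0)) -> Envelope:
    """Wrap a raw positive array as a single-segment Envelope."""
    return Envelope(
        data=np.atleast_2d(arr), fs=fs, band=band,
        segment_lengths=[np.atleast_2d(arr).shape[1]], edge_trim=0.0,
    )


@pytest.fixture(scope="session")
def tiny_subject():
    """One 4-channel subject with two implanted bands (fast to analyze)."""
    profiles = {
        (8.0, 13.0): BistableProfile(mu_lo=1.0, mu_hi=30.0, w_hi=0.35, dwell=0.4),
        (4.0, 8.0): FractionalProfile(hurst=0.8),
    }
    return gen_subject(profiles, fs=200.0, rng=404, n_channels=4, subject_id="T001")


@pytest.fixture(scope="session")
def mini_cohort():
    """Six-subject cohort with one implanted bistability effect."""
    spec = CohortSpec(
        n_hc=3, n_mdd=3, n_channels=1, fs=200.0,
        effects={(4, "bis"): -1.0}, seed=77,
    )
    return gen_cohort(spec)
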
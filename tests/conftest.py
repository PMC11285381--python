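from datetime import datetime

import numpy as np
import pytest

from circacp.io import ActigraphySeries


def make_series(values, epoch_s=60, subject_id="S1", start=None):
    return ActigraphySeries(
        subject_id=subject_id,
        start_time=start or datetime(2024, 1, 1, 0, 0),
        epoch_s=epoch_s,
        values=np.asarray(values, dtype=float),
    )


@pytest.fixture
def cosine_series():
    """Noiseless cosinor curve: mes=300, amp=250, phi=900, T=1440, 3 days."""
    t = np.arange(4320, dtype=float)
    y = 300.0 + 250.0 * np.cos((t - 900.0) * 2.0 * np.pi / 1440.0)
    return make_series(y)


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated subjects at generator defaults (shared, read-only)."""
    from circacp.synth import simulate_cohort

    return simulate_cohort(n_subjects=5, seed=1234)
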
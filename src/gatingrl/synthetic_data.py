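"""The rat behavioral fixture and synthetic cohort generation.

The only empirical input to the whole analysis is the per-animal number of
training sessions to criterion for the six rats, plus summary facts about
their session structure.  Synthetic cohorts — model-generated
sessions-to-criterion samples at arbitrary parameters — stand in for animal
cohorts in parameter-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiment import Criterion, SessionSchedule, sessions_to_criterion_array, simulate_runs
from .fitting import GaussianSummary, gaussian_from_samples
from .presets import OperatingPoint

#: Per-rat sessions to the 85% x 3 acquisition criterion (six animals).
RAT_SESSIONS_TO_CRITERION = (17, 19, 20, 21, 22, 25)

#: Rats ran 36 +/- 4 trials per session, with balanced starts.
RAT_TRIALS_PER_SESSION_MEAN = 36
RAT_TRIALS_PER_SESSION_SD = 4

#: Session spans of the two phases of the experiment.
RAT_PRE_REVERSAL_SESSIONS = (1, 25)
RAT_POST_REVERSAL_SESSIONS = (26, 37)


def rat_fixture_frame() -> pd.DataFrame:
    """The fixture as a tidy table (one row per animal)."""
    return pd.DataFrame({
        "animal": [f"rat{i + 1}" for i in range(len(RAT_SESSIONS_TO_CRITERION))],
        "sessions_to_criterion": RAT_SESSIONS_TO_CRITERION,
    })


def rat_target() -> GaussianSummary:
    """Gaussian fitting target recomputed from the six fixture values."""
    return gaussian_from_samples(RAT_SESSIONS_TO_CRITERION)


def generate_synthetic_cohort(point: OperatingPoint, n_animals: int,
                              schedule: SessionSchedule | None = None,
                              seed: int = 0,
                              criterion: Criterion | None = None) -> np.ndarray:
    """Sessions-to-criterion for ``n_animals`` independent model runs.

    Censored runs (never reaching criterion within the session cap) enter at
    the cap; an all-censored cohort raises.
    """
    if n_animals < 2:
        raise ValueError("n_animals must be >= 2")
    schedule = schedule or SessionSchedule()
    runs = simulate_runs(point, n_animals, schedule, seed, criterion)
    if all(r.censored for r in runs):
        raise RuntimeError("all synthetic runs censored at the session cap")
    return sessions_to_criterion_array(runs).astype(int)
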